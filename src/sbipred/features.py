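"""Assembly of the four per-drug feature modalities into one bundle.

The four modalities, matching the four prediction sub-models:

- ``CNN``      — integer token sequences (SMILES chars / residues);
- ``FP_EMB``   — SMD hashed-path fingerprint + BioD sequence embedding;
- ``SPI_BPI``  — drug-protein topology: PCA-reduced SPI-Jaccard rows for
  SMDs, raw BPI-Jaccard rows for BioDs;
- ``SSI_BBI``  — intra-type topology: PCA-reduced SSI-Jaccard rows for
  SMDs, raw BBI-Jaccard rows for BioDs.

For the vector modalities a pair's feature is the concatenation
``[smd_vector, biod_vector]``; the CNN modality keeps the two token arrays
separate (one per encoder channel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from sbipred.corpus import DrugUniverse
from sbipred.structure_features import (
    BIOD_MAX_LEN,
    SMD_MAX_LEN,
    Vocabulary,
    build_vocabulary,
    fingerprint,
    protein_embedding,
    tokenize,
)
from sbipred.topology_features import (
    PCA_COMPONENTS,
    PCATransform,
    onehot_profile,
    partner_universe,
    reduce_pca,
    similarity_matrix,
)

MODALITIES = ("CNN", "FP_EMB", "SPI_BPI", "SSI_BBI")
VECTOR_MODALITIES = ("FP_EMB", "SPI_BPI", "SSI_BBI")


@dataclass(frozen=True)
class FeatureBundle:
    """Per-drug feature stores for all four modalities, id-indexed."""

    smd_ids: tuple[str, ...]
    biod_ids: tuple[str, ...]
    tokens_smd: np.ndarray   # (n_smd, smd_max_len) int
    tokens_biod: np.ndarray  # (n_biod, biod_max_len) int
    fp_smd: np.ndarray       # (n_smd, 1024)
    emb_biod: np.ndarray     # (n_biod, 1280)
    topo: Mapping[str, np.ndarray]  # keys: SPI_smd, BPI_biod, SSI_smd, BBI_biod
    vocab_smiles: Vocabulary
    vocab_aa: Vocabulary
    pca: Mapping[str, PCATransform]  # keys: SPI, SSI

    @property
    def smd_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.smd_ids)}

    @property
    def biod_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.biod_ids)}

    def modality_dims(self, modality: str) -> tuple[int, int]:
        """(SMD dim, BioD dim) of one vector modality."""
        if modality == "FP_EMB":
            return self.fp_smd.shape[1], self.emb_biod.shape[1]
        if modality == "SPI_BPI":
            return self.topo["SPI_smd"].shape[1], self.topo["BPI_biod"].shape[1]
        if modality == "SSI_BBI":
            return self.topo["SSI_smd"].shape[1], self.topo["BBI_biod"].shape[1]
        raise KeyError(f"not a vector modality: {modality}")


def build_feature_bundle(
    universe: DrugUniverse,
    smd_max_len: int = SMD_MAX_LEN,
    biod_max_len: int = BIOD_MAX_LEN,
    pca_k: int = PCA_COMPONENTS,
    embedding_backend="fallback",
    seed: int = 0,
) -> FeatureBundle:
    """Featurize every drug of a universe in all four modalities.

    The Jaccard similarity matrices are computed over all drugs of each
    type from the four input networks (which never contain SMD-BioD edges,
    so they are label-disjoint from the prediction target), and the SMD
    rows are PCA-reduced to ``min(pca_k, n_smd)`` components.
    """
    smds, biods = universe.smd_ids, universe.biod_ids
    smiles = [universe.drugs[d].structure for d in smds]
    seqs = [universe.drugs[d].structure for d in biods]

    vocab_smiles = build_vocabulary(smiles, "SMILES")
    vocab_aa = build_vocabulary(seqs, "AA")
    tokens_smd = np.stack(
        [tokenize(s, vocab_smiles, smd_max_len).tokens for s in smiles]
    )
    tokens_biod = np.stack([tokenize(s, vocab_aa, biod_max_len).tokens for s in seqs])

    fp_smd = np.stack([fingerprint(s).vector for s in smiles])
    emb_biod = np.stack(
        [protein_embedding(s, backend=embedding_backend).vector for s in seqs]
    )

    topo: dict[str, np.ndarray] = {}
    pca: dict[str, PCATransform] = {}
    for net, drug_ids, key in (
        ("SPI", smds, "SPI_smd"),
        ("SSI", smds, "SSI_smd"),
        ("BPI", biods, "BPI_biod"),
        ("BBI", biods, "BBI_biod"),
    ):
        el = universe.edge_lists[net]
        partners = partner_universe(el)
        profiles = [onehot_profile(d, el, partners) for d in drug_ids]
        sim = similarity_matrix(profiles)
        if key.endswith("_smd"):
            scores, transform = reduce_pca(sim, k=pca_k, seed=seed)
            topo[key] = scores
            pca[net] = transform
        else:
            topo[key] = sim.matrix
    return FeatureBundle(
        smd_ids=smds,
        biod_ids=biods,
        tokens_smd=tokens_smd,
        tokens_biod=tokens_biod,
        fp_smd=fp_smd,
        emb_biod=emb_biod,
        topo=topo,
        vocab_smiles=vocab_smiles,
        vocab_aa=vocab_aa,
        pca=pca,
    )


def pair_vectors(
    bundle: FeatureBundle,
    pairs: Sequence[tuple[str, str]],
    modality: str,
) -> np.ndarray:
    """Concatenated ``[smd_feature, biod_feature]`` rows for one vector
    modality."""
    si, bi = bundle.smd_index, bundle.biod_index
    rows_s = np.array([si[s] for s, _ in pairs])
    rows_b = np.array([bi[b] for _, b in pairs])
    if modality == "FP_EMB":
        left, right = bundle.fp_smd, bundle.emb_biod
    elif modality == "SPI_BPI":
        left, right = bundle.topo["SPI_smd"], bundle.topo["BPI_biod"]
    elif modality == "SSI_BBI":
        left, right = bundle.topo["SSI_smd"], bundle.topo["BBI_biod"]
    else:
        raise KeyError(f"not a vector modality: {modality}")
    return np.hstack([left[rows_s], right[rows_b]])


def pair_tokens(
    bundle: FeatureBundle, pairs: Sequence[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """(SMD token array, BioD token array) for the CNN modality."""
    si, bi = bundle.smd_index, bundle.biod_index
    rows_s = np.array([si[s] for s, _ in pairs])
    rows_b = np.array([bi[b] for _, b in pairs])
    return bundle.tokens_smd[rows_s], bundle.tokens_biod[rows_b]


def fit_standardizer(x_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and scale of a training block (constant features get
    scale 1). Vector modalities mix binary fingerprint bits with small-scale
    projections and PCA scores, so sub-models train on z-scored inputs; the
    statistics are always fitted on training rows only."""
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def apply_standardizer(
    x: np.ndarray, stats: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    mu, sd = stats
    return (x - mu) / sd


def pu_feature_matrix(
    bundle: FeatureBundle,
    pairs: Sequence[tuple[str, str]],
    recipe: Sequence[str] = VECTOR_MODALITIES,
) -> np.ndarray:
    """Classifier-ready pair features for the PU sampler: the configured
    vector modalities concatenated."""
    mats = [pair_vectors(bundle, pairs, m) for m in recipe]
    return np.hstack(mats)
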