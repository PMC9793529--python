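"""Network-topology features: one-hot interaction profiles, Jaccard
similarity among same-type drugs, and PCA compression for the SMD side.

Each drug's position in one prior-knowledge network is encoded as a binary
*interaction profile* over that network's partner-node universe. Profiles
are then compared with the Jaccard index

    J(A, B) = |A ∩ B| / (|A| + |B| - |A ∩ B|)

over their supports, giving a square similarity matrix per network whose
rows are the drugs' topology feature vectors (dimension = the number of
same-type drugs). The high-dimensional SMD rows are reduced with PCA
(default 512 components); the small BioD rows are kept raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from sbipred.corpus import EdgeList

logger = logging.getLogger(__name__)

PCA_COMPONENTS = 512


@dataclass(frozen=True)
class OneHotProfile:
    """Binary membership vector of one drug over a partner-node universe."""

    drug_id: str
    network: str
    bits: np.ndarray

    @property
    def degree(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Jaccard similarity among same-type drugs, row-indexed."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    network: str

    def row(self, drug_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(drug_id)]


@dataclass(frozen=True)
class PCATransform:
    """Fitted centering + orthonormal projection, reusable on unseen rows.

    Sign convention: within each component the loading of largest magnitude
    is positive, so the fit is deterministic.
    """

    mean: np.ndarray
    components: np.ndarray  # (k, d)
    explained_variance: np.ndarray

    def project(self, rows: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(rows) - self.mean) @ self.components.T

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, components=self.components,
                 explained_variance=self.explained_variance)

    @classmethod
    def load(cls, path) -> "PCATransform":
        with np.load(path) as z:
            return cls(mean=z["mean"], components=z["components"],
                       explained_variance=z["explained_variance"])


def partner_universe(edge_list: EdgeList) -> tuple[str, ...]:
    """Sorted union of partner nodes observed in the network.

    For drug–protein networks these are the proteins; for intra-type
    networks, every drug appearing in any edge (either endpoint).
    """
    if edge_list.intra_type:
        nodes = {n for e in edge_list.edges for n in e}
    else:
        nodes = {b for _, b in edge_list.edges}
    return tuple(sorted(nodes))


def onehot_profile(
    drug_id: str, edge_list: EdgeList, partners: Sequence[str]
) -> OneHotProfile:
    """Bit i is set iff the drug is linked to ``partners[i]``; drugs absent
    from the network get the all-zero profile."""
    neighbors = edge_list.neighbors(drug_id)
    bits = np.fromiter(
        (1.0 if p in neighbors else 0.0 for p in partners),
        dtype=np.float64,
        count=len(partners),
    )
    return OneHotProfile(drug_id=drug_id, network=edge_list.network, bits=bits)


def jaccard(a: OneHotProfile | np.ndarray, b: OneHotProfile | np.ndarray) -> float:
    """Set Jaccard of two profiles' supports; two empty supports give 0."""
    av = a.bits if isinstance(a, OneHotProfile) else np.asarray(a, dtype=float)
    bv = b.bits if isinstance(b, OneHotProfile) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"profile dimensions differ: {av.shape} vs {bv.shape}")
    sa, sb = av > 0, bv > 0
    union = np.logical_or(sa, sb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(sa, sb).sum() / union)


def similarity_matrix(profiles: Sequence[OneHotProfile]) -> SimilarityMatrix:
    """Pairwise Jaccard of all profiles (one network, one drug type)."""
    if not profiles:
        raise ValueError("need at least one profile")
    nets = {p.network for p in profiles}
    if len(nets) != 1:
        raise ValueError(f"profiles from mixed networks: {sorted(nets)}")
    X = np.stack([p.bits > 0 for p in profiles]).astype(np.float64)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(
        ids=tuple(p.drug_id for p in profiles), matrix=J, network=nets.pop()
    )


def reduce_pca(
    sim: SimilarityMatrix | np.ndarray,
    k: int = PCA_COMPONENTS,
    seed: int = 0,
) -> tuple[np.ndarray, PCATransform]:
    """Center the similarity rows and keep the top-``k`` principal
    components by explained variance.

    Returns the per-drug scores (rows in component space) and the fitted
    transform, so unseen drugs' similarity rows can be projected later. If
    ``k`` exceeds the feasible rank, the rank is kept with a warning.
    """
    rows = sim.matrix if isinstance(sim, SimilarityMatrix) else np.asarray(sim)
    n, d = rows.shape
    feasible = min(n, d)
    if k > feasible:
        logger.warning("PCA k=%d exceeds feasible rank %d; keeping %d",
                       k, feasible, feasible)
        k = feasible
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(rows)
    components = pca.components_.copy()
    # Deterministic sign: largest-|loading| entry of each component positive.
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    transform = PCATransform(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
    )
    return scores, transform
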