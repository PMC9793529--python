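"""Seeded miniature drug universes with planted, learnable interaction signal.

The generator emulates the shape of a curated drug-interaction corpus:

- two drug populations (SMDs with grammar-built SMILES, BioDs with random
  amino-acid sequences whose residue composition is biased by a latent
  factor),
- sparse drug–protein bipartite networks (SPI, BPI) whose neighborhoods
  correlate with each drug's latent factor,
- sparse intra-type drug–drug networks (SSI, BBI) favoring latently similar
  pairs,
- a multi-event positive interaction set whose pair selection and event
  labels are driven by ``signal_strength × (latent affinity + shared-protein
  count)``, so both the structure and the network-topology modalities carry
  signal,
- a configurable fraction of true positives withheld from the labeled set
  (*hidden positives*), the ground truth that positive–unlabeled sampling
  is meant to avoid mislabeling as negatives.

Every draw comes from one ``numpy`` generator seeded from ``SimConfig.seed``,
so an identical config yields a byte-identical universe.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from sbipred.corpus import (
    Drug,
    DrugUniverse,
    EdgeList,
    Quaternary,
    validate_universe,
    write_counts_sidecar,
)

#: Chain-extensible SMILES fragments: every fragment is a valid SMILES on its
#: own and both its first and last atoms have spare valence, so any
#: concatenation of fragments is itself a valid molecule.
DEFAULT_SMILES_GRAMMAR = (
    "CC", "CCC", "CCO", "CO", "CN", "CCN", "OC", "NC",
    "C(=O)O", "C(=O)N", "C(C)C", "C=C", "C=CC",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "c1ccsc1",
)

#: Standard residues grouped so each latent dimension biases a different
#: quarter of the composition (hydrophobic / polar / charged / small+aromatic).
_RESIDUE_GROUPS = ("AVLIM", "STNQC", "DEKRH", "FWYGP")

#: Per-drug latent factors have two halves: the first four dimensions drive
#: the drug's network neighborhoods (SPI/BPI/SSI/BBI), the last four drive
#: its structure-string composition. Interaction propensity and event labels
#: depend on both halves, so the topology and structure modalities each
#: carry a complementary part of the signal and multi-modal fusion is
#: genuinely useful.
_LATENT_DIM = 8
_NET = slice(0, 4)
_STRUCT = slice(4, 8)
_N_GROUPS = 4

#: Sharpness of the latent-factor bias on fragment / residue composition.
#: Higher values make a drug's structure string more diagnostic of its
#: latent factor, hence of its interaction behavior.
_COMPOSITION_TEMPERATURE = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic universe.

    Defaults are a desk-scale corpus: 120 SMDs x 30 BioDs (3600 candidate
    pairs), 80 proteins, 6 event types — large enough for stratified 5-fold
    cross-validation, small enough for minutes-scale end-to-end runs.
    """

    n_smd: int = 120
    n_biod: int = 30
    n_protein: int = 80
    n_events: int = 6
    smiles_grammar: tuple[str, ...] = DEFAULT_SMILES_GRAMMAR
    seq_length_range: tuple[int, int] = (60, 180)
    edge_density: Mapping[str, float] = field(
        default_factory=lambda: {"SSI": 0.04, "BBI": 0.10, "SPI": 0.08, "BPI": 0.10}
    )
    positive_rate: float = 0.12
    hidden_positive_fraction: float = 0.10
    multi_event_rate: float = 0.05
    signal_strength: float = 4.0
    min_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_smd", "n_biod", "n_protein", "n_events"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("positive_rate", "hidden_positive_fraction", "multi_event_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for net, d in self.edge_density.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"edge_density[{net}] must lie in [0, 1], got {d}")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        n_pos = round(self.positive_rate * self.n_smd * self.n_biod)
        if n_pos < 1:
            raise ValueError(
                "infeasible config: positive_rate yields zero positive pairs"
            )
        if self.n_events > n_pos:
            raise ValueError(
                f"infeasible config: {self.n_events} events but only "
                f"{n_pos} positive pairs"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("smiles_grammar", "seq_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["smiles_grammar"] = list(self.smiles_grammar)
        raw["seq_length_range"] = list(self.seq_length_range)
        raw["edge_density"] = dict(self.edge_density)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _make_smiles(z: np.ndarray, grammar: tuple[str, ...], rng: np.random.Generator) -> str:
    """Assemble a SMILES by chaining fragments chosen via the latent factor."""
    by_dim = [list(grammar[d::_N_GROUPS]) for d in range(_N_GROUPS)]
    n_frag = int(rng.integers(6, 15))
    probs = _softmax(_COMPOSITION_TEMPERATURE * z[_STRUCT])
    parts = []
    for _ in range(n_frag):
        d = int(rng.choice(_N_GROUPS, p=probs))
        frags = by_dim[d] or list(grammar)
        parts.append(frags[int(rng.integers(len(frags)))])
    return "".join(parts)


def _make_sequence(
    z: np.ndarray, length_range: tuple[int, int], rng: np.random.Generator
) -> str:
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    probs = _softmax(_COMPOSITION_TEMPERATURE * z[_STRUCT])
    dims = rng.choice(_N_GROUPS, size=length, p=probs)
    chars = [
        _RESIDUE_GROUPS[d][int(rng.integers(len(_RESIDUE_GROUPS[d])))] for d in dims
    ]
    return "".join(chars)


def _top_k_neighbors(
    affinity: np.ndarray, degree: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Per-row top-``degree[i]`` picks by affinity + Gumbel noise."""
    noisy = affinity + rng.gumbel(size=affinity.shape)
    edges = []
    for i in range(affinity.shape[0]):
        k = int(degree[i])
        if k <= 0:
            continue
        picks = np.argpartition(-noisy[i], k - 1)[:k]
        edges.extend((i, int(j)) for j in sorted(picks))
    return edges


def _intra_edges(
    z: np.ndarray, density: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Undirected top-m edges by latent similarity + Gumbel noise."""
    n = z.shape[0]
    if n < 2:
        return []
    m = round(density * n * (n - 1) / 2)
    if m == 0:
        return []
    iu, ju = np.triu_indices(n, k=1)
    score = (z[iu] * z[ju]).sum(axis=1) + rng.gumbel(size=iu.shape[0])
    top = np.argpartition(-score, m - 1)[:m]
    return [(int(iu[t]), int(ju[t])) for t in sorted(top)]


def generate_universe(
    config: SimConfig,
) -> tuple[DrugUniverse, set[tuple[str, str]], dict[str, np.ndarray]]:
    """Draw one universe.

    Returns
    -------
    universe
        A validated :class:`~sbipred.corpus.DrugUniverse` whose labeled
        positive set excludes the hidden positives.
    hidden_positives
        Pairs ``(smd_id, biod_id)`` that truly interact but were withheld
        from the labeled set (they sit in the unlabeled pool).
    latent
        The per-drug latent factors and per-pair true affinity used for
        generation: keys ``z_smd``, ``z_biod``, ``affinity`` (an
        ``n_smd x n_biod`` array).
    """
    rng = np.random.default_rng(config.seed)
    smd_ids = [f"S{i:04d}" for i in range(config.n_smd)]
    biod_ids = [f"B{i:04d}" for i in range(config.n_biod)]
    protein_ids = [f"P{i:04d}" for i in range(config.n_protein)]

    z_smd = rng.normal(size=(config.n_smd, _LATENT_DIM))
    z_biod = rng.normal(size=(config.n_biod, _LATENT_DIM))
    w_protein = rng.normal(size=(config.n_protein, _NET.stop - _NET.start))

    drugs: dict[str, Drug] = {}
    for i, did in enumerate(smd_ids):
        drugs[did] = Drug(
            id=did, kind="SMD",
            structure=_make_smiles(z_smd[i], config.smiles_grammar, rng),
        )
    for i, did in enumerate(biod_ids):
        drugs[did] = Drug(
            id=did, kind="BioD",
            structure=_make_sequence(z_biod[i], config.seq_length_range, rng),
        )

    # Bipartite drug-protein networks: each drug's degree is binomial at the
    # target density; neighborhoods favor proteins aligned with the latent.
    spi_aff = z_smd[:, _NET] @ w_protein.T / 2.0
    bpi_aff = z_biod[:, _NET] @ w_protein.T / 2.0
    spi_deg = rng.binomial(config.n_protein, config.edge_density["SPI"], config.n_smd)
    bpi_deg = rng.binomial(config.n_protein, config.edge_density["BPI"], config.n_biod)
    spi = [(smd_ids[i], protein_ids[j]) for i, j in _top_k_neighbors(spi_aff, spi_deg, rng)]
    bpi = [(biod_ids[i], protein_ids[j]) for i, j in _top_k_neighbors(bpi_aff, bpi_deg, rng)]

    ssi = [
        (smd_ids[i], smd_ids[j])
        for i, j in _intra_edges(z_smd[:, _NET], config.edge_density["SSI"], rng)
    ]
    bbi = [
        (biod_ids[i], biod_ids[j])
        for i, j in _intra_edges(z_biod[:, _NET], config.edge_density["BBI"], rng)
    ]

    # Shared-protein counts feed the interaction propensity so that the
    # SPI/BPI modality carries signal about which pairs interact.
    spi_inc = np.zeros((config.n_smd, config.n_protein))
    for s, p in spi:
        spi_inc[smd_ids.index(s), protein_ids.index(p)] = 1.0
    bpi_inc = np.zeros((config.n_biod, config.n_protein))
    for b, p in bpi:
        bpi_inc[biod_ids.index(b), protein_ids.index(p)] = 1.0
    shared = spi_inc @ bpi_inc.T
    shared_z = (shared - shared.mean()) / (shared.std() + 1e-12)

    affinity = z_smd @ z_biod.T / np.sqrt(_LATENT_DIM) + 0.5 * shared_z
    n_pairs = config.n_smd * config.n_biod
    n_pos = round(config.positive_rate * n_pairs)
    score = (config.signal_strength * affinity).ravel() + rng.gumbel(size=n_pairs)
    pos_flat = np.sort(np.argpartition(-score, n_pos - 1)[:n_pos])
    pos_pairs = [(int(f) // config.n_biod, int(f) % config.n_biod) for f in pos_flat]

    # Event labels: per-event direction vectors + a decaying prior, so early
    # event ids are frequent and late ones naturally fall in the rare bucket.
    u_ev = rng.normal(size=(config.n_events, _LATENT_DIM))
    v_ev = rng.normal(size=(config.n_events, _LATENT_DIM))
    g_ev = rng.normal(size=config.n_events)
    prior = -0.8 * np.arange(config.n_events)

    def _event_probs(i: int, j: int) -> np.ndarray:
        logits = config.signal_strength * (
            u_ev @ z_smd[i] + v_ev @ z_biod[j] + g_ev * shared_z[i, j]
        ) / np.sqrt(_LATENT_DIM) + prior
        return _softmax(logits)

    def _quaternary(i: int, j: int, event: int) -> Quaternary:
        return Quaternary(
            drug_a=smd_ids[i],
            drug_b=biod_ids[j],
            mechanism=f"mechanism_{event // 2 + 1}",
            action="increase" if event % 2 == 0 else "decrease",
        )

    quaternaries: dict[tuple[str, str], list[Quaternary]] = {}
    for i, j in pos_pairs:
        p = _event_probs(i, j)
        ev = int(rng.choice(config.n_events, p=p))
        qs = [_quaternary(i, j, ev)]
        if config.n_events > 1 and rng.random() < config.multi_event_rate:
            second = int(rng.choice(config.n_events, p=p))
            if second != ev:
                qs.append(_quaternary(i, j, second))
        quaternaries[(smd_ids[i], biod_ids[j])] = qs

    n_hidden = round(config.hidden_positive_fraction * n_pos)
    hidden_idx = rng.choice(n_pos, size=n_hidden, replace=False)
    hidden = {
        (smd_ids[pos_pairs[t][0]], biod_ids[pos_pairs[t][1]])
        for t in sorted(int(h) for h in hidden_idx)
    }
    labeled = [
        q for pair, qs in sorted(quaternaries.items()) if pair not in hidden
        for q in qs
    ]

    universe = validate_universe(
        drugs,
        protein_ids,
        {
            "SSI": EdgeList("SSI", frozenset(ssi)),
            "BBI": EdgeList("BBI", frozenset(bbi)),
            "SPI": EdgeList("SPI", frozenset(spi)),
            "BPI": EdgeList("BPI", frozenset(bpi)),
        },
        labeled,
        min_count=config.min_count,
    )
    latent = {"z_smd": z_smd, "z_biod": z_biod, "affinity": affinity}
    return universe, hidden, latent


def write_universe(universe: DrugUniverse, out_dir: str | Path) -> dict[str, Path]:
    """Write a universe in the corpus file formats; round-trips via
    :func:`sbipred.corpus.load_universe`.

    Returns the mapping of logical names to written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "smiles": out / "smd.csv",
        "fasta": out / "biod.fasta",
        "SSI": out / "ssi.tsv",
        "BBI": out / "bbi.tsv",
        "SPI": out / "spi.tsv",
        "BPI": out / "bpi.tsv",
        "sbi": out / "sbi.csv",
        "counts": out / "counts.json",
    }
    with open(paths["smiles"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles"])
        for did in universe.smd_ids:
            w.writerow([did, universe.drugs[did].structure])
    with open(paths["fasta"], "w") as fh:
        for did in universe.biod_ids:
            seq = universe.drugs[did].structure
            fh.write(f">{did}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
    for net in ("SSI", "BBI", "SPI", "BPI"):
        with open(paths[net], "w") as fh:
            for a, b in sorted(universe.edge_lists[net].edges):
                fh.write(f"{a}\t{b}\n")
    with open(paths["sbi"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_a", "drug_b", "mechanism", "action"])
        for q in universe.quaternaries:
            w.writerow([q.drug_a, q.drug_b, q.mechanism, q.action])
    write_counts_sidecar(universe, paths["counts"])
    return paths


def write_pairs_csv(pairs: set[tuple[str, str]], path: str | Path) -> None:
    """Persist a pair set (e.g. the hidden positives) as a 2-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smd_id", "biod_id"])
        for s, b in sorted(pairs):
            w.writerow([s, b])


def load_pairs_csv(path: str | Path) -> set[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return {(r["smd_id"], r["biod_id"]) for r in reader}
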