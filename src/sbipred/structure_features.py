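"""Structure modalities: tokenized sequences and fixed-length drug vectors.

Two representations are produced per drug:

* **Token vectors** — the raw structure string mapped character-by-character
  to integer indices (SMILES for SMDs, amino acids for BioDs), right-padded
  or truncated to a fixed length (defaults: 1000 for SMDs, 100 for BioDs).
  These feed the learned 1D-CNN encoders.
* **Structure vectors** — a 1024-bit hashed linear-path fingerprint for SMDs
  (topological, Daylight-style: every simple atom-bond path up to 7 bonds is
  hashed onto the bit space) and a 1280-dimensional embedding for BioDs. The
  BioD embedding backend is pluggable: the built-in ``fallback`` backend is a
  deterministic L2-normalized hashed 3-mer profile pushed through a fixed
  random projection; an ``external`` backend may wrap any pretrained protein
  language model producing 1280 dimensions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import json
import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

SMD_MAX_LEN = 1000
BIOD_MAX_LEN = 100
FINGERPRINT_BITS = 1024
EMBEDDING_DIM = 1280
PATH_MAX_BONDS = 7
EMBED_TRUNCATE_RESIDUES = 1024  # only the leading residues are embedded

_KMER_K = 3
_KMER_BUCKETS = 2048


class FeaturizationError(ValueError):
    """A drug structure could not be featurized."""


@dataclass(frozen=True)
class Vocabulary:
    """Character-to-index map with 0 reserved for padding.

    Indices are contiguous from 1; characters never seen at build time map
    to the reserved ``unknown_index`` (= vocabulary size + 1) at tokenize
    time so novel drugs can still be scored.
    """

    index: dict[str, int]
    kind: str  # "SMILES" | "AA"

    def __post_init__(self) -> None:
        vals = sorted(self.index.values())
        if vals != list(range(1, len(vals) + 1)):
            raise ValueError("vocabulary indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.index)

    @property
    def unknown_index(self) -> int:
        return len(self.index) + 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "index": self.index}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(index=raw["index"], kind=raw["kind"])


@dataclass(frozen=True)
class TokenVector:
    """Fixed-length integer encoding of one structure string."""

    tokens: np.ndarray
    original_length: int


@dataclass(frozen=True)
class StructureVector:
    """Fixed-length real feature vector with featurizer provenance."""

    vector: np.ndarray
    featurizer: str


def build_vocabulary(structures: Iterable[str], kind: str) -> Vocabulary:
    """One index per distinct character, in first-occurrence order over the
    sorted input corpus (deterministic for any input ordering)."""
    index: dict[str, int] = {}
    for s in sorted(structures):
        for ch in s:
            if ch not in index:
                index[ch] = len(index) + 1
    if not index:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(index=index, kind=kind)


def tokenize(structure: str, vocab: Vocabulary, max_len: int) -> TokenVector:
    """Map the first ``max_len`` characters to indices; right-pad with 0."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = np.zeros(max_len, dtype=np.int64)
    unknown = 0
    for i, ch in enumerate(structure[:max_len]):
        idx = vocab.index.get(ch)
        if idx is None:
            idx = vocab.unknown_index
            unknown += 1
        tokens[i] = idx
    if unknown:
        logger.warning(
            "%d character(s) outside the %s vocabulary mapped to the unknown "
            "index %d", unknown, vocab.kind, vocab.unknown_index,
        )
    return TokenVector(tokens=tokens, original_length=len(structure))


# --- SMD fingerprint -------------------------------------------------------

def _atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    charge = atom.GetFormalCharge()
    return sym if charge == 0 else f"{sym}{charge:+d}"

_BOND_LABEL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def enumerate_linear_paths(mol: Chem.Mol, max_bonds: int = PATH_MAX_BONDS) -> set[str]:
    """All simple linear atom-bond paths of 0..``max_bonds`` bonds.

    Each path is rendered as an alternating atom/bond label string and
    normalized to the lexicographically smaller of its two directions, so the
    result is independent of atom numbering (hence of the SMILES alias used).
    """
    paths: set[str] = set()

    def walk(atom_idx: int, visited: list[int], labels: list[str]) -> None:
        forward = "".join(labels)
        backward = "".join(reversed(labels))
        paths.add(min(forward, backward))
        if (len(visited) - 1) >= max_bonds:
            return
        atom = mol.GetAtomWithIdx(atom_idx)
        for bond in atom.GetBonds():
            nxt = bond.GetOtherAtomIdx(atom_idx)
            if nxt in visited:
                continue
            blabel = _BOND_LABEL.get(bond.GetBondType(), "~")
            walk(
                nxt,
                visited + [nxt],
                labels + [blabel, _atom_label(mol.GetAtomWithIdx(nxt))],
            )

    for a in mol.GetAtoms():
        walk(a.GetIdx(), [a.GetIdx()], [_atom_label(a)])
    return paths


def _path_bits(path: str, n_bits: int, bits_per_path: int = 2) -> list[int]:
    digest = hashlib.sha256(path.encode()).digest()
    return [
        int.from_bytes(digest[2 * i : 2 * i + 2], "big") % n_bits
        for i in range(bits_per_path)
    ]


def fingerprint(smiles: str, n_bits: int = FINGERPRINT_BITS) -> StructureVector:
    """Binary hashed-path fingerprint of one molecule.

    The molecule is parsed and sanitized, every simple linear path up to
    7 bonds is enumerated, and each path string sets 2 bits chosen by a
    cryptographic hash — a deterministic, alias-invariant topological
    fingerprint in the Daylight tradition.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    vec = np.zeros(n_bits, dtype=np.float64)
    for path in enumerate_linear_paths(mol):
        for b in _path_bits(path, n_bits):
            vec[b] = 1.0
    return StructureVector(vector=vec, featurizer=f"hashed-path-fp/1.0:{n_bits}")


def tanimoto(a: StructureVector, b: StructureVector) -> float:
    """Tanimoto similarity of two binary fingerprints."""
    av, bv = a.vector > 0, b.vector > 0
    union = np.logical_or(av, bv).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(av, bv).sum() / union)


# --- BioD embedding --------------------------------------------------------

def kmer_bucket_counts(
    sequence: str, k: int = _KMER_K, n_buckets: int = _KMER_BUCKETS
) -> np.ndarray:
    """Counts of overlapping k-mers hashed into a fixed bucket space."""
    counts = np.zeros(n_buckets, dtype=np.float64)
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        bucket = int.from_bytes(hashlib.sha256(kmer.encode()).digest()[:4], "big")
        counts[bucket % n_buckets] += 1.0
    return counts


_projection_cache: dict[tuple[int, int], np.ndarray] = {}


def _projection(n_in: int, n_out: int) -> np.ndarray:
    key = (n_in, n_out)
    if key not in _projection_cache:
        # Fixed seed: the projection is part of the featurizer definition,
        # identical across runs and platforms.
        rng = np.random.default_rng(7_411_931)
        _projection_cache[key] = rng.normal(size=(n_in, n_out)) / np.sqrt(n_in)
    return _projection_cache[key]


def fallback_embedding(sequence: str, dim: int = EMBEDDING_DIM) -> np.ndarray:
    """Deterministic sequence embedding: L2-normalized hashed 3-mer counts
    through a fixed Gaussian random projection."""
    counts = kmer_bucket_counts(sequence)
    norm = np.linalg.norm(counts)
    if norm > 0:
        counts = counts / norm
    return counts @ _projection(_KMER_BUCKETS, dim)


def protein_embedding(
    sequence: str,
    backend: str | Callable[[str], np.ndarray] = "fallback",
    dim: int = EMBEDDING_DIM,
) -> StructureVector:
    """Embed a BioD amino-acid sequence into ``dim`` dimensions.

    Only the first 1024 residues are embedded (longer tails are ignored).
    ``backend`` is either the built-in ``"fallback"`` or any callable
    implementing the adapter contract ``sequence -> (dim,) array`` — e.g. a
    wrapper around a pretrained protein language model.
    """
    if not sequence:
        raise FeaturizationError("empty amino-acid sequence")
    head = sequence[:EMBED_TRUNCATE_RESIDUES]
    if backend == "fallback":
        vec = fallback_embedding(head, dim)
        name = f"kmer-projection/1.0:{dim}"
    elif callable(backend):
        vec = np.asarray(backend(head), dtype=np.float64)
        name = f"external:{getattr(backend, '__name__', 'adapter')}"
    else:
        raise ValueError(f"unknown embedding backend {backend!r}")
    if vec.shape != (dim,):
        raise FeaturizationError(
            f"embedding backend returned shape {vec.shape}, expected ({dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise FeaturizationError("embedding contains non-finite entries")
    return StructureVector(vector=vec, featurizer=name)
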