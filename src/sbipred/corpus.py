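"""Drug universe loading, validation, and event-catalog construction.

A *universe* bundles the two drug populations (SMDs with SMILES structures,
BioDs with amino-acid sequences), the protein set, the four prior-knowledge
networks (SSI, BBI, SPI, BPI), and the labeled positive interaction set.
Positive interactions are *quaternaries* ``(drug A, drug B, mechanism,
action)``; each distinct ``(mechanism, action)`` combination is an event
class, with infrequent events pooled into a single rare bucket.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 25-letter amino-acid alphabet accepted for BioD sequences: the 20
#: standard residues plus the ambiguity/rare codes B, X, Z, U, O.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBXZUO"

NETWORKS = ("SSI", "BBI", "SPI", "BPI")

ACTIONS = ("increase", "decrease")


class ValidationError(ValueError):
    """An input row violates a universe invariant."""


@dataclass(frozen=True)
class Drug:
    """A drug node: an SMD (SMILES structure) or a BioD (AA sequence)."""

    id: str
    kind: str  # "SMD" | "BioD"
    structure: str

    def __post_init__(self) -> None:
        if self.kind not in ("SMD", "BioD"):
            raise ValidationError(f"drug {self.id!r}: unknown kind {self.kind!r}")
        if not self.structure:
            raise ValidationError(f"drug {self.id!r}: empty structure")
        if self.kind == "BioD":
            bad = set(self.structure.upper()) - set(AA_ALPHABET)
            if bad:
                raise ValidationError(
                    f"drug {self.id!r}: residues {sorted(bad)} outside the "
                    f"25-letter amino-acid alphabet"
                )


@dataclass(frozen=True)
class EdgeList:
    """Deduplicated edge set of one network.

    Intra-type networks (SSI, BBI) are undirected: edges are stored with
    endpoints sorted. Drug–protein networks (SPI, BPI) are ordered
    ``(drug, protein)`` pairs.
    """

    network: str
    edges: frozenset[tuple[str, str]]

    @property
    def intra_type(self) -> bool:
        return self.network in ("SSI", "BBI")

    def neighbors(self, node: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif self.intra_type and b == node:
                out.add(a)
        return out


@dataclass(frozen=True)
class Quaternary:
    """One labeled positive interaction: (SMD, BioD, mechanism, action)."""

    drug_a: str
    drug_b: str
    mechanism: str
    action: str

    @property
    def event_key(self) -> tuple[str, str]:
        return (self.mechanism, self.action)


@dataclass(frozen=True)
class EventCatalog:
    """Mapping from (mechanism, action) to contiguous event ids ``1..K``.

    Events whose count is at most ``min_count`` collapse into a single rare
    bucket placed after all frequent events. Id 0 is reserved for the
    no-interaction class, so the total label-vector dimension is
    ``n_classes = K + 1``.
    """

    event_ids: Mapping[tuple[str, str], int]
    counts: Mapping[tuple[str, str], int]
    rare_bucket_id: int | None
    min_count: int

    @property
    def n_events(self) -> int:
        """Number of event classes K (frequent + the rare bucket if present)."""
        return max(self.event_ids.values(), default=0)

    @property
    def n_classes(self) -> int:
        """Total label classes including class 0 (no interaction)."""
        return self.n_events + 1

    def event_id(self, mechanism: str, action: str) -> int:
        return self.event_ids[(mechanism, action)]


@dataclass(frozen=True)
class DrugUniverse:
    """All drugs, proteins, networks, and labeled positives of one study."""

    drugs: Mapping[str, Drug]
    proteins: tuple[str, ...]
    edge_lists: Mapping[str, EdgeList]
    quaternaries: tuple[Quaternary, ...]
    catalog: EventCatalog

    @property
    def smd_ids(self) -> tuple[str, ...]:
        return tuple(sorted(d.id for d in self.drugs.values() if d.kind == "SMD"))

    @property
    def biod_ids(self) -> tuple[str, ...]:
        return tuple(sorted(d.id for d in self.drugs.values() if d.kind == "BioD"))

    @property
    def positive_pairs(self) -> set[tuple[str, str]]:
        return {(q.drug_a, q.drug_b) for q in self.quaternaries}

    def counts(self) -> dict[str, int]:
        """Entity and edge counts, one row per data category."""
        out = {
            "SMD": len(self.smd_ids),
            "BioD": len(self.biod_ids),
            "Protein": len(self.proteins),
        }
        for net in NETWORKS:
            out[net] = len(self.edge_lists[net].edges)
        out["SBI"] = len(self.quaternaries)
        return out


def build_event_catalog(
    quaternaries: Sequence[Quaternary], min_count: int = 10
) -> EventCatalog:
    """Assign event ids by descending frequency, pooling rare events.

    Frequent events (count strictly greater than ``min_count``) receive ids
    ``1..F`` ordered by descending count with ties broken lexicographically
    on ``(mechanism, action)``. All events with count at most ``min_count``
    map to a single rare-bucket id ``F + 1``. The result is independent of
    the input order.
    """
    if not quaternaries:
        raise ValueError("cannot build an event catalog from zero quaternaries")
    counts = Counter(q.event_key for q in quaternaries)
    frequent = sorted(
        (k for k, c in counts.items() if c > min_count),
        key=lambda k: (-counts[k], k),
    )
    rare = [k for k, c in counts.items() if c <= min_count]
    event_ids = {k: i + 1 for i, k in enumerate(frequent)}
    rare_bucket_id = len(frequent) + 1 if rare else None
    for k in rare:
        event_ids[k] = rare_bucket_id
    return EventCatalog(
        event_ids=dict(event_ids),
        counts=dict(counts),
        rare_bucket_id=rare_bucket_id,
        min_count=min_count,
    )


def _dedup_edges(
    network: str, raw: Iterable[tuple[str, str]]
) -> frozenset[tuple[str, str]]:
    intra = network in ("SSI", "BBI")
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for a, b in raw:
        if a == b:
            raise ValidationError(f"{network}: self-loop on {a!r}")
        key = (min(a, b), max(a, b)) if intra else (a, b)
        if key in seen:
            n_dup += 1
        else:
            seen.add(key)
    if n_dup:
        logger.warning("%s: %d duplicate edge rows collapsed", network, n_dup)
    return frozenset(seen)


def _validate_edges(
    universe_edges: Mapping[str, EdgeList],
    drugs: Mapping[str, Drug],
    proteins: set[str],
) -> None:
    expect = {
        "SSI": ("SMD", "SMD"),
        "BBI": ("BioD", "BioD"),
        "SPI": ("SMD", "protein"),
        "BPI": ("BioD", "protein"),
    }
    for net, el in universe_edges.items():
        kind_a, kind_b = expect[net]
        for a, b in sorted(el.edges):
            if a not in drugs or drugs[a].kind != kind_a:
                raise ValidationError(
                    f"{net} edge ({a!r}, {b!r}): {a!r} is not a known {kind_a}"
                )
            if kind_b == "protein":
                if b not in proteins:
                    raise ValidationError(
                        f"{net} edge ({a!r}, {b!r}): {b!r} is not a known protein"
                    )
            elif b not in drugs or drugs[b].kind != kind_b:
                raise ValidationError(
                    f"{net} edge ({a!r}, {b!r}): {b!r} is not a known {kind_b}"
                )


def validate_universe(
    drugs: Mapping[str, Drug],
    proteins: Sequence[str],
    edge_lists: Mapping[str, EdgeList],
    quaternaries: Sequence[Quaternary],
    min_count: int = 10,
) -> DrugUniverse:
    """Assemble a :class:`DrugUniverse`, enforcing all type invariants."""
    protein_set = set(proteins)
    missing = [n for n in NETWORKS if n not in edge_lists]
    if missing:
        raise ValidationError(f"missing networks: {missing}")
    _validate_edges(edge_lists, drugs, protein_set)
    seen_pairs: set[tuple[str, str, str, str]] = set()
    for i, q in enumerate(quaternaries):
        for did, want in ((q.drug_a, "SMD"), (q.drug_b, "BioD")):
            if did not in drugs:
                raise ValidationError(f"SBI row {i}: unknown drug id {did!r}")
            if drugs[did].kind != want:
                raise ValidationError(
                    f"SBI row {i}: {did!r} is a {drugs[did].kind}, expected {want}"
                )
        if q.action not in ACTIONS:
            raise ValidationError(f"SBI row {i}: action {q.action!r} not in {ACTIONS}")
        key = (q.drug_a, q.drug_b, q.mechanism, q.action)
        if key in seen_pairs:
            raise ValidationError(f"SBI row {i}: duplicate quaternary {key}")
        seen_pairs.add(key)
    catalog = build_event_catalog(quaternaries, min_count=min_count)
    return DrugUniverse(
        drugs=dict(drugs),
        proteins=tuple(sorted(protein_set)),
        edge_lists=dict(edge_lists),
        quaternaries=tuple(quaternaries),
        catalog=catalog,
    )


def _read_edge_file(path: Path, network: str) -> frozenset[tuple[str, str]]:
    raw: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            raw.append((parts[0], parts[1]))
    return _dedup_edges(network, raw)


def load_universe(
    smiles_path: str | Path,
    fasta_path: str | Path,
    edge_paths: Mapping[str, str | Path],
    sbi_path: str | Path,
    min_count: int = 10,
) -> DrugUniverse:
    """Read a universe from disk and validate it.

    Parameters
    ----------
    smiles_path
        CSV with columns ``id,smiles`` — one row per SMD.
    fasta_path
        FASTA of BioD amino-acid sequences; record id = drug id.
    edge_paths
        Mapping of network name (``SSI``, ``BBI``, ``SPI``, ``BPI``) to a
        2-column TSV of node-id pairs. Protein ids are collected from the
        SPI/BPI files.
    sbi_path
        CSV with columns ``drug_a,drug_b,mechanism,action`` — the labeled
        positive interactions.
    min_count
        Rare-event threshold: events with at most this many interactions are
        pooled into the rare bucket.
    """
    drugs: dict[str, Drug] = {}
    with open(smiles_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"id", "smiles"}:
            raise ValidationError(f"{smiles_path}: expected CSV header id,smiles")
        for lineno, row in enumerate(reader, 2):
            did = row["id"]
            if did in drugs:
                raise ValidationError(f"{smiles_path}:{lineno}: duplicate id {did!r}")
            drugs[did] = Drug(id=did, kind="SMD", structure=row["smiles"])

    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in drugs:
            raise ValidationError(f"{fasta_path}: duplicate id {record.id!r}")
        drugs[record.id] = Drug(id=record.id, kind="BioD", structure=str(record.seq))

    edge_lists: dict[str, EdgeList] = {}
    proteins: set[str] = set()
    for net in NETWORKS:
        if net not in edge_paths:
            raise ValidationError(f"no edge file given for network {net}")
        edges = _read_edge_file(Path(edge_paths[net]), net)
        edge_lists[net] = EdgeList(network=net, edges=edges)
        if net in ("SPI", "BPI"):
            proteins.update(b for _, b in edges)

    quaternaries: list[Quaternary] = []
    with open(sbi_path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"drug_a", "drug_b", "mechanism", "action"}
        if reader.fieldnames is None or set(reader.fieldnames) < need:
            raise ValidationError(
                f"{sbi_path}: expected CSV header drug_a,drug_b,mechanism,action"
            )
        for row in reader:
            quaternaries.append(
                Quaternary(
                    drug_a=row["drug_a"],
                    drug_b=row["drug_b"],
                    mechanism=row["mechanism"],
                    action=row["action"],
                )
            )

    universe = validate_universe(
        drugs, sorted(proteins), edge_lists, quaternaries, min_count=min_count
    )
    logger.info("loaded universe: %s", universe.counts())
    return universe


def enumerate_candidate_pairs(universe: DrugUniverse) -> pd.DataFrame:
    """Enumerate the full SMD × BioD candidate space with positive labels.

    Returns a DataFrame with one row per ordered pair ``(smd_id, biod_id)``
    — exactly ``|SMD| * |BioD|`` rows — and columns:

    - ``smd_id``, ``biod_id``
    - ``positive``: True iff the pair appears in the labeled quaternary set
    - ``event_ids``: tuple of event ids for positive pairs (a pair with
      several quaternaries gets all of them — a multi-hot label), empty
      tuple for unlabeled pairs.
    """
    events_by_pair: dict[tuple[str, str], set[int]] = {}
    for q in universe.quaternaries:
        eid = universe.catalog.event_id(q.mechanism, q.action)
        events_by_pair.setdefault((q.drug_a, q.drug_b), set()).add(eid)

    smds, biods = universe.smd_ids, universe.biod_ids
    rows = []
    for s in smds:
        for b in biods:
            ev = events_by_pair.get((s, b))
            rows.append((s, b, ev is not None, tuple(sorted(ev)) if ev else ()))
    df = pd.DataFrame(rows, columns=["smd_id", "biod_id", "positive", "event_ids"])
    n_pos = int(df["positive"].sum())
    logger.info(
        "candidate space: %d pairs = %d SMD x %d BioD; %d positive, %d unlabeled",
        len(df), len(smds), len(biods), n_pos, len(df) - n_pos,
    )
    return df


def write_counts_sidecar(universe: DrugUniverse, path: str | Path) -> None:
    """Write the universe's category counts as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(universe.counts(), fh, indent=2)
        fh.write("\n")
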