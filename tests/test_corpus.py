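import random

import pytest

from sbipred.corpus import (
    Drug,
    EdgeList,
    Quaternary,
    ValidationError,
    build_event_catalog,
    enumerate_candidate_pairs,
    load_universe,
    validate_universe,
)
from sbipred.synthetic_data import write_universe


def _quats(counts):
    """One quaternary list realizing the given {(mech, action): count}."""
    out = []
    for (mech, act), c in counts.items():
        for i in range(c):
            out.append(Quaternary(f"S{mech}{act}{i}", f"B{i}", mech, act))
    return out


class TestEventCatalog:
    @pytest.mark.parametrize(
        "counts,min_count,expected_ids,expected_rare,n_classes",
        [
            # threshold arithmetic: 8 <= 10 pooled, others ranked by count
            ({("e1", "increase"): 50, ("e2", "increase"): 8, ("e3", "increase"): 12},
             10,
             {("e1", "increase"): 1, ("e3", "increase"): 2, ("e2", "increase"): 3},
             3, 4),
            # boundary: 11 > 10 stays frequent, no rare bucket
            ({("e1", "increase"): 11}, 10, {("e1", "increase"): 1}, None, 2),
            # boundary: exactly 10 means "no more than 10" -> rare bucket
            ({("e1", "increase"): 10}, 10, {("e1", "increase"): 1}, 1, 2),
        ],
    )
    def test_threshold_and_ordering(
        self, counts, min_count, expected_ids, expected_rare, n_classes
    ):
        cat = build_event_catalog(_quats(counts), min_count=min_count)
        assert dict(cat.event_ids) == expected_ids
        assert cat.rare_bucket_id == expected_rare
        assert cat.n_classes == n_classes

    def test_tie_break_is_lexicographic(self):
        counts = {("b", "increase"): 20, ("a", "increase"): 20}
        cat = build_event_catalog(_quats(counts), min_count=10)
        assert cat.event_id("a", "increase") == 1
        assert cat.event_id("b", "increase") == 2

    def test_order_independence(self):
        quats = _quats(
            {("m1", "increase"): 15, ("m2", "decrease"): 3, ("m3", "increase"): 40}
        )
        cat_a = build_event_catalog(quats, min_count=10)
        shuffled = quats[:]
        random.Random(5).shuffle(shuffled)
        cat_b = build_event_catalog(shuffled, min_count=10)
        assert cat_a == cat_b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_event_catalog([])


class TestValidation:
    def _base(self):
        drugs = {
            "S1": Drug("S1", "SMD", "CCO"),
            "S2": Drug("S2", "SMD", "CCN"),
            "B1": Drug("B1", "BioD", "ACDEF"),
        }
        edges = {
            "SSI": EdgeList("SSI", frozenset({("S1", "S2")})),
            "BBI": EdgeList("BBI", frozenset()),
            "SPI": EdgeList("SPI", frozenset({("S1", "P1")})),
            "BPI": EdgeList("BPI", frozenset({("B1", "P1")})),
        }
        quats = [Quaternary("S1", "B1", "metabolism", "increase")]
        return drugs, edges, quats

    def test_valid_universe_assembles(self):
        drugs, edges, quats = self._base()
        u = validate_universe(drugs, ["P1"], edges, quats, min_count=0)
        assert u.counts()["SBI"] == 1

    def test_biod_as_drug_a_rejected(self):
        drugs, edges, _ = self._base()
        bad = [Quaternary("B1", "B1", "metabolism", "increase")]
        with pytest.raises(ValidationError, match="expected SMD"):
            validate_universe(drugs, ["P1"], edges, bad, min_count=0)

    def test_unknown_edge_endpoint_rejected(self):
        drugs, edges, quats = self._base()
        edges["SSI"] = EdgeList("SSI", frozenset({("S1", "S9")}))
        with pytest.raises(ValidationError, match="S9"):
            validate_universe(drugs, ["P1"], edges, quats, min_count=0)

    def test_biod_alphabet_enforced(self):
        with pytest.raises(ValidationError, match="alphabet"):
            Drug("B9", "BioD", "ACDEF123")


class TestLoadUniverse:
    def test_round_trip_identity(self, tiny_universe, tmp_path):
        paths = write_universe(tiny_universe, tmp_path)
        reloaded = load_universe(
            paths["smiles"], paths["fasta"],
            {n: paths[n] for n in ("SSI", "BBI", "SPI", "BPI")},
            paths["sbi"], min_count=tiny_universe.catalog.min_count,
        )
        assert reloaded.drugs == tiny_universe.drugs
        assert reloaded.proteins == tiny_universe.proteins
        for net in ("SSI", "BBI", "SPI", "BPI"):
            assert (
                reloaded.edge_lists[net].edges == tiny_universe.edge_lists[net].edges
            )
        assert set(reloaded.quaternaries) == set(tiny_universe.quaternaries)
        assert reloaded.catalog == tiny_universe.catalog

    def test_duplicate_edge_collapsed_with_warning(
        self, tiny_universe, tmp_path, caplog
    ):
        paths = write_universe(tiny_universe, tmp_path)
        ssi = paths["SSI"].read_text().splitlines()
        (tmp_path / "ssi_dup.tsv").write_text("\n".join(ssi + [ssi[0]]) + "\n")
        with caplog.at_level("WARNING"):
            reloaded = load_universe(
                paths["smiles"], paths["fasta"],
                {"SSI": tmp_path / "ssi_dup.tsv", "BBI": paths["BBI"],
                 "SPI": paths["SPI"], "BPI": paths["BPI"]},
                paths["sbi"], min_count=tiny_universe.catalog.min_count,
            )
        assert reloaded.edge_lists["SSI"].edges == tiny_universe.edge_lists["SSI"].edges
        assert "duplicate" in caplog.text

    def test_malformed_edge_row_reports_line(self, tiny_universe, tmp_path):
        paths = write_universe(tiny_universe, tmp_path)
        (tmp_path / "bad.tsv").write_text("a\tb\tc\n")
        with pytest.raises(ValidationError, match="bad.tsv:1"):
            load_universe(
                paths["smiles"], paths["fasta"],
                {"SSI": tmp_path / "bad.tsv", "BBI": paths["BBI"],
                 "SPI": paths["SPI"], "BPI": paths["BPI"]},
                paths["sbi"],
            )


class TestCandidateEnumeration:
    def test_small_product(self):
        drugs = {
            "S1": Drug("S1", "SMD", "CC"),
            "S2": Drug("S2", "SMD", "CO"),
            "B1": Drug("B1", "BioD", "ACD"),
            "B2": Drug("B2", "BioD", "ACE"),
            "B3": Drug("B3", "BioD", "ACF"),
        }
        edges = {n: EdgeList(n, frozenset()) for n in ("SSI", "BBI", "SPI", "BPI")}
        quats = [Quaternary("S1", "B2", "metabolism", "increase")]
        u = validate_universe(drugs, [], edges, quats, min_count=0)
        df = enumerate_candidate_pairs(u)
        assert len(df) == 6
        assert int(df["positive"].sum()) == 1
        row = df[df["positive"]].iloc[0]
        assert (row["smd_id"], row["biod_id"]) == ("S1", "B2")
        assert row["event_ids"] == (1,)

    def test_partition_arithmetic(self, tiny_universe):
        df = enumerate_candidate_pairs(tiny_universe)
        n_smd = len(tiny_universe.smd_ids)
        n_biod = len(tiny_universe.biod_ids)
        assert len(df) == n_smd * n_biod
        n_pos = int(df["positive"].sum())
        assert n_pos == len(tiny_universe.positive_pairs)
        assert (~df["positive"]).sum() == len(df) - n_pos

    def test_every_positive_has_events_in_range(self, tiny_universe):
        df = enumerate_candidate_pairs(tiny_universe)
        K = tiny_universe.catalog.n_events
        for evs in df.loc[df["positive"], "event_ids"]:
            assert len(evs) >= 1
            assert all(1 <= e <= K for e in evs)
        assert (df.loc[~df["positive"], "event_ids"].map(len) == 0).all()
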