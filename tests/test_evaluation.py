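import numpy as np
import pytest

from sbipred.evaluation import (
    Metrics,
    MetricReport,
    assemble_dataset,
    compute_metrics,
    make_folds,
    run_cv,
    top1_accuracy,
)
from sbipred.model import TrainConfig, label_matrix


def sweep_oracle(y_true, y_score):
    """Brute-force threshold sweep over the pooled indicator cells:
    trapezoidal ROC area and step-interpolated PR area."""
    t = np.asarray(y_true, float).ravel()
    s = np.asarray(y_score, float).ravel()
    P, N = t.sum(), (1 - t).sum()
    thresholds = np.unique(s)[::-1]
    tpr, fpr, pre, rec = [0.0], [0.0], [], []
    for th in thresholds:
        pred = s >= th
        tp = float((pred * t).sum())
        fp = float((pred * (1 - t)).sum())
        tpr.append(tp / P)
        fpr.append(fp / N)
        pre.append(tp / (tp + fp))
        rec.append(tp / P)
    auc = float(np.trapezoid(tpr, fpr))
    aupr, prev_rec = 0.0, 0.0
    for p, r in zip(pre, rec):
        aupr += (r - prev_rec) * p
        prev_rec = r
    return auc, aupr


def random_fixture(rng, n=40, k=4):
    y = (rng.random((n, k)) < 0.3).astype(float)
    y[0] = 1.0  # ensure both classes present overall
    y[1] = 0.0
    s = rng.random((n, k))
    return y, s


class TestMakeFolds:
    def _pairs(self, n):
        return [(f"s{i:03d}", f"b{i:03d}") for i in range(n)]

    def test_partition_arithmetic(self):
        plan = make_folds(self._pairs(100), [i % 3 for i in range(100)], k=5, seed=0)
        tests = [set(te) for _, te in plan.folds]
        assert all(len(t) == 20 for t in tests)
        assert set().union(*tests) == set(range(100))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]
        for tr, te in plan.folds:
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == 100

    def test_deterministic_given_seed(self):
        a = make_folds(self._pairs(50), [0] * 50, k=5, seed=3)
        b = make_folds(self._pairs(50), [0] * 50, k=5, seed=3)
        assert a == b
        c = make_folds(self._pairs(50), [0] * 50, k=5, seed=4)
        assert a != c

    def test_stratification_balances_classes(self):
        strata = [0] * 60 + [1] * 40
        plan = make_folds(self._pairs(100), strata, k=5, seed=0)
        for _, te in plan.folds:
            labels = [strata[i] for i in te]
            assert labels.count(1) == 8  # 40/5 per fold

    def test_rare_strata_pooled(self):
        strata = [0] * 47 + [7, 7, 8]  # strata smaller than k merge
        plan = make_folds(self._pairs(50), strata, k=5, seed=0)
        assert plan.k == 5

    def test_cold_start_smd_disjoint(self):
        pairs = [(f"s{i % 10}", f"b{j}") for i in range(10) for j in range(4)]
        plan = make_folds(pairs, [0] * len(pairs), k=5, seed=0, mode="cold_smd")
        for tr, te in plan.folds:
            tr_smd = {plan.pairs[i][0] for i in tr}
            te_smd = {plan.pairs[i][0] for i in te}
            assert not tr_smd & te_smd

    def test_k_larger_than_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self._pairs(3), [0, 0, 0], k=5)


class TestComputeMetrics:
    def test_hand_counts_single_class(self):
        # TP=2 FP=1 FN=1 TN=6 at threshold .5
        y = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0], float)[:, None]
        s = np.array([.9, .9, .9, .1, .1, .1, .1, .1, .1, .1])[:, None]
        m = compute_metrics(y, s)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.acc == pytest.approx(0.8)

    def test_perfect_scores_give_all_ones(self):
        y = (np.random.default_rng(0).random((30, 5)) < 0.4).astype(float)
        y[0, 0], y[1, 0] = 1.0, 0.0
        m = compute_metrics(y, y.copy())
        assert (m.acc, m.auc, m.aupr, m.f1, m.precision, m.recall) == (1,) * 6

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            y, s = random_fixture(rng)
            m = compute_metrics(y, s)
            auc, aupr = sweep_oracle(y, s)
            assert m.auc == pytest.approx(auc, abs=1e-10)
            assert m.aupr == pytest.approx(aupr, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y, s = random_fixture(rng)
        perm = rng.permutation(len(y))
        assert compute_metrics(y, s) == compute_metrics(y[perm], s[perm])

    def test_single_class_truth_reports_nan_auc(self, caplog):
        y = np.ones((5, 2))
        s = np.random.default_rng(0).random((5, 2))
        with caplog.at_level("WARNING"):
            m = compute_metrics(y, s)
        assert np.isnan(m.auc) and np.isnan(m.aupr)
        assert m.recall >= 0

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones((2, 1)), np.array([[1.5], [0.2]]))

    def test_macro_mode_averages_classes(self):
        rng = np.random.default_rng(2)
        y, s = random_fixture(rng, n=60, k=3)
        macro = compute_metrics(y, s, mode="macro")
        per_class = [
            compute_metrics(y[:, j:j + 1], s[:, j:j + 1]) for j in range(3)
        ]
        assert macro.acc == pytest.approx(np.mean([m.acc for m in per_class]))

    def test_top1_accuracy(self):
        y = label_matrix([(1,), (), (2,)], 3)
        s = np.array([[.1, .8, .1], [.9, .05, .05], [.2, .5, .3]])
        assert top1_accuracy(y, s) == pytest.approx(2 / 3)


class TestReportAggregation:
    def test_mean_is_arithmetic(self):
        r = MetricReport(folds=(
            Metrics(.8, .9, .7, .6, .5, .4), Metrics(.6, .7, .5, .4, .3, .2),
        ))
        expected = Metrics(.7, .8, .6, .5, .4, .3)
        for got, want in zip(
            r.mean.as_dict().values(), expected.as_dict().values()
        ):
            assert got == pytest.approx(want)


class TestAssembleDataset:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assemble_dataset({("s", "b"): (1,)}, [("s", "b")], 3)

    def test_labels_and_strata(self):
        pairs, Y, strata = assemble_dataset(
            {("s1", "b1"): (2,), ("s2", "b1"): (1, 2)}, [("s3", "b9")], 3
        )
        assert len(pairs) == 3
        assert Y.sum() == 4  # 1 + 2 event bits + 1 negative bit
        assert list(strata) == [2, 1, 0]


class TestRunCV:
    def test_report_bookkeeping_and_fold_hygiene(
        self, tiny_bundle, tiny_positive_map, tiny_unlabeled, tiny_universe
    ):
        from sbipred.pu_sampling import random_sample_negatives

        negatives = random_sample_negatives(
            tiny_unlabeled, len(tiny_positive_map), seed=0
        )
        pairs, Y, strata = assemble_dataset(
            tiny_positive_map, negatives, tiny_universe.catalog.n_classes
        )
        cfg = TrainConfig(max_epochs=4, patience=3, batch_size=32, seed=0)
        reports = run_cv(
            tiny_bundle, pairs, Y, strata, [("SPI_BPI",), ("SPI_BPI", "SSI_BBI")],
            train_config=cfg, k=5, seed=0,
        )
        assert set(reports) == {"SPI_BPI", "SPI_BPI+SSI_BBI"}
        for rep in reports.values():
            assert len(rep.folds) == 5
            for m in rep.folds:
                assert 0 <= m.aupr <= 1
        # determinism of the whole driver
        again = run_cv(
            tiny_bundle, pairs, Y, strata, [("SPI_BPI",)],
            train_config=cfg, k=5, seed=0,
        )
        assert again["SPI_BPI"] == reports["SPI_BPI"]
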