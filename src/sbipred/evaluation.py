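"""Cross-validation driver and the six evaluation metrics.

Performance is measured with stratified 5-fold cross-validation over drug
pairs (80% train / 20% test per fold; the report averages the folds) and
six metrics — ACC, AUC, AUPR, F1, precision, recall — micro-averaged over
the event classes: per-class indicator decisions at threshold 0.5 are
pooled into global TP/FP/TN/FN counts, the ROC area is the trapezoidal
area over the pooled score-label pairs, and the PR area is the
step-interpolated area (average precision). Macro averaging is available
behind a flag.

``run_cv`` trains each requested modality's sub-model once per fold and
caches its test-fold predictions, so evaluating many modality-subset
recipes (ablation tables) costs no extra training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold

from sbipred.features import FeatureBundle, apply_standardizer, fit_standardizer
from sbipred.model import (
    CNNEncoderSpec,
    SubModelSpec,
    TrainConfig,
    build_submodel,
    label_matrix,
    modality_input,
    predict_submodel,
    split_validation,
    train_submodel,
)

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class Metrics:
    """The six micro-averaged metrics of one evaluation."""

    acc: float
    auc: float
    aupr: float
    f1: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc, "AUC": self.auc, "AUPR": self.aupr,
            "F1": self.f1, "Pre": self.precision, "Rec": self.recall,
        }


@dataclass(frozen=True)
class MetricReport:
    """Per-fold metrics plus their arithmetic mean."""

    folds: tuple[Metrics, ...]

    @property
    def mean(self) -> Metrics:
        arrays = np.array(
            [[m.acc, m.auc, m.aupr, m.f1, m.precision, m.recall] for m in self.folds]
        )
        vals = arrays.mean(axis=0)
        return Metrics(*[float(v) for v in vals])


@dataclass(frozen=True)
class FoldPlan:
    """A k-fold partition of a pair list, stratified by event label."""

    pairs: tuple[Pair, ...]
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, test)
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(
    pairs: Sequence[Pair],
    strata: Sequence[int],
    k: int = 5,
    seed: int = 0,
    mode: str = "pair",
) -> FoldPlan:
    """Stratified random k-fold partition of drug pairs.

    ``strata`` is one integer label per pair (its primary event class);
    strata with fewer than ``k`` members are pooled into a single stratum
    so every fold remains constructible. ``mode="cold_smd"`` switches to
    SMD-disjoint folds (grouped by the small-molecule drug) for cold-start
    evaluation; the reference protocol is the default pair-level split.
    """
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds {len(pairs)} pairs")
    order = np.argsort([f"{s}\t{b}" for s, b in pairs])
    pairs_sorted = [pairs[i] for i in order]
    strata_arr = np.asarray([strata[i] for i in order])
    if mode == "cold_smd":
        groups = [s for s, _ in pairs_sorted]
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(np.zeros(len(pairs_sorted)), groups=groups)
    elif mode == "pair":
        vals, counts = np.unique(strata_arr, return_counts=True)
        rare = set(vals[counts < k])
        pooled = np.array([-1 if s in rare else s for s in strata_arr])
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(pooled)), pooled)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    folds = tuple(
        (tuple(int(i) for i in tr), tuple(int(i) for i in te)) for tr, te in splits
    )
    return FoldPlan(pairs=tuple(pairs_sorted), folds=folds, seed=seed)


def _micro_counts(y_true: np.ndarray, y_score: np.ndarray, threshold: float):
    pred = y_score >= threshold
    truth = y_true > 0
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return tp, fp, tn, fn


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def compute_metrics(
    y_true: np.ndarray,
    y_score: np.ndarray,
    mode: str = "micro",
    threshold: float = 0.5,
) -> Metrics:
    """The six metrics of one prediction set.

    ``y_true`` is the multi-hot label matrix, ``y_score`` the matching
    probability matrix. In micro mode all class indicators are pooled
    before computing each metric; in macro mode metrics are computed per
    class and averaged. A truth matrix containing a single class value
    leaves the ranking metrics undefined; they are reported as NaN with a
    warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_score.shape}")
    if np.any((y_score < 0) | (y_score > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if mode == "macro":
        per_class = [
            compute_metrics(y_true[:, j : j + 1], y_score[:, j : j + 1],
                            mode="micro", threshold=threshold)
            for j in range(y_true.shape[1])
        ]
        vals = np.array([[m.acc, m.auc, m.aupr, m.f1, m.precision, m.recall]
                         for m in per_class])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return Metrics(*[float(v) for v in np.nanmean(vals, axis=0)])
    if mode != "micro":
        raise ValueError(f"unknown averaging mode {mode!r}")

    flat_true = y_true.ravel()
    flat_score = y_score.ravel()
    tp, fp, tn, fn = _micro_counts(y_true, y_score, threshold)
    acc = _safe_div(tp + tn, tp + fp + tn + fn)
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * rec * pre, rec + pre)
    if flat_true.min() == flat_true.max():
        logger.warning("single-class truth: AUC/AUPR undefined, reported as NaN")
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(flat_true, flat_score))
        aupr = float(average_precision_score(flat_true, flat_score))
    return Metrics(acc=acc, auc=auc, aupr=aupr, f1=f1, precision=pre, recall=rec)


def top1_accuracy(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Fraction of pairs whose highest-scoring class is a true class —
    the subset-accuracy alternative to per-indicator micro ACC."""
    top = y_score.argmax(axis=1)
    return float(np.mean(y_true[np.arange(len(top)), top] > 0))


def assemble_dataset(
    positives: Mapping[Pair, tuple[int, ...]],
    negatives: Sequence[Pair],
    n_classes: int,
) -> tuple[list[Pair], np.ndarray, np.ndarray]:
    """Pairs, multi-hot labels, and stratification key of one training set.

    ``positives`` maps each positive pair to its event-id tuple; negatives
    get the class-0 label. Negatives must be disjoint from positives.
    """
    overlap = set(negatives) & set(positives)
    if overlap:
        raise ValueError(f"negatives overlap positives: {sorted(overlap)[:3]} ...")
    pairs = sorted(positives) + sorted(negatives)
    events = [positives[p] for p in sorted(positives)] + [() for _ in negatives]
    Y = label_matrix(events, n_classes)
    strata = np.array([evs[0] if evs else 0 for evs in events])
    return pairs, Y, strata


def run_cv(
    bundle: FeatureBundle,
    pairs: Sequence[Pair],
    Y: np.ndarray,
    strata: Sequence[int],
    recipes: Sequence[Sequence[str]],
    train_config: TrainConfig = TrainConfig(),
    k: int = 5,
    seed: int = 0,
    sub_spec: SubModelSpec | None = None,
    cnn_spec: CNNEncoderSpec = CNNEncoderSpec(),
    mode: str | tuple[str, ...] = "micro",
    max_folds: int | None = None,
) -> dict[str, MetricReport]:
    """Cross-validate every modality-subset recipe.

    Each distinct modality is trained once per fold on that fold's training
    pairs (with a stratified 10% validation split for early stopping) and
    its test predictions are cached; a recipe's prediction is the
    unweighted mean of its modalities' cached outputs. Returns one
    :class:`MetricReport` per recipe, keyed ``"+".join(recipe)``.

    ``max_folds`` caps how many of the k folds are actually trained and
    evaluated (e.g. ``max_folds=1`` gives a single 80/20 holdout while
    keeping the stratified fold construction). ``mode`` may be a tuple of
    averaging modes, in which case each report key is suffixed ``|<mode>``
    and the sub-models are still trained only once.
    """
    n_classes = Y.shape[1]
    if sub_spec is None:
        sub_spec = SubModelSpec(n_classes=n_classes)
    elif sub_spec.n_classes != n_classes:
        raise ValueError("sub_spec.n_classes disagrees with the label matrix")
    needed = sorted({m for r in recipes for m in r})
    plan = make_folds(pairs, strata, k=k, seed=seed)
    pair_arr = list(plan.pairs)
    reorder = [pairs.index(p) for p in pair_arr]
    Y = Y[reorder]

    fold_metrics: dict[str, list[Metrics]] = {"+".join(r): [] for r in recipes}
    use_folds = plan.folds if max_folds is None else plan.folds[:max_folds]
    for f, (tr, te) in enumerate(use_folds):
        tr, te = np.array(tr), np.array(te)
        assert not set(tr) & set(te)
        preds: dict[str, np.ndarray] = {}
        tr_sub, val = split_validation(
            len(tr), Y[tr], TrainConfig().val_fraction, seed=seed + f
        )
        for modality in needed:
            x_all = modality_input(bundle, pair_arr, modality)
            if not isinstance(x_all, tuple):  # z-score on train-fold stats
                x_all = apply_standardizer(x_all, fit_standardizer(x_all[tr]))
            take = (lambda idx: tuple(a[idx] for a in x_all)) if isinstance(
                x_all, tuple) else (lambda idx: x_all[idx])
            if modality == "CNN":
                net = build_submodel(
                    "CNN",
                    n_tokens_smd=len(bundle.vocab_smiles) + 2,
                    n_tokens_biod=len(bundle.vocab_aa) + 2,
                    spec=sub_spec, cnn_spec=cnn_spec, seed=seed + f,
                )
            else:
                dim = (x_all.shape[1])
                net = build_submodel(
                    modality, pair_dim=dim, spec=sub_spec, seed=seed + f
                )
            train_submodel(
                net, take(tr[tr_sub]), Y[tr[tr_sub]], take(tr[val]), Y[tr[val]],
                config=train_config,
            )
            preds[modality] = predict_submodel(net, take(te))
        for recipe in recipes:
            key = "+".join(recipe)
            mean_pred = np.mean([preds[m] for m in recipe], axis=0)
            fold_metrics[key].append(
                compute_metrics(Y[te], mean_pred, mode=mode)
                if isinstance(mode, str)
                else tuple(compute_metrics(Y[te], mean_pred, mode=m) for m in mode)
            )
        logger.info("fold %d/%d done (%d test pairs)", f + 1, plan.k, len(te))
    if isinstance(mode, str):
        return {k: MetricReport(folds=tuple(ms)) for k, ms in fold_metrics.items()}
    return {
        f"{k}|{m}": MetricReport(folds=tuple(t[i] for t in ms))
        for k, ms in fold_metrics.items()
        for i, m in enumerate(mode)
    }
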