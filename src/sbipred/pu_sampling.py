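"""Positive-unlabeled undersampling of the candidate pair space.

Interaction corpora record only positive pairs; everything else is
*unlabeled*, a mix of true negatives and not-yet-annotated positives.
Training against randomly drawn unlabeled pairs therefore plants false
negatives. This module implements a three-step undersampling procedure:

1. Draw ``|P|`` unlabeled pairs uniformly as temporary negatives, train a
   decision tree of positives vs the draw on the pair features, and score
   every unlabeled pair with the tree's positive-class probability.
2. Repeat ``T`` times; the per-pair mean score is the confidence that the
   pair is a hidden positive.
3. Discard pairs whose mean score reaches the elimination threshold θ
   (default 1.0: unanimously positive-looking) and keep the ``n``
   lowest-scoring survivors as the high-confidence negative set.

The selected set is balanced against the positives (``n = |P|`` by
default) and, on data with planted hidden positives, contains measurably
fewer of them than a uniform random draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from sbipred.features import VECTOR_MODALITIES, FeatureBundle, pu_feature_matrix

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class PUConfig:
    """Settings of the PU scorer.

    ``T`` controls the variance of the mean score (decaying as 1/T); 50
    repetitions stabilize the score ranking at desk scale. ``theta`` is the
    elimination threshold on the mean score; 1.0 removes only pairs every
    tree called positive.
    """

    T: int = 50
    max_depth: int | None = 8
    min_samples_leaf: int = 5
    theta: float = 1.0
    feature_recipe: tuple[str, ...] = VECTOR_MODALITIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")


@dataclass(frozen=True)
class ScoreTable:
    """Mean PU confidence per unlabeled pair."""

    pairs: tuple[Pair, ...]
    mean_score: np.ndarray
    n_evals: int

    def as_dict(self) -> dict[Pair, float]:
        return {p: float(s) for p, s in zip(self.pairs, self.mean_score)}

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["smd_id", "biod_id", "mean_score", "n_evals"])
            for (s, b), m in zip(self.pairs, self.mean_score):
                w.writerow([s, b, f"{m:.10g}", self.n_evals])


def score_unlabeled(
    positives: Sequence[Pair],
    unlabeled: Sequence[Pair],
    features,
    config: PUConfig = PUConfig(),
) -> ScoreTable:
    """Mean positive-class probability of every unlabeled pair over ``T``
    balanced decision trees.

    Each repetition draws ``|P|`` unlabeled pairs without replacement as
    temporary negatives (draws are independent across repetitions), fits a
    tree on the configured concatenated pair features, and scores all of
    ``U``. Fully seeded: identical inputs and config give an identical
    table.

    ``features`` is a :class:`~sbipred.features.FeatureBundle` (featurized
    per ``config.feature_recipe``) or any callable mapping a pair list to a
    feature matrix.
    """
    P = sorted(positives)
    U = sorted(unlabeled)
    if len(P) < 2:
        raise ValueError("need at least 2 positive pairs")
    if len(U) < len(P):
        raise ValueError(f"|U|={len(U)} < |P|={len(P)}: cannot draw balanced sets")
    if isinstance(features, FeatureBundle):
        featurize = lambda pairs: pu_feature_matrix(
            features, pairs, config.feature_recipe
        )
    else:
        featurize = features
    X_p = featurize(P)
    X_u = featurize(U)
    spread = np.vstack([X_p, X_u])
    if np.all(spread.max(axis=0) - spread.min(axis=0) == 0):
        raise ValueError("degenerate features: all columns constant")

    rng = np.random.default_rng(config.seed)
    y = np.concatenate([np.ones(len(P)), np.zeros(len(P))])
    total = np.zeros(len(U))
    for t in range(config.T):
        draw = rng.choice(len(U), size=len(P), replace=False)
        X_t = np.vstack([X_p, X_u[draw]])
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X_t, y)
        proba = tree.predict_proba(X_u)
        pos_col = int(np.argmax(tree.classes_ == 1.0))
        total += proba[:, pos_col]
    return ScoreTable(
        pairs=tuple(U), mean_score=total / config.T, n_evals=config.T
    )


def select_negatives(
    scores: ScoreTable, n: int, theta: float = 1.0
) -> list[Pair]:
    """Keep the ``n`` lowest-scoring pairs after eliminating those whose
    mean score reaches ``theta``.

    Ties in score break lexicographically on the pair id, so the output is
    a deterministic function of (table, n, theta).
    """
    surviving = [
        (float(s), p) for p, s in zip(scores.pairs, scores.mean_score) if s < theta
    ]
    eliminated = len(scores.pairs) - len(surviving)
    logger.info(
        "PU selection: %d pairs eliminated at theta=%g, %d surviving",
        eliminated, theta, len(surviving),
    )
    if n > len(surviving):
        raise ValueError(
            f"requested {n} negatives but only {len(surviving)} pairs survive "
            f"theta={theta} (shortfall {n - len(surviving)})"
        )
    surviving.sort(key=lambda t: (t[0], t[1]))
    return [p for _, p in surviving[:n]]


def random_sample_negatives(
    unlabeled: Sequence[Pair], n: int, seed: int = 0
) -> list[Pair]:
    """Uniform draw of ``n`` unlabeled pairs without replacement — the
    traditional negative-sampling baseline."""
    U = sorted(unlabeled)
    if n > len(U):
        raise ValueError(f"cannot draw {n} from {len(U)} unlabeled pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(U), size=n, replace=False)
    return [U[i] for i in sorted(idx)]
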