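"""Reference experiment harnesses on synthetic universes.

These drive the three headline study designs at desk scale:

- :func:`pu_vs_random` — contamination of the selected negative set by
  planted hidden positives, and downstream test AUPR, under PU-sampling
  versus uniform random sampling (the sampling-comparison design);
- :func:`ablation` — mean test AUPR of each single-modality sub-model
  versus the four-modality average ensemble (the feature-ablation design);
- :func:`null_calibration` — chance-level check on signal-free universes.

Problem sizes are the generator defaults (120 SMDs x 30 BioDs); training
uses a single stratified 80/20 holdout per seed and a compact CNN encoder
so a full multi-seed harness runs in minutes on one core. Both the
per-class (macro) and pooled (micro) AUC are reported by the null harness:
under label independence the per-class AUC sits at chance while the pooled
AUC reflects class-prior calibration only, so the former is the
calibration statistic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from sbipred.evaluation import assemble_dataset, run_cv
from sbipred.features import MODALITIES, build_feature_bundle
from sbipred.model import CNNEncoderSpec, TrainConfig
from sbipred.pu_sampling import (
    PUConfig,
    random_sample_negatives,
    score_unlabeled,
    select_negatives,
)
from sbipred.synthetic_data import SimConfig, generate_universe

logger = logging.getLogger(__name__)

#: Desk-scale training settings used by the harnesses.
HARNESS_TRAIN = dict(max_epochs=35, patience=8, batch_size=128)
HARNESS_CNN = CNNEncoderSpec(base_filters=8, embed_width=24)
HARNESS_FEATURES = dict(smd_max_len=96, biod_max_len=100, pca_k=64)


def _prepare(sim: SimConfig):
    """Generate one universe and its derived artifacts."""
    universe, hidden, _ = generate_universe(sim)
    bundle = build_feature_bundle(universe, seed=sim.seed, **HARNESS_FEATURES)
    positives: dict = {}
    for q in universe.quaternaries:
        eid = universe.catalog.event_id(q.mechanism, q.action)
        positives.setdefault((q.drug_a, q.drug_b), set()).add(eid)
    positives = {k: tuple(sorted(v)) for k, v in positives.items()}
    all_pairs = {(s, b) for s in universe.smd_ids for b in universe.biod_ids}
    unlabeled = sorted(all_pairs - set(positives))
    return universe, hidden, bundle, positives, unlabeled


def _holdout_report(universe, bundle, positives, negatives, recipes, seed,
                    mode="micro"):
    pairs, Y, strata = assemble_dataset(
        positives, negatives, universe.catalog.n_classes
    )
    return run_cv(
        bundle, pairs, Y, strata, recipes,
        train_config=TrainConfig(seed=seed, **HARNESS_TRAIN),
        k=5, seed=seed, cnn_spec=HARNESS_CNN, mode=mode, max_folds=1,
    )


def pu_vs_random(
    seeds: Sequence[int],
    sim: SimConfig = SimConfig(),
    pu_T: int = 50,
    downstream_recipe: tuple[str, ...] = ("FP_EMB",),
) -> dict:
    """PU-sampling versus random sampling on universes with hidden positives.

    For each seed: generate a universe, select a balanced negative set with
    each strategy, count how many planted hidden positives each set
    contains, and train/evaluate the downstream recipe on each. Returns
    per-seed counts and AUPRs plus their means.
    """
    out = {"hidden_in_pu": [], "hidden_in_random": [],
           "aupr_pu": [], "aupr_random": [], "n_hidden": [], "n_negatives": []}
    key = "+".join(downstream_recipe)
    for seed in seeds:
        cfg = dataclasses.replace(sim, seed=seed)
        universe, hidden, bundle, positives, unlabeled = _prepare(cfg)
        P = sorted(positives)
        table = score_unlabeled(P, unlabeled, bundle, PUConfig(T=pu_T, seed=seed))
        neg_pu = select_negatives(table, len(P))
        neg_rd = random_sample_negatives(unlabeled, len(P), seed=seed)
        out["hidden_in_pu"].append(len(hidden & set(neg_pu)))
        out["hidden_in_random"].append(len(hidden & set(neg_rd)))
        out["n_hidden"].append(len(hidden))
        out["n_negatives"].append(len(P))
        for label, neg in (("aupr_pu", neg_pu), ("aupr_random", neg_rd)):
            rep = _holdout_report(
                universe, bundle, positives, neg, [downstream_recipe], seed
            )
            out[label].append(rep[key].mean.aupr)
        logger.info(
            "seed %d: hidden in PU=%d, random=%d; AUPR PU=%.3f random=%.3f",
            seed, out["hidden_in_pu"][-1], out["hidden_in_random"][-1],
            out["aupr_pu"][-1], out["aupr_random"][-1],
        )
    for k in ("hidden_in_pu", "hidden_in_random", "aupr_pu", "aupr_random"):
        out[f"mean_{k}"] = float(np.mean(out[k]))
    return out


def ablation(
    seeds: Sequence[int],
    sim: SimConfig = SimConfig(),
) -> dict[str, list[float]]:
    """Per-seed test AUPR of each single modality and the full ensemble,
    trained on random-sampled balanced negatives."""
    recipes = [(m,) for m in MODALITIES] + [tuple(MODALITIES)]
    results: dict[str, list[float]] = {"+".join(r): [] for r in recipes}
    for seed in seeds:
        cfg = dataclasses.replace(sim, seed=seed)
        universe, _, bundle, positives, unlabeled = _prepare(cfg)
        negatives = random_sample_negatives(unlabeled, len(positives), seed=seed)
        reports = _holdout_report(
            universe, bundle, positives, negatives, recipes, seed
        )
        for k, rep in reports.items():
            results[k].append(rep.mean.aupr)
        logger.info("seed %d: %s", seed,
                    {k: round(v[-1], 3) for k, v in results.items()})
    return results


def null_calibration(
    seeds: Sequence[int],
    sim: SimConfig = SimConfig(),
    recipe: tuple[str, ...] = ("SPI_BPI",),
) -> dict[str, list[float]]:
    """AUC of a sub-model trained on signal-free universes.

    Returns per-seed per-class (macro) AUC — chance-level 0.5 under the
    null — and pooled (micro) AUC, which under the null reflects only how
    well the model reproduces the class priors.
    """
    cfg0 = dataclasses.replace(sim, signal_strength=0.0)
    key = "+".join(recipe)
    out: dict[str, list[float]] = {"macro_auc": [], "micro_auc": []}
    for seed in seeds:
        cfg = dataclasses.replace(cfg0, seed=seed)
        universe, _, bundle, positives, unlabeled = _prepare(cfg)
        negatives = random_sample_negatives(unlabeled, len(positives), seed=seed)
        rep = _holdout_report(
            universe, bundle, positives, negatives, [recipe], seed,
            mode=("macro", "micro"),
        )
        out["macro_auc"].append(rep[f"{key}|macro"].mean.auc)
        out["micro_auc"].append(rep[f"{key}|micro"].mean.auc)
        logger.info("seed %d: macro AUC %.3f, micro AUC %.3f",
                    seed, out["macro_auc"][-1], out["micro_auc"][-1])
    return out
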