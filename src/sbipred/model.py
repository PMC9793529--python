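"""The four per-modality sub-models and their average-fused ensemble.

Each sub-model is a multi-label classifier over the event classes
(class 0 = no interaction, classes ``1..K`` = event types; the reference
configuration has 49 outputs). Three sub-models consume precomputed pair
vectors (fingerprint+embedding, SPI/BPI topology, SSI/BBI topology) through
a ``512 -> 256 -> n_classes`` fully connected head with ReLU activations,
dropout 0.3 on hidden units, and sigmoid outputs — sigmoid rather than
softmax because a pair may carry several events at once. The fourth
sub-model first encodes the raw SMILES and amino-acid token sequences with
two independent three-layer 1D-CNN blocks (kernel length 8; filter counts
f, 2f, 3f; global max pooling), concatenates the two pooled outputs, and
feeds the same head.

The ensemble prediction is the unweighted arithmetic mean of the fitted
sub-models' 49-dimensional sigmoid outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from sbipred import nn
from sbipred.features import MODALITIES, FeatureBundle, pair_tokens, pair_vectors

#: Reference output dimension: 1 negative class + 48 event types.
DEFAULT_N_CLASSES = 49


@dataclass(frozen=True)
class CNNEncoderSpec:
    """One 1D-CNN sequence encoder: three convolutions with filter counts
    (f, 2f, 3f), kernel length 8, then global max pooling (output 3f)."""

    kernel: int = 8
    base_filters: int = 64
    embed_width: int = 128

    @property
    def filters(self) -> tuple[int, int, int]:
        return (self.base_filters, 2 * self.base_filters, 3 * self.base_filters)

    @property
    def pooled_dim(self) -> int:
        return 3 * self.base_filters


@dataclass(frozen=True)
class SubModelSpec:
    """The shared classifier head: hidden 512 -> hidden 256 -> output."""

    hidden: tuple[int, int] = (512, 256)
    n_classes: int = DEFAULT_N_CLASSES
    dropout: float = 0.3


@dataclass(frozen=True)
class TrainConfig:
    """Adam training schedule.

    The default learning rate is 1e-3; the reference configuration's
    printed 0.3 remains selectable. Early stopping watches the validation
    loss with patience 10 and restores the best weights.
    """

    lr: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 256
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")


def label_matrix(
    event_ids: Sequence[tuple[int, ...]], n_classes: int
) -> np.ndarray:
    """Multi-hot event label vectors.

    ``event_ids[i]`` is the tuple of event ids of pair i (empty for a
    negative pair). Negative pairs get exactly bit 0; positive pairs get
    one bit per event in ``1..K`` and bit 0 unset.
    """
    Y = np.zeros((len(event_ids), n_classes))
    for i, evs in enumerate(event_ids):
        if evs:
            for e in evs:
                if not 1 <= e < n_classes:
                    raise ValueError(f"event id {e} outside 1..{n_classes - 1}")
                Y[i, e] = 1.0
        else:
            Y[i, 0] = 1.0
    return Y


def _encoder(spec: CNNEncoderSpec, n_tokens: int, rng: np.random.Generator) -> nn.Sequential:
    f1, f2, f3 = spec.filters
    return nn.Sequential([
        nn.Embedding(n_tokens, spec.embed_width, rng),
        nn.Conv1D(spec.embed_width, f1, spec.kernel, rng),
        nn.ReLU(),
        nn.Conv1D(f1, f2, spec.kernel, rng),
        nn.ReLU(),
        nn.Conv1D(f2, f3, spec.kernel, rng),
        nn.ReLU(),
        nn.GlobalMaxPool(),
    ])


def _head(n_in: int, spec: SubModelSpec, rng: np.random.Generator) -> list[nn.Layer]:
    h1, h2 = spec.hidden
    return [
        nn.Dense(n_in, h1, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout, rng),
        nn.Dense(h1, h2, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout, rng),
        nn.Dense(h2, spec.n_classes, rng),
    ]


def build_submodel(
    modality: str,
    *,
    pair_dim: int | None = None,
    n_tokens_smd: int | None = None,
    n_tokens_biod: int | None = None,
    spec: SubModelSpec = SubModelSpec(),
    cnn_spec: CNNEncoderSpec = CNNEncoderSpec(),
    seed: int = 0,
) -> nn.Layer:
    """Build one trainable sub-model.

    For the ``CNN`` modality pass the two token-vocabulary sizes (including
    padding and unknown indices); for vector modalities pass ``pair_dim``,
    the length of the concatenated (SMD, BioD) pair vector.
    """
    rng = np.random.default_rng(seed)
    if modality == "CNN":
        if n_tokens_smd is None or n_tokens_biod is None:
            raise ValueError("CNN modality needs both token-vocabulary sizes")
        branches = nn.BranchConcat([
            _encoder(cnn_spec, n_tokens_smd, rng),
            _encoder(cnn_spec, n_tokens_biod, rng),
        ])
        head = _head(2 * cnn_spec.pooled_dim, spec, rng)
        return nn.Sequential([branches] + head)
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if pair_dim is None:
        raise ValueError(f"{modality} modality needs pair_dim")
    return nn.Sequential(_head(pair_dim, spec, rng))


def modality_input(
    bundle: FeatureBundle, pairs: Sequence[tuple[str, str]], modality: str
):
    """The sub-model input for a pair list: a (tokens, tokens) tuple for
    CNN, a concatenated vector matrix otherwise."""
    if modality == "CNN":
        return pair_tokens(bundle, pairs)
    return pair_vectors(bundle, pairs, modality)


def train_submodel(
    net: nn.Layer,
    x_train,
    y_train: np.ndarray,
    x_val,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> nn.History:
    """Fit one sub-model; early stopping restores best-validation weights."""
    return nn.fit(
        net, x_train, y_train, x_val, y_val,
        lr=config.lr, max_epochs=config.max_epochs, patience=config.patience,
        batch_size=config.batch_size, seed=config.seed,
    )


def split_validation(
    n: int, y: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/validation index split for early stopping."""
    rng = np.random.default_rng(seed)
    strata = y.argmax(axis=1)
    val_idx: list[int] = []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        members = members[rng.permutation(len(members))]
        k = max(1, round(val_fraction * len(members))) if len(members) > 1 else 0
        val_idx.extend(members[:k])
    val = np.array(sorted(val_idx), dtype=int)
    train = np.setdiff1d(np.arange(n), val)
    return train, val


def predict_submodel(net: nn.Layer, x) -> np.ndarray:
    return nn.predict_proba(net, x)


def predict_ensemble(
    models: Mapping[str, nn.Layer],
    inputs: Mapping[str, object],
    allow_subset: bool = False,
) -> np.ndarray:
    """Average the sigmoid outputs of the fitted sub-models.

    All four modalities are required unless ``allow_subset`` is set (needed
    for ablation experiments on modality subsets).
    """
    missing = [m for m in MODALITIES if m not in models]
    if missing and not allow_subset:
        raise ValueError(
            f"missing modalities {missing}; pass allow_subset=True for ablations"
        )
    if not models:
        raise ValueError("no sub-models given")
    outs = [nn.predict_proba(net, inputs[m]) for m, net in sorted(models.items())]
    shapes = {o.shape for o in outs}
    if len(shapes) != 1:
        raise ValueError(f"sub-models disagree on output shape: {shapes}")
    return np.mean(outs, axis=0)
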