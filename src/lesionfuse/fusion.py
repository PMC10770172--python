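"""Deck-two CNN, 64-unit bottleneck extraction, and feature fusion.

Deck two is the feature-engineering CNN: four convolutions (32, 64, 128, 256
filters of 3x3), three 2x2 max pools, then a dense stack 256-128-64-32-2
ending in a 2-unit sigmoid head, trained with Adamax on binary cross-entropy.
The activations of the 64-unit dense layer (post-ReLU, hence non-negative)
are the learned "bottleneck" features.

Fusion concatenates, in a fixed persisted order,

    core68:  [bn_00..bn_63, A, B, C, D]                      -> 68 values
    extended: [bn_00..bn_63, A, B, C, D, E, S_Flag1..S_Flag3] -> 72 values

The with/without-flag ablation toggles exactly the three flag columns, so an
extended vector with its flag (and E) columns dropped reproduces the core68
vector bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .errors import InvalidArchitectureError, InvalidInputError, InvalidModelError

CLINICAL_COLS = ["A", "B", "C", "D"]
EXTENDED_COLS = ["A", "B", "C", "D", "E", "S_Flag1", "S_Flag2", "S_Flag3"]
FLAG_COLS = ["S_Flag1", "S_Flag2", "S_Flag3"]
BN_COLS = [f"bn_{i:02d}" for i in range(64)]


def build_deck_two_cnn(input_size: int = 32, seed: int = 0) -> nn.Sequential:
    """The deck-two stack per its printed layer table."""
    rng = np.random.default_rng(seed)
    size = int(input_size)
    layers = []
    ch = 3
    plan = [("conv", 32), ("conv", 64), ("pool", None), ("conv", 128),
            ("pool", None), ("conv", 256), ("pool", None)]
    for kind, filters in plan:
        if kind == "conv":
            layers += [nn.Conv2D(ch, filters, 3, rng), nn.ReLU()]
            ch = filters
            size -= 2
        else:
            layers.append(nn.MaxPool2())
            size = nn.pool_output_size(size, 2, 2)
        if size < 1:
            raise InvalidArchitectureError(
                f"input size {input_size} too small for the deck-two stack"
            )
    flat = size * size * ch
    layers.append(nn.Flatten())
    for units in (256, 128, 64, 32):
        layers += [nn.Dense(flat if units == 256 else prev, units, rng), nn.ReLU()]
        prev = units
    layers += [nn.Dense(32, 2, rng), nn.Sigmoid()]
    return nn.Sequential(layers, head="sigmoid")


def train_deck_two(model, samples, *, epochs: int = 150, batch_size: int = 40,
                   learning_rate: float = 0.001, seed: int = 0, images=None):
    """Adamax / binary cross-entropy; returns per-epoch loss history."""
    from .deck_one import train_baseline  # same contract, different optimiser

    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        from .errors import DegenerateTrainingError

        raise DegenerateTrainingError("training requires both classes present")
    if images is None:
        images = np.stack([s.image for s in samples]).astype(float) / 255.0
    return nn.train(model, images, labels, epochs=epochs, batch_size=batch_size,
                    learning_rate=learning_rate, seed=seed, optimizer="adamax")


def _bottleneck_index(model) -> int:
    """Index of the ReLU following the 64-unit dense layer."""
    for i, layer in enumerate(model.layers[:-1]):
        if isinstance(layer, nn.Dense) and layer.units == 64 \
                and isinstance(model.layers[i + 1], nn.ReLU):
            return i + 1
    raise InvalidModelError("model has no 64-unit dense layer to extract from")


def extract_bottleneck(model, images) -> np.ndarray:
    """Post-ReLU activations of the 64-unit dense layer.

    ``images`` is one HxWx3 array or a batch NHWC (both [0,1] float or uint8);
    returns (64,) or (n, 64).
    """
    stop = _bottleneck_index(model)
    x = np.asarray(images, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.max() > 1.5:
        x = x / 255.0
    for layer in model.layers[: stop + 1]:
        x = layer.forward(x, training=False)
    return x[0] if single else x


@dataclass
class FusedFeatureVector:
    values: np.ndarray
    mode: str  # "core68" | "extended"

    @property
    def columns(self):
        return BN_COLS + (CLINICAL_COLS if self.mode == "core68" else EXTENDED_COLS)


def fuse_features(bottleneck, abcde, flags=None, mode: str = "core68") -> FusedFeatureVector:
    """Concatenate bottleneck + clinical (+ flag) features in the fixed order."""
    bn = np.asarray(bottleneck, dtype=float).ravel()
    if bn.shape != (64,):
        raise InvalidInputError(f"bottleneck must have 64 values, got {bn.shape}")
    clin = np.array([abcde.A, abcde.B, abcde.C, abcde.D], dtype=float)
    if mode == "core68":
        values = np.concatenate([bn, clin])
    elif mode == "extended":
        if flags is None:
            raise InvalidInputError("extended mode requires flag features")
        s2 = flags.S_Flag2 if np.isfinite(flags.S_Flag2) else 1e6  # inf sentinel capped
        extra = np.array([abcde.E, flags.S_Flag1, s2, flags.S_Flag3], dtype=float)
        values = np.concatenate([bn, clin, extra])
    else:
        raise InvalidInputError(f"unknown fusion mode {mode!r}")
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("fused vector contains non-finite values")
    return FusedFeatureVector(values=values, mode=mode)


def drop_flag_columns(vector: FusedFeatureVector) -> FusedFeatureVector:
    """Project an extended vector onto core68 (ablation consistency)."""
    if vector.mode != "extended":
        raise InvalidInputError("only extended vectors carry flag columns")
    return FusedFeatureVector(values=vector.values[:68], mode="core68")


def feature_table(sample_ids, vectors, labels) -> pd.DataFrame:
    """Assemble the fused-feature table with its persisted column order."""
    vectors = list(vectors)
    if not vectors:
        raise InvalidInputError("no fused vectors supplied")
    mode = vectors[0].mode
    if any(v.mode != mode for v in vectors):
        raise InvalidInputError("mixed fusion modes in one table")
    df = pd.DataFrame([v.values for v in vectors], columns=vectors[0].columns)
    df.insert(0, "sample_id", list(sample_ids))
    df["label"] = list(labels)
    return df


def write_feature_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False)  # full repr precision: round-trips to < 1e-9


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
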