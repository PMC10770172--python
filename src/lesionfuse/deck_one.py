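"""Deck-one baseline CNN, confidence scoring, and the Baseline Separated
Channel (BSC) triage.

The baseline deck is a small four-conv-block CNN (15 filters of 3x3 per conv,
batch norm, three 2x2 max pools, 0.2 dropout, a 100-unit dense layer and a
2-unit softmax head) trained with Adam (lr 0.001) on binary cross-entropy.

The *confidence factor* (also called the intra-class variance score) of a
sample is |p_benign - p_malignant|.  Samples whose confidence falls below the
threshold j = 0.999995 are routed to the BSC — the hard-sample channel that
the second deck and the fused-feature classifiers handle — while confident
samples are retained and classified by this deck alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import (
    DegenerateTrainingError,
    EmptyPartitionError,
    InvalidInputError,
    UndefinedRatioError,
)

BSC_THRESHOLD = 0.999995  # j; k (the upper bound) is 1


@dataclass(frozen=True)
class ProbabilityPair:
    p_benign: float
    p_malignant: float

    def validate(self, tol=1e-6):
        if not (0 <= self.p_benign <= 1 and 0 <= self.p_malignant <= 1):
            raise InvalidInputError(f"probabilities outside [0,1]: {self}")
        if abs(self.p_benign + self.p_malignant - 1.0) > tol:
            raise InvalidInputError(f"probabilities do not sum to 1: {self}")


@dataclass(frozen=True)
class ConfidenceRecord:
    sample_id: str
    probabilities: ProbabilityPair
    confidence: float
    predicted: int
    truth: int
    tie: bool = False  # p_benign == p_malignant exactly


@dataclass
class BscPartition:
    retained: list  # sample_ids with confidence >= j
    bsc: list  # sample_ids with confidence < j
    threshold_j: float
    threshold_k: float = 1.0


def build_baseline_cnn(input_size: int = 32, seed: int = 0) -> nn.Sequential:
    """The deck-one stack: [conv15-BN, conv15-BN, pool, drop] x structure with
    four convs and three pools, then flatten -> dense(100) -> drop -> dense(2)
    softmax.  Raises if ``input_size`` cannot survive all pooling stages."""
    rng = np.random.default_rng(seed)
    size = int(input_size)

    def conv_out(s):
        return s - 2  # valid 3x3

    def pool_out(s):
        return nn.pool_output_size(s, 2, 2)

    layers = []
    drop_rng = np.random.default_rng(rng.integers(2**31))
    ch = 3
    plan = ["conv", "bn", "conv", "bn", "pool", "drop",
            "conv", "bn", "pool", "drop", "conv", "bn", "pool"]
    for item in plan:
        if item == "conv":
            layers += [nn.Conv2D(ch, 15, 3, rng), ]
            ch = 15
            size = conv_out(size)
        elif item == "bn":
            layers += [nn.BatchNorm(ch), nn.ReLU()]
        elif item == "pool":
            layers.append(nn.MaxPool2())
            size = pool_out(size)
        elif item == "drop":
            layers.append(nn.Dropout(0.2, drop_rng))
        if size < 1:
            from .errors import InvalidArchitectureError

            raise InvalidArchitectureError(
                f"input size {input_size} too small for the deck-one pooling stages"
            )
    flat = size * size * 15
    layers += [
        nn.Flatten(),
        nn.Dense(flat, 100, rng),
        nn.ReLU(),
        nn.Dropout(0.2, drop_rng),
        nn.Dense(100, 2, rng),
        nn.Softmax(),
    ]
    return nn.Sequential(layers, head="softmax")


def train_baseline(model, samples, *, epochs: int = 50, batch_size: int = 40,
                   learning_rate: float = 0.001, seed: int = 0, images=None):
    """Adam / binary cross-entropy training; returns per-epoch loss history.

    ``samples`` is a sequence of LabeledSample; pre-resized float image arrays
    can be supplied via ``images`` (NHWC, [0,1]) to skip rescaling.
    """
    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise DegenerateTrainingError("training requires both classes present")
    if images is None:
        images = np.stack([s.image for s in samples]).astype(float) / 255.0
    return nn.train(model, images, labels, epochs=epochs, batch_size=batch_size,
                    learning_rate=learning_rate, seed=seed, optimizer="adam")


def confidence_score(probabilities: ProbabilityPair) -> float:
    """|p_benign - p_malignant|, the confidence factor in [0, 1]."""
    probabilities.validate()
    return abs(probabilities.p_benign - probabilities.p_malignant)


def predict_records(model, samples, images=None) -> list:
    """Forward-pass every sample and build ConfidenceRecords.

    A 0.5/0.5 tie predicts benign and flags the record (ties are maximally
    low-confidence and always routed to the BSC anyway).
    """
    if images is None:
        images = np.stack([s.image for s in samples]).astype(float) / 255.0
    probs = model.predict_proba(images)
    records = []
    for s, (pb, pm) in zip(samples, probs):
        pair = ProbabilityPair(float(pb), float(pm))
        tie = pb == pm
        records.append(
            ConfidenceRecord(
                sample_id=s.sample_id,
                probabilities=pair,
                confidence=confidence_score(pair),
                predicted=0 if tie else int(pm > pb),
                truth=s.label,
                tie=bool(tie),
            )
        )
    return records


def segregate_bsc(records, j: float = BSC_THRESHOLD) -> BscPartition:
    """Partition records: confidence < j goes to the BSC, the rest are
    retained (a confidence of exactly j is retained — strict less-than).
    Input order is preserved within each side."""
    records = list(records)
    if not records:
        raise EmptyPartitionError("segregate_bsc requires at least one record")
    bsc = [r.sample_id for r in records if r.confidence < j]
    retained = [r.sample_id for r in records if r.confidence >= j]
    return BscPartition(retained=retained, bsc=bsc, threshold_j=j)


def error_ratio(records, lo: float, hi: float) -> float:
    """Misclassified fraction among records with confidence in [lo, hi)."""
    if not 0 <= lo < hi <= 1 + 1e-12:
        raise InvalidInputError(f"invalid band [{lo}, {hi})")
    band = [r for r in records if lo <= r.confidence < hi]
    if not band:
        raise UndefinedRatioError(f"no records with confidence in [{lo}, {hi})")
    wrong = sum(1 for r in band if r.predicted != r.truth)
    return wrong / len(band)


def error_ratio_curve(records, band_edges):
    """One row per band [e_i, e_{i+1}) (final band closed above).

    Returns a list of dicts ``{lo, hi, count, error_ratio, empty}``; empty
    bands are flagged with ``error_ratio=None`` rather than dropped.
    """
    edges = list(band_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidInputError("band edges must be strictly increasing")
    if edges[0] < 0 or edges[-1] > 1:
        raise InvalidInputError("band edges must lie within [0, 1]")
    rows = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        band = [r for r in records
                if lo <= r.confidence and (r.confidence <= hi if last else r.confidence < hi)]
        if band:
            wrong = sum(1 for r in band if r.predicted != r.truth)
            rows.append({"lo": lo, "hi": hi, "count": len(band),
                         "error_ratio": wrong / len(band), "empty": False})
        else:
            rows.append({"lo": lo, "hi": hi, "count": 0, "error_ratio": None, "empty": True})
    return rows


def write_records_csv(records, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "p_benign", "p_malignant", "confidence", "predicted", "truth"])
        for r in records:
            w.writerow([r.sample_id, repr(r.probabilities.p_benign),
                        repr(r.probabilities.p_malignant), repr(r.confidence),
                        r.predicted, r.truth])


def read_records_csv(path):
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pair = ProbabilityPair(float(row["p_benign"]), float(row["p_malignant"]))
            records.append(ConfidenceRecord(
                sample_id=row["sample_id"], probabilities=pair,
                confidence=float(row["confidence"]),
                predicted=int(row["predicted"]), truth=int(row["truth"]),
            ))
    return records
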