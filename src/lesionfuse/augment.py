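"""Rotation / horizontal-flip / Gaussian-noise augmentation and class balancing.

The default rotation mode uses the lossless 90-degree-multiple set
{180, 270, 360}; ``uniform_range`` draws a continuous angle in
[-rotation_range, +rotation_range] with interpolation.  Noise is zero-mean
Gaussian with variance ``noise_amount`` on [0,1]-scaled intensities (default
0.05), clipped back to the valid range.  Balancing always augments the
minority class up to parity — originals are never dropped — and every
synthetic sample records its source id and transform string.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .errors import InvalidInputError, UnbalanceableError
from .synthetic import LabeledSample


@dataclass(frozen=True)
class AugmentSpec:
    rotation_mode: str = "fixed_set"  # {180,270,360} rot90 multiples | "uniform_range"
    rotation_range: float = 45.0  # degrees, used by uniform_range
    noise_amount: float = 0.05  # Gaussian variance on the [0,1] scale
    flip: bool = True
    seed: int = 0

    def validate(self):
        if self.noise_amount < 0:
            raise InvalidInputError("noise_amount must be >= 0")
        if not 0 < self.rotation_range <= 180:
            raise InvalidInputError("rotation_range must lie in (0, 180]")
        if self.rotation_mode not in ("fixed_set", "uniform_range"):
            raise InvalidInputError(f"unknown rotation_mode {self.rotation_mode!r}")


def hflip(image) -> np.ndarray:
    """Horizontal mirror; an involution (applying twice restores the input)."""
    return np.asarray(image)[:, ::-1].copy()


def augment_image(image, spec: AugmentSpec, rng=None):
    """One random augmentation draw; returns (augmented uint8 image, transform tag)."""
    spec.validate()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected HxWx3 image, got {img.shape}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    tags = []
    if spec.rotation_mode == "fixed_set":
        deg = int(rng.choice([180, 270, 360]))
        out = np.rot90(img, k=deg // 90).copy()
        tags.append(f"rot{deg}")
    else:
        deg = float(rng.uniform(-spec.rotation_range, spec.rotation_range))
        out = nd_rotate(img, deg, axes=(0, 1), reshape=False, mode="nearest", order=1)
        tags.append(f"rot{deg:+.1f}")
    if spec.flip and rng.random() < 0.5:
        out = hflip(out)
        tags.append("hflip")
    if spec.noise_amount > 0:
        scaled = out.astype(float) / 255.0
        scaled += rng.normal(0.0, np.sqrt(spec.noise_amount), size=scaled.shape)
        out = np.clip(scaled, 0.0, 1.0) * 255.0
        tags.append(f"noise{spec.noise_amount:g}")
    return np.rint(out).astype(np.uint8), "+".join(tags)


def balance_dataset(samples, spec: AugmentSpec, axis: str = "label"):
    """Augment the minority group up to parity with the majority.

    ``axis="label"`` balances benign/malignant counts; ``axis="hairy"``
    balances hairy vs non-hairy samples (requires ground truth).  The output
    is a superset of the input; square images are required for the lossless
    fixed-set rotations.
    """
    spec.validate()
    samples = list(samples)

    def group_of(s):
        if axis == "label":
            return s.label
        if axis == "hairy":
            if s.ground_truth is None:
                raise InvalidInputError("hairy-axis balancing needs ground truth")
            return int(s.ground_truth.hair_mask.any())
        raise InvalidInputError(f"unknown balancing axis {axis!r}")

    groups = {0: [s for s in samples if group_of(s) == 0],
              1: [s for s in samples if group_of(s) == 1]}
    if not groups[0] or not groups[1]:
        raise UnbalanceableError(f"cannot balance: group counts "
                                 f"{{0: {len(groups[0])}, 1: {len(groups[1])}}}")
    n0, n1 = len(groups[0]), len(groups[1])
    if n0 == n1:
        return samples
    minority = groups[0] if n0 < n1 else groups[1]
    deficit = abs(n1 - n0)
    rng = np.random.default_rng(spec.seed)
    new = []
    for i in range(deficit):
        src = minority[i % len(minority)]
        img, tag = augment_image(src.image, spec, rng)
        new.append(LabeledSample(
            image=img, label=src.label,
            ground_truth=None,
            sample_id=f"{src.sample_id}_aug{i:04d}",
            source_id=src.sample_id, transform=tag,
        ))
    return samples + new
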