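"""The 'F' flag features: blue-white-veil (BWV) detection and the
circularity / ellipticity shape measures that disambiguate blue nevi.

A confluent grey-blue veil over a lesion is a strong melanoma marker, but a
blue nevus also shows a high blue-area fraction; very circular and/or
elliptical veiled lesions are therefore down-weighted via two shape scores.

    S_Flag1 = area(BWV) / area(lesion)                       in [0, 1]
    S_Flag2 = mean(d_n) / std(d_n)    d_n = centroid-to-boundary distances
    S_Flag3 = 16 pi^2 M   if M <= 1/(16 pi^2)   else   1/(16 pi^2 M)

where M is the second-order affine moment invariant
(mu20 * mu02 - mu11^2) / mu00^4, which equals exactly 1/(16 pi^2) for any
ellipse (so ellipses score S_Flag3 = 1) and 1/144 for a square
(S_Flag3 = 9/pi^2 ~ 0.912).  A variant invariant built from third/fourth
order moments is available behind ``literal=True`` but is degenerate for
symmetric shapes and not used by default.

BWV pixels are found by a per-pixel rule on two properties: F7, the
grey-blue pigment response (hue 185-255 deg, saturation 0.15-0.65, value
0.25-0.75 by default), and F13, an atypical-globules pigment-network
response (normalised local variance of a 5x5 Laplacian-of-Gaussian).  A
depth-<=3 Gini decision tree over (F7, F13, h, s, v) can be trained on
synthetic per-pixel labels and used in place of the fixed rule; the raw mask
is smoothed with a 3x3 majority filter either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv
from sklearn.tree import DecisionTreeClassifier

from .abcde import LesionSegmentation, segmentation_from_mask
from .errors import InvalidInputError, UndefinedScoreError
from .hair import to_grayscale

# default F7 grey-blue band (hue in degrees/360)
F7_HUE = (185.0 / 360.0, 255.0 / 360.0)
F7_SAT = (0.15, 0.65)
F7_VAL = (0.25, 0.75)
SIXTEEN_PI_SQ = 16.0 * np.pi**2


def pixel_features(image) -> np.ndarray:
    """Per-pixel feature stack (H, W, 5): F7, F13, hue, saturation, value."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected HxWx3 image, got {img.shape}")
    hsv = rgb2hsv(img)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    f7 = (
        (h >= F7_HUE[0]) & (h <= F7_HUE[1])
        & (s >= F7_SAT[0]) & (s <= F7_SAT[1])
        & (v >= F7_VAL[0]) & (v <= F7_VAL[1])
    ).astype(float)
    log = ndimage.gaussian_laplace(to_grayscale(img) / 255.0, sigma=1.0)
    local_var = ndimage.uniform_filter(log**2, size=5) - ndimage.uniform_filter(log, size=5) ** 2
    local_var = np.clip(local_var, 0.0, None)
    peak = local_var.max()
    f13 = local_var / peak if peak > 0 else local_var
    return np.stack([f7, f13, h, s, v], axis=-1)


class BwvDecisionTree:
    """Depth-limited Gini tree over per-pixel (F7, F13, h, s, v) features."""

    def __init__(self, max_depth: int = 3, seed: int = 0):
        self.tree = DecisionTreeClassifier(max_depth=max_depth, criterion="gini",
                                           random_state=seed)

    def fit(self, samples, pixels_per_image: int = 400, seed: int = 0):
        """Train on generator ground truth: lesion pixels labelled by bwv_mask."""
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for s in samples:
            if s.ground_truth is None:
                raise InvalidInputError("BWV tree training needs ground-truth masks")
            stack = pixel_features(s.image)
            inside = np.argwhere(s.ground_truth.lesion_mask)
            if len(inside) == 0:
                continue
            take = inside[rng.choice(len(inside), size=min(pixels_per_image, len(inside)),
                                     replace=False)]
            feats.append(stack[take[:, 0], take[:, 1]])
            labels.append(s.ground_truth.bwv_mask[take[:, 0], take[:, 1]])
        x = np.concatenate(feats)
        y = np.concatenate(labels)
        if len(np.unique(y)) < 2:
            raise InvalidInputError("training pixels cover a single class")
        self.tree.fit(x, y)
        return self

    def predict_mask(self, image) -> np.ndarray:
        stack = pixel_features(image)
        flat = stack.reshape(-1, stack.shape[-1])
        return self.tree.predict(flat).reshape(stack.shape[:2]).astype(bool)


def _resolve_lesion_mask(lesion) -> np.ndarray:
    if isinstance(lesion, LesionSegmentation):
        return lesion.full_mask
    return np.asarray(lesion, dtype=bool)


def bwv_mask(image, lesion, rules: BwvDecisionTree | None = None) -> np.ndarray:
    """Binary veil mask restricted to the lesion; default thresholds or tree."""
    lmask = _resolve_lesion_mask(lesion)
    if not lmask.any():
        raise InvalidInputError("empty lesion mask")
    if rules is None:
        raw = pixel_features(image)[..., 0] > 0.5  # the F7 rule
    else:
        raw = rules.predict_mask(image)
    return raw & lmask


def majority_filter(mask) -> np.ndarray:
    """3x3 strict-majority vote; windows are clipped at image borders and a
    tie votes 0."""
    m = np.asarray(mask, dtype=bool)
    ones = ndimage.convolve(m.astype(int), np.ones((3, 3), int), mode="constant")
    total = ndimage.convolve(np.ones_like(m, dtype=int), np.ones((3, 3), int), mode="constant")
    return ones * 2 > total


def s_flag1(bwv, lesion) -> float:
    """BWV area over lesion area."""
    lmask = _resolve_lesion_mask(lesion)
    area = int(lmask.sum())
    if area == 0:
        raise UndefinedScoreError("zero lesion area")
    return float(np.asarray(bwv, dtype=bool).sum() / area)


@dataclass
class BoundaryRepresentation:
    points: np.ndarray  # (px, 2) ordered boundary coordinates
    centroid: np.ndarray  # (r_bar, c_bar), mean of mask coordinates


def boundary_representation(mask) -> BoundaryRepresentation:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise UndefinedScoreError("empty mask has no boundary")
    contours = measure.find_contours(m.astype(float), 0.5)
    points = max(contours, key=len)
    if len(points) < 3:
        raise UndefinedScoreError("boundary needs at least 3 points")
    return BoundaryRepresentation(points=points, centroid=np.argwhere(m).mean(axis=0))


def circularity(boundary: BoundaryRepresentation) -> float:
    """S_Flag2 = mean radial distance / std of radial distances.

    All-equidistant boundaries (a perfect continuous circle) return the
    +infinity sentinel rather than raising.
    """
    d = np.linalg.norm(boundary.points - boundary.centroid, axis=1)
    if len(d) < 3:
        raise UndefinedScoreError("boundary needs at least 3 points")
    std = d.std()
    if std <= 1e-9 * max(d.mean(), 1.0):  # all points equidistant
        return float("inf")
    return float(d.mean() / std)


@dataclass
class MomentSet:
    mu: np.ndarray  # central moments mu[x, y] for x + y <= 4 (pixel units)


def central_moments(mask) -> MomentSet:
    m = np.asarray(mask, dtype=float)
    if m.sum() == 0:
        raise UndefinedScoreError("zero-area mask")
    return MomentSet(mu=measure.moments_central(m, order=4))


def moment_invariant(moments: MomentSet, literal: bool = False) -> float:
    """Default: the affine invariant (mu20*mu02 - mu11^2) / mu00^4.

    ``literal=True`` evaluates (mu30*mu03 - mu11^2) / mu04^4 instead; that
    combination is <= 0 for every centrally symmetric shape, so it cannot
    grade ellipticity and exists only for comparison.
    """
    mu = moments.mu
    if mu[0, 0] <= 0:
        raise UndefinedScoreError("mu00 must be positive")
    if literal:
        return float((mu[3, 0] * mu[0, 3] - mu[1, 1] ** 2) / mu[0, 4] ** 4)
    return float((mu[2, 0] * mu[0, 2] - mu[1, 1] ** 2) / mu[0, 0] ** 4)


def ellipticity(moments: MomentSet, literal: bool = False) -> float:
    """S_Flag3: 16 pi^2 M folded through its reciprocal so ellipses score 1."""
    m = moment_invariant(moments, literal=literal)
    if m <= 1.0 / SIXTEEN_PI_SQ:
        return float(SIXTEEN_PI_SQ * m)
    return float(1.0 / (SIXTEEN_PI_SQ * m))


@dataclass
class FlagFeatures:
    S_Flag1: float
    S_Flag2: float
    S_Flag3: float
    circularity_degenerate: bool = False  # S_Flag2 hit the zero-std sentinel


def flag_features(image, lesion, rules: BwvDecisionTree | None = None) -> FlagFeatures:
    """bwv_mask -> majority_filter -> S_Flag1, plus the two shape scores."""
    lmask = _resolve_lesion_mask(lesion)
    veil = majority_filter(bwv_mask(image, lmask, rules=rules))
    s1 = s_flag1(veil, lmask)
    s2 = circularity(boundary_representation(lmask))
    s3 = ellipticity(central_moments(lmask))
    return FlagFeatures(S_Flag1=s1, S_Flag2=s2, S_Flag3=s3,
                        circularity_degenerate=not np.isfinite(s2))


def flag_features_from_segmentation(image, seg: LesionSegmentation,
                                    rules: BwvDecisionTree | None = None) -> FlagFeatures:
    return flag_features(image, seg.full_mask, rules=rules)


__all__ = [
    "BwvDecisionTree", "BoundaryRepresentation", "MomentSet", "FlagFeatures",
    "pixel_features", "bwv_mask", "majority_filter", "s_flag1",
    "boundary_representation", "circularity", "central_moments",
    "moment_invariant", "ellipticity", "flag_features",
    "flag_features_from_segmentation", "segmentation_from_mask",
]
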