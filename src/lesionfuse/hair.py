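"""Hair-artefact detection and inpainting.

Detection: grayscale (ITU-R BT.601 luma) -> morphological black-hat (closing
minus image; highlights dark thin structures such as hairs on a brighter
background) -> fixed intensity threshold.

Inpainting: the image is tiled into floor(N/p) x floor(M/p) non-overlapping
patches traversed row-major; a patch with no hairy pixel is skipped
immediately (termination contract).  Each masked pixel is replaced by the
weight-normalised sum of the *unmasked* pixels in its neighbourhood, with
Gaussian weights decreasing in Euclidean distance, so every inpainted value
is a convex combination of clean neighbours — the filled pixel can never fall
outside the intensity range of the neighbourhood it was computed from, and
pixels outside the mask are returned bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import grey_closing

from .errors import InvalidInputError, UnfillableMaskError

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601


@dataclass(frozen=True)
class HairRemovalConfig:
    blackhat_kernel: int = 17  # square side, odd
    hair_threshold: float = 10.0  # on the 0-255 black-hat response
    patch_size: int = 16  # p; tiling is floor(N/p) x floor(M/p)
    neighbourhood_radius: int = 5  # px
    weight_scale: float = 2.5  # Gaussian length scale of the weights, px
    min_hair_length: int = 20  # px; shorter response blobs are not hairs
    max_hair_halfwidth: float = 4.0  # px; wider structures are lesion texture

    def validate(self):
        if self.blackhat_kernel < 3 or self.blackhat_kernel % 2 == 0:
            raise InvalidInputError("blackhat_kernel must be odd and >= 3")
        if self.patch_size < 1 or self.neighbourhood_radius < 1:
            raise InvalidInputError("patch_size and neighbourhood_radius must be >= 1")


@dataclass
class HairMask:
    mask: np.ndarray  # bool, 1 = hair pixel


def _disk_footprint(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def _check_rgb(image):
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise InvalidInputError(f"expected a non-empty HxWx3 image, got shape {img.shape}")
    return img


def to_grayscale(image) -> np.ndarray:
    """BT.601 luma on the 0-255 scale (float)."""
    img = _check_rgb(image).astype(float)
    r, g, b = LUMA_WEIGHTS
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


def detect_hair_mask(image, config: HairRemovalConfig = HairRemovalConfig()) -> HairMask:
    """Black-hat response thresholding on the luma image.

    The raw threshold mask is refined by a shape filter: the black-hat
    transform also responds at compact dark features narrower than its
    kernel (tapering lesion tips, thin stripes between pigment tones), so a
    connected component is kept only when it looks like a hair — spatial
    extent of at least ``min_hair_length``, and any region wider than
    ``2 * max_hair_halfwidth`` (recovered by an opening with a disk of that
    radius, then dilated back to its rim) is excluded pixel-wise — so a hair
    that touches a wide dark blob keeps its thin run while the blob stays.
    """
    config.validate()
    gray = to_grayscale(image)
    k = config.blackhat_kernel
    blackhat = grey_closing(gray, size=(k, k)) - gray
    raw = blackhat > config.hair_threshold
    if raw.any() and config.max_hair_halfwidth > 0:
        r = int(np.ceil(config.max_hair_halfwidth))
        disk = _disk_footprint(r)
        wide_core = ndimage.binary_opening(raw, structure=disk)
        wide = ndimage.binary_dilation(wide_core, structure=disk) & raw
        raw = raw & ~wide
    if raw.any() and config.min_hair_length > 1:
        labels, n = ndimage.label(raw, structure=np.ones((3, 3), int))
        keep = np.zeros(n + 1, dtype=bool)
        for i, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is not None:
                extent = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
                keep[i] = extent >= config.min_hair_length
        raw = keep[labels]
    return HairMask(mask=raw)


def _fill_pixel(image, mask, r, c, radius, scale):
    h, w = mask.shape
    r0, r1 = max(0, r - radius), min(h, r + radius + 1)
    c0, c1 = max(0, c - radius), min(w, c + radius + 1)
    sub = mask[r0:r1, c0:c1]
    clean = ~sub
    if not clean.any():
        return None
    rr, cc = np.nonzero(clean)
    d2 = (rr + r0 - r) ** 2.0 + (cc + c0 - c) ** 2.0
    wts = np.exp(-d2 / (2.0 * scale * scale))
    wts /= wts.sum()
    return wts @ image[rr + r0, cc + c0].astype(float)


def inpaint_hair(image, mask: HairMask, config: HairRemovalConfig = HairRemovalConfig()) -> np.ndarray:
    """Replace masked pixels by Gaussian-weighted means of clean neighbours."""
    config.validate()
    img = _check_rgb(image)
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape != img.shape[:2]:
        raise InvalidInputError(f"mask shape {m.shape} != image shape {img.shape[:2]}")
    out = img.copy()
    if not m.any():
        return out
    h, w = m.shape
    p = config.patch_size
    n_pr, n_pc = h // p, w // p
    for pi in range(max(1, n_pr)):
        for pj in range(max(1, n_pc)):
            # last patch in each direction absorbs the remainder
            r0, c0 = pi * p, pj * p
            r1 = h if pi == max(1, n_pr) - 1 else (pi + 1) * p
            c1 = w if pj == max(1, n_pc) - 1 else (pj + 1) * p
            patch_mask = m[r0:r1, c0:c1]
            if not patch_mask.any():
                continue  # no hairy pixel: this patch terminates immediately
            for r, c in np.argwhere(patch_mask) + (r0, c0):
                radius = config.neighbourhood_radius
                val = _fill_pixel(img, m, r, c, radius, config.weight_scale)
                while val is None and radius <= 4 * config.neighbourhood_radius:
                    radius *= 2  # escalate when every neighbour is masked
                    val = _fill_pixel(img, m, r, c, radius, config.weight_scale)
                if val is None:
                    raise UnfillableMaskError(
                        f"pixel ({r},{c}) has no unmasked neighbour within radius {radius}"
                    )
                out[r, c] = np.rint(val) if np.issubdtype(img.dtype, np.integer) else val
    return out


def remove_hair(image, config: HairRemovalConfig = HairRemovalConfig()):
    """detect_hair_mask -> inpaint_hair; returns (cleaned image, mask)."""
    mask = detect_hair_mask(image, config)
    return inpaint_hair(image, mask, config), mask
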