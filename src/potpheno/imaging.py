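"""Plant/background segmentation for white-background studio photographs.

The workflow mirrors the classic semi-automatic Fiji recipe used in
pot-based shoot phenotyping: convert the RGB raster to an HSB stack,
build a 256-bin histogram of one channel, find the triangle-method
threshold, and label the darker (sub-threshold) side as plant.  All
pixel coordinates are 0-based, row-major, origin top-left; connectivity
is 8 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationConfig",
    "SegmentationError",
    "Roi",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "channel_histogram",
    "triangle_threshold",
    "segment_plant",
    "extract_roi",
]

#: value range of each HSB channel, used when binning histograms
_CHANNEL_RANGE = {"hue": 360.0, "saturation": 100.0, "brightness": 100.0}


class SegmentationError(RuntimeError):
    """Raised when thresholding produces an empty plant mask."""

    def __init__(self, message: str, thr: int | None = None):
        super().__init__(message)
        self.thr = thr


@dataclass
class SegmentationConfig:
    """Settings for :func:`segment_plant`.

    channel
        HSB channel whose histogram is thresholded.  Brightness is the
        default because a white studio background separates best in B;
        saturation is the usual fallback for glossy backgrounds.
    min_object_px
        Connected components (8-connectivity) smaller than this are
        removed — the automated stand-in for manual mask touch-up.
    largest_only
        Keep only the largest component instead of the union of all
        surviving components (a pot may hold more than one seedling).
    exclude_margin_px
        Number of bottom image rows forced to background before
        cleanup.  Studio scenes reserve this strip for the calibration
        ruler, which is dark and would otherwise survive thresholding.
    """

    channel: str = "brightness"
    min_object_px: int = 64
    largest_only: bool = False
    exclude_margin_px: int = 0

    def __post_init__(self) -> None:
        if self.channel not in _CHANNEL_RANGE:
            raise ValueError(f"unknown HSB channel {self.channel!r}")
        if self.min_object_px < 0 or self.exclude_margin_px < 0:
            raise ValueError("pixel counts must be non-negative")


@dataclass
class Roi:
    """A color image restricted to the plant mask.

    ``color`` is a float array with NaN outside the mask so that
    background pixels can never be mistaken for black plant pixels.
    """

    mask: np.ndarray
    color: np.ndarray
    thr: int | None = None

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def plant_pixels(self) -> np.ndarray:
        """Return an (n, 3) float array of the RGB plant pixels."""
        return self.color[self.mask.astype(bool)]


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("RGB values must lie in 0..255")
    return img


def rgb_to_hsb(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to an HSB stack.

    Returns a float array of shape (H, W, 3) holding hue in degrees
    (0–360), saturation in percent (0–100) and brightness in percent
    (0–100).  The standard hexcone model is used; achromatic pixels
    (R = G = B) get S = 0 and, by convention, H = 0.
    """
    img = _validate_rgb(img).astype(np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    v = img.max(axis=-1)
    c = v - img.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hue = np.select(
            [c == 0, v == r, v == g],
            [0.0,
             (60.0 * (g - b) / c) % 360.0,
             60.0 * (b - r) / c + 120.0],
            60.0 * (r - g) / c + 240.0,
        )
        sat = np.where(v == 0, 0.0, c / np.where(v == 0, 1.0, v)) * 100.0
    return np.stack([hue, sat, v / 255.0 * 100.0], axis=-1)


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse hexcone transform; returns a rounded uint8 RGB raster."""
    hsb = np.asarray(hsb, dtype=np.float64)
    h = (hsb[..., 0] % 360.0) / 60.0
    s = hsb[..., 1] / 100.0
    v = hsb[..., 2] / 100.0 * 255.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    choices = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    out = np.empty(hsb.shape, dtype=np.float64)
    for k, (rr, gg, bb) in enumerate(choices):
        m = i == k
        out[..., 0][m] = rr[m]
        out[..., 1][m] = gg[m]
        out[..., 2][m] = bb[m]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def channel_histogram(hsb: np.ndarray, channel: str = "brightness") -> np.ndarray:
    """256-bin count histogram of one HSB channel over its full range."""
    idx = {"hue": 0, "saturation": 1, "brightness": 2}[channel]
    values = np.asarray(hsb)[..., idx].ravel()
    hist, _ = np.histogram(values, bins=256, range=(0.0, _CHANNEL_RANGE[channel]))
    return hist


def triangle_threshold(hist: np.ndarray) -> int:
    """Triangle-method threshold of a count histogram.

    A line is drawn from the histogram peak (max-count bin) to the
    farthest nonzero bin on the side with the longer peak-to-tail span;
    the threshold is the bin whose histogram point lies farthest
    (perpendicular distance) from that line.  Ties break toward the
    tail.  Degenerate single-bin histograms return that bin.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array")
    if hist.min() < 0:
        raise ValueError("histogram counts must be non-negative")
    nz = np.flatnonzero(hist)
    if nz.size == 0:
        raise ValueError("degenerate input: all-zero histogram")
    peak = int(np.argmax(hist))
    lo, hi = int(nz[0]), int(nz[-1])
    # side with the longer peak-to-extreme span
    if hi - peak >= peak - lo:
        tail = hi
    else:
        tail = lo
    if tail == peak:
        return peak
    # perpendicular distance of every profile point between peak and tail
    # from the peak->tail line; scan in peak->tail order so that ties
    # resolved by ">" fall toward the tail via the final argmax reversal
    step = 1 if tail > peak else -1
    bins = np.arange(peak, tail + step, step, dtype=np.float64)
    counts = hist[bins.astype(int)]
    dx, dy = float(tail - peak), float(hist[tail] - hist[peak])
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (bins - peak) - dx * (counts - hist[peak])) / norm
    # ties toward the tail: pick the last index attaining the maximum
    best = np.flatnonzero(dist == dist.max())[-1]
    return int(bins[best])


def segment_plant(img: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Segment a plant from a white-background photograph.

    Thresholds the configured HSB channel with the triangle method and
    labels the darker (sub-threshold) side as plant: pixels exceeding
    the threshold are background (0), others plant (1).  Small objects
    are then removed (``cfg.min_object_px``, 8-connectivity).

    Returns a uint8 mask (1 = plant).  Raises
    :class:`SegmentationError` (carrying the threshold used) if no
    plant pixels survive.
    """
    cfg = cfg or SegmentationConfig()
    hsb = rgb_to_hsb(img)
    hist = channel_histogram(hsb, cfg.channel)
    thr = triangle_threshold(hist)
    if np.count_nonzero(hist) == 1:
        # all pixels in one bin (e.g. a pure-white frame): nothing to separate
        raise SegmentationError(
            f"no foreground/background contrast (THR bin {thr})", thr=thr
        )
    idx = {"hue": 0, "saturation": 1, "brightness": 2}[cfg.channel]
    bin_width = _CHANNEL_RANGE[cfg.channel] / 256.0
    pixel_bin = np.minimum(np.floor(hsb[..., idx] / bin_width), 255).astype(int)
    mask = pixel_bin <= thr
    if cfg.exclude_margin_px > 0:
        mask[-cfg.exclude_margin_px:, :] = False
    mask = _clean_mask(mask, cfg)
    if not mask.any():
        raise SegmentationError(
            f"no plant pixels survive thresholding (THR bin {thr})", thr=thr
        )
    return mask.astype(np.uint8)


def _clean_mask(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    structure = np.ones((3, 3), bool)  # 8-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    if cfg.largest_only:
        keep = np.array([np.argmax(sizes) + 1])
        keep = keep[sizes[keep - 1] >= cfg.min_object_px]
    else:
        keep = np.flatnonzero(sizes >= cfg.min_object_px) + 1
    return np.isin(labels, keep)


def extract_roi(img: np.ndarray, mask: np.ndarray, thr: int | None = None) -> Roi:
    """Superimpose the RGB image on a binary mask.

    The returned :class:`Roi` carries the color values on plant pixels
    and NaN elsewhere, so downstream colorimetric traits can never
    silently include background.
    """
    img = _validate_rgb(img)
    mask = np.asarray(mask)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape[:2]}"
        )
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary with values in {0, 1}")
    if not mask.any():
        raise ValueError("empty mask: no plant pixels to extract")
    color = img.astype(np.float64).copy()
    color[~mask.astype(bool)] = np.nan
    return Roi(mask=mask.astype(np.uint8), color=color, thr=thr)
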