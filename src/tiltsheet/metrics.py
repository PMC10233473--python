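"""Image-quality metrics: signal-to-background ratios, SSIM, NRMSE.

Two SBR conventions are used in light-sheet work and both appear here:

* structure SBR — mean over a signal ROI divided by mean over a background
  ROI (e.g. nucleolar-rim signal over nucleolar-centre background);
* spot SBR — (peak - background) / background for a single molecule, which
  can fall below 1 for dim spots drowned in epi background.

All SBRs assume camera-offset-corrected images; subtract the offset first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "RoiSpec",
    "sbr_structure",
    "sbr_spot",
    "enhancement",
    "ssim",
    "nrmse",
    "disk_mask",
    "annulus_mask",
]


@dataclass(frozen=True)
class RoiSpec:
    """Disjoint boolean masks selecting signal and background pixels."""

    signal_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.signal_mask, bool)
        b = np.asarray(self.background_mask, bool)
        if s.shape != b.shape:
            raise ValueError("masks must share a shape")
        if not s.any() or not b.any():
            raise ValueError("both masks must be non-empty")
        if (s & b).any():
            raise ValueError("signal and background masks must be disjoint")
        object.__setattr__(self, "signal_mask", s)
        object.__setattr__(self, "background_mask", b)


def disk_mask(shape: tuple[int, int], center_rc: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2


def annulus_mask(
    shape: tuple[int, int], center_rc: tuple[float, float], r_in: float, r_out: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
    return (d2 > r_in**2) & (d2 <= r_out**2)


def sbr_structure(image: np.ndarray, roi: RoiSpec) -> float:
    """mean(signal ROI) / mean(background ROI) on an offset-corrected image."""
    image = np.asarray(image, float)
    bg = float(image[roi.background_mask].mean())
    if bg <= 0:
        raise ValueError("background mean must be positive")
    return float(image[roi.signal_mask].mean()) / bg


def sbr_spot(
    image: np.ndarray,
    peak_xy: tuple[float, float],
    r_peak: float = 1.0,
    r_in: float = 3.0,
    r_out: float = 6.0,
) -> float:
    """Single-molecule SBR: (mean over peak disk - annulus median) / annulus median.

    ``peak_xy`` is (col, row) in pixels.  The above-background convention
    allows values below 1 for spots dimmer than their surroundings' shot
    level.
    """
    if not (r_out > r_in >= r_peak >= 1):
        raise ValueError("need r_out > r_in >= r_peak >= 1")
    image = np.asarray(image, float)
    col, row = peak_xy
    if not (r_out <= col <= image.shape[1] - 1 - r_out and r_out <= row <= image.shape[0] - 1 - r_out):
        raise ValueError("annulus extends outside the image")
    peak = disk_mask(image.shape, (row, col), r_peak)
    ring = annulus_mask(image.shape, (row, col), r_in, r_out)
    bg = float(np.median(image[ring]))
    if bg == 0:
        # a genuinely flat, zero-background image has zero contrast
        return 0.0 if math.isclose(float(image[peak].mean()), 0.0, abs_tol=1e-300) else math.inf
    return (float(image[peak].mean()) - bg) / bg


def enhancement(sbr_a: float, sbr_b: float) -> float:
    """Fold improvement of one SBR over another, ``sbr_a / sbr_b``."""
    if sbr_b == 0:
        raise ZeroDivisionError("reference SBR is zero")
    return sbr_a / sbr_b


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float | None = None,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity index with a Gaussian window.

    The standard formulation: local means/variances/covariance from an
    11x11 Gaussian window (SD 1.5), stabilisers C1 = (k1 L)^2 and
    C2 = (k2 L)^2 with L the dynamic range (inferred from ``b``, the
    reference, when not given), averaged over the valid interior.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0:
            raise ValueError("reference image is constant; pass data_range")
    filt = lambda img: gaussian_filter(img, sigma, truncate=truncate)
    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    va = uaa - ua * ua
    vb = ubb - ub * ub
    cov = uab - ua * ub
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * cov + c2)) / (
        (ua**2 + ub**2 + c1) * (va + vb + c2)
    )
    pad = int(truncate * sigma + 0.5)  # window radius
    return float(s[pad:-pad, pad:-pad].mean())


def nrmse(a: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error normalized by the reference dynamic range."""
    a = np.asarray(a, float)
    ref = np.asarray(ref, float)
    if a.shape != ref.shape:
        raise ValueError("images must share a shape")
    rng = float(ref.max() - ref.min())
    if rng == 0:
        raise ValueError("reference image is constant")
    return float(np.sqrt(np.mean((a - ref) ** 2)) / rng)
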