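"""Frame preprocessing: illumination correction, cropping, masked-median
background subtraction and the power log-log slope blur metric."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "CropSpec",
    "fwhm_to_sigma",
    "correct_vignetting",
    "crop_margins",
    "subtract_background",
    "foreground_mask",
    "power_loglog_slope",
]

log = logging.getLogger(__name__)

#: FWHM -> sigma conversion factor, 2 * sqrt(2 * ln 2)
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_FACTOR


@dataclass(frozen=True)
class CropSpec:
    """Pixel margins removed from each image edge."""

    top: int = 30
    left: int = 30
    right: int = 60
    bottom: int = 160

    def validate(self, shape: tuple[int, int]) -> None:
        if min(self.top, self.left, self.right, self.bottom) < 0:
            raise ValueError("crop margins must be non-negative")
        h, w = shape
        if self.top + self.bottom >= h or self.left + self.right >= w:
            raise ValueError(f"crop {self} consumes the whole {h}x{w} image")


def correct_vignetting(frame: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Divide ``frame`` by the illumination gain ``field`` elementwise."""
    frame = np.asarray(frame, dtype=float)
    field = np.asarray(field, dtype=float)
    if frame.shape != field.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs field {field.shape}")
    if np.any(field <= 0):
        raise ValueError("illumination field must be strictly positive")
    return frame / field


def crop_margins(frame: np.ndarray, spec: CropSpec = CropSpec()) -> np.ndarray:
    frame = np.asarray(frame)
    spec.validate(frame.shape)
    h, w = frame.shape
    return frame[spec.top : h - spec.bottom, spec.left : w - spec.right]


def foreground_mask(
    frame: np.ndarray, smooth_fwhm: float = 6.0, min_diameter: float = 15.0
) -> np.ndarray:
    """Gaussian-smoothed global-Otsu foreground with small objects removed.

    Otsu runs on a 256-bin histogram of the smoothed image; connected
    components with equivalent diameter below ``min_diameter`` are dropped.
    """
    frame = np.asarray(frame, dtype=float)
    smoothed = ndimage.gaussian_filter(frame, fwhm_to_sigma(smooth_fwhm))
    if np.ptp(smoothed) == 0:
        return np.zeros(frame.shape, dtype=bool)
    thr = threshold_otsu(smoothed, nbins=256)
    mask = smoothed > thr
    lab = label(mask)
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for rp in regionprops(lab):
        if rp.equivalent_diameter_area >= min_diameter:
            keep[rp.label] = True
    return keep[lab]


def subtract_background(
    frame: np.ndarray, smooth_fwhm: float = 6.0, min_diameter: float = 15.0
) -> tuple[np.ndarray, float]:
    """Subtract the median intensity outside the foreground mask.

    Returns the clipped-at-zero corrected frame and the background value.
    Constant frames pass through unchanged (their constant is the
    background); a mask covering everything falls back to the global
    median with a logged warning.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return frame.copy(), float(frame.flat[0]) if frame.size else 0.0
    mask = foreground_mask(frame, smooth_fwhm=smooth_fwhm, min_diameter=min_diameter)
    outside = frame[~mask]
    if outside.size == 0:
        log.warning("foreground mask covers the entire frame; using global median")
        background = float(np.median(frame))
    else:
        background = float(np.median(outside))
    return np.clip(frame - background, 0.0, None), background


def power_loglog_slope(frame: np.ndarray) -> float:
    """Slope of log radially-averaged power spectrum vs log frequency.

    Radial averaging uses integer-radius annuli on the centered FFT grid;
    the fit spans frequencies from the fundamental up to Nyquist and
    excludes the DC component.  White noise gives a slope near 0; blur
    pushes it negative.  Returns NaN for degenerate (constant) frames.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if h < 16 or w < 16:
        raise ValueError("frame must be at least 16x16")
    if np.ptp(frame) == 0:
        return float("nan")
    spec = np.fft.fftshift(np.abs(np.fft.fft2(frame - frame.mean())) ** 2)
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    # normalized frequency radius scaled so integer bins span to Nyquist
    nbins = min(h, w) // 2
    r = np.sqrt(((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2)  # cycles/px
    rbin = np.round(r * 2 * nbins).astype(int)  # Nyquist (0.5 c/px) -> nbins
    valid = (rbin >= 1) & (rbin <= nbins)
    sums = np.bincount(rbin[valid], weights=spec[valid], minlength=nbins + 1)
    counts = np.bincount(rbin[valid], minlength=nbins + 1)
    radii = np.arange(nbins + 1)
    ok = (counts > 0) & (sums > 0) & (radii >= 1)
    if ok.sum() < 2:
        return float("nan")
    logf = np.log(radii[ok] / (2.0 * nbins))  # back to cycles/px
    logp = np.log(sums[ok] / counts[ok])
    slope = np.polyfit(logf, logp, 1)[0]
    return float(slope)
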