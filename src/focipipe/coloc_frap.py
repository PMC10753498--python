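"""Secondary quantifications: Manders M1, object-based colocalization,
proximity-ligation positivity within a metric radius, normalized line
profiles, and FRAP min-max normalization plus exponential recovery fits."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.measure import label as sk_label, regionprops

from .synthetic_scenes import FrapCurve

__all__ = [
    "ColocResult",
    "FrapFit",
    "manders_m1",
    "object_coloc_fraction",
    "pla_positive_fraction",
    "line_profile",
    "normalize_frap",
    "fit_frap",
]


@dataclass(frozen=True)
class ColocResult:
    m1: Optional[float]
    fraction_a_in_b: float
    fraction_b_in_a: float
    n_a: int
    n_a_coloc: int
    n_b: int
    n_b_coloc: int


@dataclass(frozen=True)
class FrapFit:
    tau: float                 # s
    halftime: float            # tau * ln 2, s
    plateau: float
    residual_rms: float
    halftime_empirical: Optional[float]  # first crossing of plateau/2
    converged: bool


def manders_m1(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi: Optional[np.ndarray] = None,
    ch2_threshold: float = 0.0,
) -> float:
    """Fraction of channel-1 intensity in pixels where channel 2 exceeds
    ``ch2_threshold`` (default: above zero), optionally within ``roi``."""
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes must match")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("roi shape must match the channels")
        a = a[roi]
        b = b[roi]
    total = a.sum()
    if total == 0:
        raise ValueError("M1 undefined: channel 1 has zero total intensity")
    return float(a[b > ch2_threshold].sum() / total)


def _object_centroids(masks: np.ndarray) -> list[tuple[float, float]]:
    """Centroids of objects given either a label image or a boolean mask."""
    m = np.asarray(masks)
    lab = sk_label(m > 0) if m.dtype == bool or m.max() <= 1 else m.astype(int)
    return [rp.centroid for rp in regionprops(lab)]


def object_coloc_fraction(objects_a: np.ndarray, objects_b: np.ndarray) -> ColocResult:
    """Object-based colocalization by the centroid-in-mask rule.

    An A object colocalizes iff the pixel under its centroid lies inside
    any B object; the symmetric B-to-A fraction is also returned.
    """
    a = np.asarray(objects_a)
    b = np.asarray(objects_b)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    cents_a = _object_centroids(a)
    cents_b = _object_centroids(b)
    if not cents_a:
        raise ValueError("no A objects: colocalization fraction undefined")
    in_b = (b > 0)
    in_a = (a > 0)

    def _inside(cents, mask):
        n = 0
        for cy, cx in cents:
            iy = min(max(int(round(cy)), 0), mask.shape[0] - 1)
            ix = min(max(int(round(cx)), 0), mask.shape[1] - 1)
            if mask[iy, ix]:
                n += 1
        return n

    na_c = _inside(cents_a, in_b)
    nb_c = _inside(cents_b, in_a) if cents_b else 0
    return ColocResult(
        m1=None,
        fraction_a_in_b=na_c / len(cents_a),
        fraction_b_in_a=(nb_c / len(cents_b)) if cents_b else float("nan"),
        n_a=len(cents_a),
        n_a_coloc=na_c,
        n_b=len(cents_b),
        n_b_coloc=nb_c,
    )


def pla_positive_fraction(
    bodies: np.ndarray,
    puncta: np.ndarray,
    radius_um: float = 1.5,
    pixel_size: float = 0.04,
) -> float:
    """Fraction of body centers with a punctum within ``radius_um``.

    ``bodies`` and ``puncta`` are (n, 2) pixel coordinates; distances are
    converted with ``pixel_size`` (um/px).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    bodies = np.asarray(bodies, dtype=float).reshape(-1, 2)
    puncta = np.asarray(puncta, dtype=float).reshape(-1, 2)
    if bodies.shape[0] == 0:
        raise ValueError("positive fraction undefined with no bodies")
    if puncta.shape[0] == 0:
        return 0.0
    radius_px = radius_um / pixel_size
    d = np.sqrt(
        ((bodies[:, None, :] - puncta[None, :, :]) ** 2).sum(axis=2)
    )
    return float((d.min(axis=1) <= radius_px).mean())


def line_profile(
    frame: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
    normalize: Optional[str] = None,
) -> np.ndarray:
    """Bilinear intensity profile along the segment p0 -> p1.

    ``normalize='max1'`` divides by the profile maximum; ``'minmax'``
    maps the profile onto [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("zero-length profile line")
    for p in (p0, p1):
        if not (0 <= p[0] <= frame.shape[0] - 1 and 0 <= p[1] <= frame.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the frame")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.outer(1 - t, p0) + np.outer(t, p1)
    prof = ndimage.map_coordinates(frame, coords.T, order=1, mode="nearest")
    if normalize == "max1":
        mx = prof.max()
        if mx == 0:
            raise ValueError("cannot max-normalize an all-zero profile")
        prof = prof / mx
    elif normalize == "minmax":
        lo, hi = prof.min(), prof.max()
        if hi == lo:
            raise ValueError("cannot min-max normalize a constant profile")
        prof = (prof - lo) / (hi - lo)
    elif normalize is not None:
        raise ValueError("normalize must be None, 'max1' or 'minmax'")
    return prof


def normalize_frap(curve: FrapCurve) -> FrapCurve:
    """Min-max normalize a FRAP curve to [0, 1].

    With a clean bleach the minimum is the first post-bleach sample, so
    the normalized post-bleach trace starts at exactly 0.
    """
    y = np.asarray(curve.intensities, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("flat curve cannot be normalized")
    return replace(curve, intensities=(y - lo) / (hi - lo))


def _exp_recovery(t, plateau, tau):
    return plateau * (1.0 - np.exp(-t / tau))


def fit_frap(curve: FrapCurve) -> FrapFit:
    """Least-squares fit of ``P * (1 - exp(-t/tau))`` to the post-bleach
    samples (time measured from the bleach).

    Initialized from a log-linear estimate; returns tau, the derived
    halftime ``tau * ln 2``, the plateau, the residual RMS, and an
    empirical half-recovery time interpolated from the data (None when
    the curve never reaches half the fitted plateau).
    """
    t = np.asarray(curve.post_times, dtype=float)
    y = np.asarray(curve.post_intensities, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach samples")
    t = t - t[0]

    p_guess = max(float(y.max()), 1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = 1.0 - y / (p_guess * 1.05)
        ok = resid > 1e-9
        tau_guess = 1.0
        if ok.sum() >= 2:
            slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
            if slope < 0:
                tau_guess = -1.0 / slope
    converged = True
    try:
        popt, _ = curve_fit(
            _exp_recovery,
            t,
            y,
            p0=[p_guess, tau_guess],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
        plateau, tau = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        plateau, tau = p_guess, tau_guess
    resid = y - _exp_recovery(t, plateau, tau)
    rms = float(np.sqrt(np.mean(resid**2)))

    half = plateau / 2.0
    emp: Optional[float] = None
    above = np.nonzero(y >= half)[0]
    if above.size:
        i = int(above[0])
        if i == 0:
            emp = float(t[0])
        else:
            y0, y1 = y[i - 1], y[i]
            emp = float(t[i - 1] + (half - y0) / (y1 - y0) * (t[i] - t[i - 1]))
    return FrapFit(
        tau=tau,
        halftime=tau * np.log(2.0),
        plateau=plateau,
        residual_rms=rms,
        halftime_empirical=emp,
        converged=converged,
    )
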