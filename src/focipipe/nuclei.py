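"""Nuclei segmentation and dead/mitotic-cell filtering.

Two parameter profiles are shipped, matching the primary and the
secondary (validation) screen setups; both are plain dataclasses so any
field can be overridden from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .preprocess import fwhm_to_sigma

__all__ = [
    "SegmentationProfile",
    "NucleusObject",
    "PRIMARY_SEGMENTATION",
    "SECONDARY_SEGMENTATION",
    "segment_nuclei",
    "filter_viable",
    "calibrate_viability_thresholds",
    "PERMISSIVE_THRESHOLDS",
]

#: features a filter rule may reference -> extractor on NucleusObject
FILTER_FEATURES = (
    "sd_intensity",
    "upper_quartile_intensity",
    "area",
    "eccentricity",
    "solidity",
    "mean_intensity",
)


@dataclass(frozen=True)
class SegmentationProfile:
    """Segmentation and viability-filter settings for one screen setup.

    ``filter_rules`` is a tuple of ``(feature, direction)`` pairs where
    direction ``"high"`` removes objects whose feature exceeds the
    threshold and ``"low"`` removes objects below it (strict inequality;
    ties are kept).
    """

    name: str
    smooth_fwhm: float
    min_diameter: float
    max_diameter: Optional[float]
    filter_rules: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.min_diameter <= 0:
            raise ValueError("min_diameter must be positive")
        if self.max_diameter is not None and self.max_diameter <= self.min_diameter:
            raise ValueError("max_diameter must exceed min_diameter")
        for feat, direction in self.filter_rules:
            if feat not in FILTER_FEATURES:
                raise ValueError(f"unknown filter feature {feat!r}")
            if direction not in ("high", "low"):
                raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")


PRIMARY_SEGMENTATION = SegmentationProfile(
    name="primary",
    smooth_fwhm=6.0,
    min_diameter=35.0,
    max_diameter=None,
    filter_rules=(
        ("sd_intensity", "high"),
        ("upper_quartile_intensity", "high"),
        ("area", "low"),
    ),
)

SECONDARY_SEGMENTATION = SegmentationProfile(
    name="secondary",
    smooth_fwhm=6.0,
    min_diameter=23.0,
    max_diameter=43.0,
    filter_rules=(
        ("sd_intensity", "high"),
        ("eccentricity", "low"),
        ("solidity", "high"),
    ),
)

#: thresholds that remove nothing (every rule at its permissive extreme)
PERMISSIVE_THRESHOLDS: Mapping[str, float] = {
    "sd_intensity": float("inf"),
    "upper_quartile_intensity": float("inf"),
    "area": float("-inf"),
    "eccentricity": float("-inf"),
    "solidity": float("inf"),
    "mean_intensity": float("inf"),
}


@dataclass
class NucleusObject:
    """One segmented nucleus in one frame, with measured features."""

    label: int
    frame: int
    centroid: tuple[float, float]      # (row, col)
    area: int                          # px^2
    mean_intensity: float
    sd_intensity: float
    upper_quartile_intensity: float
    integrated_intensity: float
    eccentricity: float
    solidity: float
    coords: np.ndarray                 # (area, 2) int pixel set
    image_shape: tuple[int, int]
    _lin: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def equivalent_diameter(self) -> float:
        return 2.0 * np.sqrt(self.area / np.pi)

    def pixel_indices(self) -> np.ndarray:
        """Sorted linear pixel indices (cached), for overlap computations."""
        if self._lin is None:
            lin = np.ravel_multi_index((self.coords[:, 0], self.coords[:, 1]), self.image_shape)
            self._lin = np.sort(lin)
        return self._lin

    def feature(self, name: str) -> float:
        return float(getattr(self, name))


def segment_nuclei(
    frame: np.ndarray,
    profile: SegmentationProfile = PRIMARY_SEGMENTATION,
    frame_index: int = 0,
) -> list[NucleusObject]:
    """Label smoothed+Otsu foreground components and measure features.

    Components whose equivalent diameter falls outside the profile's
    diameter gate are discarded.  Features are measured on the *input*
    frame (not the smoothed copy).  Constant frames yield an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return []
    smoothed = ndimage.gaussian_filter(frame, fwhm_to_sigma(profile.smooth_fwhm))
    if np.ptp(smoothed) == 0:
        return []
    thr = threshold_otsu(smoothed, nbins=256)
    lab = label(smoothed > thr)
    out: list[NucleusObject] = []
    for rp in regionprops(lab, intensity_image=frame):
        d = rp.equivalent_diameter_area
        if d < profile.min_diameter:
            continue
        if profile.max_diameter is not None and d > profile.max_diameter:
            continue
        vals = frame[rp.coords[:, 0], rp.coords[:, 1]]
        out.append(
            NucleusObject(
                label=int(rp.label),
                frame=frame_index,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                mean_intensity=float(vals.mean()),
                sd_intensity=float(vals.std()),
                upper_quartile_intensity=float(np.percentile(vals, 75)),
                integrated_intensity=float(vals.sum()),
                eccentricity=float(rp.eccentricity),
                solidity=float(rp.solidity),
                coords=rp.coords.copy(),
                image_shape=frame.shape,
            )
        )
    return out


def filter_viable(
    objects: Sequence[NucleusObject],
    profile: SegmentationProfile,
    thresholds: Mapping[str, float],
) -> tuple[list[NucleusObject], list[NucleusObject]]:
    """Partition nuclei into (kept, removed) under the profile's rules.

    An object is removed iff it *strictly* violates any rule: feature >
    threshold for "high" rules, feature < threshold for "low" rules.
    Objects exactly at a threshold are kept.
    """
    for feat, _ in profile.filter_rules:
        if feat not in thresholds:
            raise ValueError(f"missing threshold for filter feature {feat!r}")
    kept: list[NucleusObject] = []
    removed: list[NucleusObject] = []
    for obj in objects:
        bad = False
        for feat, direction in profile.filter_rules:
            v = obj.feature(feat)
            t = thresholds[feat]
            if (direction == "high" and v > t) or (direction == "low" and v < t):
                bad = True
                break
        (removed if bad else kept).append(obj)
    return kept, removed


def calibrate_viability_thresholds(
    normal_objects: Iterable[NucleusObject],
    profile: SegmentationProfile,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
) -> dict[str, float]:
    """Set each rule's threshold at the 1st/99th percentile of a null
    (healthy-cell) population: 'high' rules at the upper percentile,
    'low' rules at the lower one."""
    objs = list(normal_objects)
    if not objs:
        raise ValueError("no objects to calibrate from")
    thresholds: dict[str, float] = {}
    for feat, direction in profile.filter_rules:
        vals = np.array([o.feature(feat) for o in objs])
        q = upper_q if direction == "high" else lower_q
        thresholds[feat] = float(np.quantile(vals, q))
    return thresholds
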