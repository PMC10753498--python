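"""Focus detection: white top-hat spot enhancement inside nucleus masks,
and prominence-based maxima finding for fixed-cell counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, opening, white_tophat

from .nuclei import NucleusObject
from .preprocess import fwhm_to_sigma

__all__ = [
    "FociProfile",
    "FocusObject",
    "PRIMARY_FOCI",
    "SECONDARY_FOCI",
    "detect_foci",
    "find_maxima",
]


@dataclass(frozen=True)
class FociProfile:
    """Spot-detection settings; ``*_diameter`` structuring elements are
    discrete disks of radius ``floor(d / 2)``."""

    name: str
    smooth_fwhm: float
    tophat_diameter: int
    opening_diameter: Optional[int]   # applied to nucleus masks; None skips
    manual_threshold: float           # on [0, 1]-scaled intensities
    min_diameter: float
    max_diameter: float

    def __post_init__(self):
        if not 0.0 <= self.manual_threshold <= 1.0:
            raise ValueError("manual_threshold must lie in [0, 1]")
        if self.min_diameter <= 0 or self.max_diameter < self.min_diameter:
            raise ValueError("need 0 < min_diameter <= max_diameter")


PRIMARY_FOCI = FociProfile(
    name="primary",
    smooth_fwhm=4.0,
    tophat_diameter=6,
    opening_diameter=15,
    manual_threshold=0.004,
    min_diameter=3.0,
    max_diameter=10.0,
)

SECONDARY_FOCI = FociProfile(
    name="secondary",
    smooth_fwhm=2.0,
    tophat_diameter=5,
    opening_diameter=None,
    manual_threshold=0.014,
    min_diameter=2.0,
    max_diameter=6.0,
)


@dataclass
class FocusObject:
    label: int
    frame: int
    centroid: tuple[float, float]
    area: int
    parent_nucleus: int          # label of the containing nucleus
    peak_intensity: float        # max of the enhanced image in the object


def _nucleus_label_image(
    nuclei: Sequence[NucleusObject], shape: tuple[int, int]
) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for n in nuclei:
        lab[n.coords[:, 0], n.coords[:, 1]] = n.label
    return lab


def detect_foci(
    frame: np.ndarray,
    nuclei: Sequence[NucleusObject],
    profile: FociProfile,
    frame_index: int = 0,
) -> list[FocusObject]:
    """Detect bright foci within (optionally opened) nucleus masks.

    The frame is Gaussian-smoothed (FWHM), enhanced with a white top-hat
    (disk of radius ``tophat_diameter // 2``), restricted to the nucleus
    masks — after a morphological opening of those masks when the profile
    requests one, which trims micronucleus protrusions — thresholded at
    the profile's manual threshold, and size-gated on equivalent
    diameter.  Each focus is assigned to the nucleus containing its
    centroid.
    """
    if not nuclei:
        return []
    frame = np.asarray(frame, dtype=float)
    nuc_labels = _nucleus_label_image(nuclei, frame.shape)
    mask = nuc_labels > 0
    if profile.opening_diameter is not None:
        mask = opening(mask, disk(profile.opening_diameter // 2))
    smoothed = ndimage.gaussian_filter(frame, fwhm_to_sigma(profile.smooth_fwhm))
    enhanced = white_tophat(smoothed, disk(profile.tophat_diameter // 2))
    candidate = (enhanced > profile.manual_threshold) & mask
    lab = sk_label(candidate)
    out: list[FocusObject] = []
    for rp in regionprops(lab, intensity_image=enhanced):
        d = rp.equivalent_diameter_area
        if not (profile.min_diameter <= d <= profile.max_diameter):
            continue
        cy, cx = rp.centroid_weighted  # intensity-weighted: sub-pixel spot center
        iy, ix = int(round(cy)), int(round(cx))
        iy = min(max(iy, 0), frame.shape[0] - 1)
        ix = min(max(ix, 0), frame.shape[1] - 1)
        parent = int(nuc_labels[iy, ix])
        if parent == 0 or not mask[iy, ix]:
            continue
        out.append(
            FocusObject(
                label=int(rp.label),
                frame=frame_index,
                centroid=(float(cy), float(cx)),
                area=int(rp.area),
                parent_nucleus=parent,
                peak_intensity=float(rp.intensity_max),
            )
        )
    return out


# ---------------------------------------------------------------------------
# prominence-based maxima


def find_maxima(frame: np.ndarray, prominence: float) -> list[tuple[float, float]]:
    """Local maxima whose topographic prominence is >= ``prominence``.

    Prominence of a peak is its height minus the highest saddle that
    connects it to any higher peak (ties broken toward the peak created
    first in height-then-raster order, mirroring flood-fill maxima
    finders); the dominant/global maximum scores peak minus global
    minimum.  Plateaus contribute a single point at the centroid of the
    equal-height plateau.  Uses 8-connectivity.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    arr = np.asarray(frame, dtype=float)
    h, w = arr.shape
    n = arr.size
    flat = arr.ravel()
    order = np.argsort(-flat, kind="stable")  # height desc, raster among ties

    parent = np.full(n, -1, dtype=np.int64)   # union-find parent; -1 unseen
    set_peak_height = {}
    set_peak_id = {}
    peak_origin: list[int] = []
    peak_height: list[float] = []
    peak_prom: list[float] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for idx in order:
        y, x = divmod(int(idx), w)
        hgt = flat[idx]
        parent[idx] = idx
        roots = set()
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                j = ny * w + nx
                if parent[j] != -1:
                    roots.add(find(j))
        if not roots:
            pid = len(peak_origin)
            peak_origin.append(int(idx))
            peak_height.append(float(hgt))
            peak_prom.append(-1.0)
            set_peak_height[idx] = float(hgt)
            set_peak_id[idx] = pid
            continue
        # merge the new pixel and all neighboring sets; the dominant peak
        # (greater height, then smaller id) survives, losers are assigned
        # prominence = their peak height - current (saddle) height
        cur = int(idx)
        set_peak_height[cur] = float(hgt)
        set_peak_id[cur] = -1  # placeholder: plain pixel, not a peak
        for r in roots:
            a, b = find(cur), find(r)
            if a == b:
                continue
            ha, ia = set_peak_height[a], set_peak_id[a]
            hb, ib = set_peak_height[b], set_peak_id[b]
            if ia == -1:
                winner, loser = b, a
            elif ib == -1:
                winner, loser = a, b
            elif (hb, -ib) > (ha, -ia):
                winner, loser = b, a
            else:
                winner, loser = a, b
            lid = set_peak_id[loser]
            if lid >= 0 and peak_prom[lid] < 0:
                peak_prom[lid] = peak_height[lid] - float(hgt)
            parent[loser] = winner
            cur = winner

    gmin = float(flat.min())
    for pid in range(len(peak_origin)):
        if peak_prom[pid] < 0:
            peak_prom[pid] = peak_height[pid] - gmin

    points: list[tuple[float, float]] = []
    for pid, prom in enumerate(peak_prom):
        if prom < prominence:
            continue
        # centroid of the equal-height plateau containing the origin
        origin = peak_origin[pid]
        plateau = _plateau_pixels(arr, origin)
        points.append((float(plateau[:, 0].mean()), float(plateau[:, 1].mean())))
    points.sort()
    return points


def _plateau_pixels(arr: np.ndarray, origin: int) -> np.ndarray:
    """8-connected component of pixels equal in height to ``origin``."""
    h, w = arr.shape
    oy, ox = divmod(origin, w)
    level = arr[oy, ox]
    comp = sk_label(arr == level, connectivity=2)
    return np.argwhere(comp == comp[oy, ox])
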