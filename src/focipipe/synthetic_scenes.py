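"""Synthetic fluorescence time-lapse scenes with per-cell ground truth.

Scenes emulate the statistical structure the screening pipeline assumes:
roughly disk-shaped nuclei performing a Gaussian random walk, a
subpopulation entering a bounded window during which a Poisson number of
bright foci appear, radially (and optionally asymmetrically) decaying
illumination, an exponentially bleaching substrate background, and
bright/round dead or mitotic cells.  Every stochastic choice is recorded
in a :class:`GroundTruth` object so downstream detection, tracking and
scoring can be validated against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SceneParams",
    "CellTruth",
    "GroundTruth",
    "TimeLapse",
    "PlateDataset",
    "ScenePosition",
    "PackingError",
    "generate_illumination_field",
    "render_timelapse",
    "generate_plate",
    "simulate_frap_curve",
    "FrapCurve",
]

#: half-max radius of a Gaussian, in units of sigma
_HALF_MAX = math.sqrt(2.0 * math.log(2.0))

VIABILITY_CLASSES = ("normal", "dead", "mitotic", "micronucleated")
WELL_ROLES = ("library", "sNEG1", "sPOLD1", "sDEK", "empty")


class PackingError(ValueError):
    """Raised when the requested cell count cannot fit in the image."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters controlling one simulated field of view."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.65           # um/px
    n_frames: int = 30
    frame_interval: float = 12.0       # min
    n_cells: int = 15
    nucleus_radius_mean: float = 12.0  # px (half-max radius)
    nucleus_radius_sd: float = 1.2
    cell_drift_sd: float = 2.0         # px/frame random-walk step
    foci_rate_lambda: float = 2.7      # expected foci per body-positive cell
    foci_lifetime_mean: float = 48.0   # min
    foci_lifetime_sd: float = 30.0
    late_s_fraction: float = 0.5
    foci_count_fixed: Optional[int] = None  # overrides Poisson sampling
    focus_radius: float = 2.0          # px (half-max radius)
    focus_amplitude: float = 0.05
    nucleus_amplitude: float = 0.25
    background_level: float = 0.08
    bleach_halflife: float = math.inf  # frames; inf disables bleaching
    vignette_strength: float = 0.0     # in [0, 1)
    vignette_asymmetry: tuple[float, float] = (0.0, 0.0)
    dead_cell_fraction: float = 0.0
    micronucleus_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise ValueError("image_shape must be at least 16x16")
        for name in ("late_s_fraction", "dead_cell_fraction", "micronucleus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.foci_rate_lambda < 0:
            raise ValueError("foci_rate_lambda must be >= 0")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.n_frames < 1 or self.n_cells < 0:
            raise ValueError("n_frames >= 1 and n_cells >= 0 required")
        if self.nucleus_radius_mean <= 0 or self.focus_radius <= 0:
            raise ValueError("radii must be positive")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.bleach_halflife <= 0:
            raise ValueError("bleach_halflife must be positive (inf disables)")


@dataclass
class CellTruth:
    """Ground-truth record for one simulated cell."""

    cell_id: int
    viability: str                      # one of VIABILITY_CLASSES
    centroids: np.ndarray               # (n_frames, 2) row/col, float
    radius: float                       # half-max radius, px
    axis_ratio: float                   # minor/major axis, (0, 1]
    theta: float                        # orientation, rad
    brightness: float                   # per-cell nuclear intensity factor
    window: Optional[tuple[int, int]]   # inclusive body-positive frames
    n_foci: int
    foci_offsets: np.ndarray            # (n_foci, 2) offsets from centroid

    def counts(self, n_frames: int) -> np.ndarray:
        c = np.zeros(n_frames, dtype=int)
        if self.window is not None and self.n_foci > 0:
            lo, hi = self.window
            c[lo : hi + 1] = self.n_foci
        return c

    def foci_positions(self, frame: int) -> np.ndarray:
        """Absolute focus centroids active at ``frame`` ((k, 2) array)."""
        if self.window is None or not (self.window[0] <= frame <= self.window[1]):
            return np.empty((0, 2))
        return self.centroids[frame] + self.foci_offsets


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    n_frames: int

    def count_matrix(self) -> np.ndarray:
        """Per-cell true focus counts, shape (n_cells, n_frames)."""
        if not self.cells:
            return np.zeros((0, self.n_frames), dtype=int)
        return np.stack([c.counts(self.n_frames) for c in self.cells])

    def total_foci(self) -> int:
        return int(sum(c.n_foci for c in self.cells if c.window is not None))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            counts = c.counts(self.n_frames)
            for t in range(self.n_frames):
                rows.append(
                    {
                        "cell_id": c.cell_id,
                        "frame": t,
                        "y": c.centroids[t, 0],
                        "x": c.centroids[t, 1],
                        "class": c.viability,
                        "n_foci": int(counts[t]),
                    }
                )
        return pd.DataFrame(
            rows, columns=["cell_id", "frame", "y", "x", "class", "n_foci"]
        )


@dataclass
class TimeLapse:
    """Ordered stack of single-channel frames with physical metadata."""

    frames: np.ndarray          # (T, H, W), float in [0, 1]
    pixel_size: float           # um/px
    frame_interval: float       # min

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def generate_illumination_field(
    shape: tuple[int, int],
    strength: float,
    asymmetry: tuple[float, float] = (0.0, 0.0),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Smooth vignetting gain field with its peak possibly off-center.

    The field equals 1 at its peak and falls off quadratically with
    normalized distance, reaching ``1 - strength`` at the farthest corner.
    ``asymmetry`` shifts the peak by the given fraction of the half-extent
    along (row, col); when ``None`` a small random shift is drawn from
    ``seed``.
    """
    if not 0.0 <= strength < 1.0:
        raise ValueError("strength must lie in [0, 1); >= 1 would zero out pixels")
    h, w = shape
    if asymmetry is None:
        rng = np.random.default_rng(seed)
        asymmetry = tuple(rng.uniform(-0.2, 0.2, size=2))
    cy = (h - 1) / 2.0 * (1.0 + float(asymmetry[0]))
    cx = (w - 1) / 2.0 * (1.0 + float(asymmetry[1]))
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    corners = [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]
    dmax2 = max((y - cy) ** 2 + (x - cx) ** 2 for y, x in corners)
    field = 1.0 - strength * d2 / dmax2
    # grid may miss the analytic peak between pixels; renormalize so the
    # brightest pixel is exactly 1 (the contract downstream relies on)
    field = field / field.max()
    return field


def _add_gaussian(
    img: np.ndarray,
    center: tuple[float, float],
    sigma_y: float,
    sigma_x: float,
    theta: float,
    amplitude: float,
    shape_power: float = 1.0,
) -> None:
    """Add a rotated anisotropic (super-)Gaussian to ``img`` in place.

    ``shape_power`` > 1 flattens the top and steepens the flanks
    (``exp(-(r^2/2)^p)``); nuclei are rendered flat-topped because real
    nucleoplasmic fluorescence is roughly uniform and a curved apex would
    itself survive the foci top-hat filter.
    """
    h, w = img.shape
    ext = 4.0 * max(sigma_y, sigma_x)
    y0 = max(int(center[0] - ext), 0)
    y1 = min(int(center[0] + ext) + 1, h)
    x0 = max(int(center[1] - ext), 0)
    x1 = min(int(center[1] + ext) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - center[0]
    dx = xx - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * dy + st * dx
    v = -st * dy + ct * dx
    r2 = 0.5 * ((u / sigma_y) ** 2 + (v / sigma_x) ** 2)
    img[y0:y1, x0:x1] += amplitude * np.exp(-(r2**shape_power))


#: half-max radius in sigma units for the flat-top (power 2) blob profile
_HALF_MAX_P2 = math.sqrt(2.0) * math.log(2.0) ** 0.25


def _sample_focus_offsets(
    rng: np.random.Generator, n: int, max_radius: float, min_sep: float
) -> np.ndarray:
    """Offsets within ``max_radius`` of the cell center, kept ``min_sep``
    apart so rendered spots stay individually resolvable.

    A single focus lands anywhere in the disk; several foci are placed on
    a randomly rotated, angle-jittered ring whose chord spacing meets the
    (feasibility-capped) separation by construction.
    """
    if n == 1:
        ang = rng.uniform(0.0, 2 * math.pi)
        rad = max_radius * math.sqrt(rng.uniform(0.05, 1.0))
        return np.array([[rad * math.sin(ang), rad * math.cos(ang)]])
    r0 = 0.92 * max_radius
    sep = min(min_sep, 2.0 * r0 * math.sin(math.pi / n))
    theta_min = 2.0 * math.asin(min(1.0, sep / (2.0 * r0))) if r0 > 0 else 0.0
    slack = max(0.0, 2.0 * math.pi / n - theta_min)  # fp guard; >= 0 by the cap
    base = rng.uniform(0.0, 2.0 * math.pi)
    jitter = rng.uniform(-0.5 * slack, 0.5 * slack, size=n)
    angles = base + 2.0 * math.pi * np.arange(n) / n + jitter
    return np.column_stack([r0 * np.sin(angles), r0 * np.cos(angles)])


def _place_positions(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_sep: float,
) -> list[np.ndarray]:
    """Rejection-sample ``n`` points pairwise >= ``min_sep`` apart.

    When the requested separation is too dense to satisfy, it is relaxed
    geometrically (dense truth-only plates tolerate touching nuclei; the
    hard infeasibility case is caught by the caller's area check).
    """
    if n == 0:
        return []
    y0, y1, x0, x1 = bounds
    # cap the separation at a density the sampler can actually achieve
    usable = max(y1 - y0, 1.0) * max(x1 - x0, 1.0)
    sep = min(min_sep, math.sqrt(0.45 * usable / max(n, 1)))
    while True:
        pts = np.empty((n, 2))
        k = 0
        for _ in range(60 * max(n, 1) + 200):
            py = rng.uniform(y0, y1)
            px = rng.uniform(x0, x1)
            if k == 0 or np.hypot(pts[:k, 0] - py, pts[:k, 1] - px).min() >= sep:
                pts[k] = (py, px)
                k += 1
                if k == n:
                    return list(pts)
        sep *= 0.85


def _sample_cells(params: SceneParams, rng: np.random.Generator) -> list[CellTruth]:
    h, w = params.image_shape
    n = params.n_cells
    r = params.nucleus_radius_mean
    margin = 1.6 * r
    min_sep = 2.4 * r
    usable = max(h - 2 * margin, 1.0) * max(w - 2 * margin, 1.0)
    if n > 0 and n * (1.5 * r) ** 2 > usable:
        raise PackingError(
            f"cannot pack {n} cells of radius ~{r:.1f} px into {h}x{w} image"
        )
    positions = _place_positions(rng, n, (margin, h - margin, margin, w - margin), min_sep)

    # viability classes
    classes = ["normal"] * n
    n_dead = int(round(params.dead_cell_fraction * n))
    for i in range(n_dead):
        classes[i] = "dead" if i % 2 == 0 else "mitotic"
    n_micro = int(round(params.micronucleus_fraction * n))
    for i in range(n_dead, min(n_dead + n_micro, n)):
        classes[i] = "micronucleated"
    order = rng.permutation(n)

    cells: list[CellTruth] = []
    T = params.n_frames
    for cid in range(n):
        cls = classes[order[cid]]
        radius = max(3.0, rng.normal(r, params.nucleus_radius_sd))
        if cls in ("dead", "mitotic"):
            radius *= 0.45
            axis_ratio = 1.0
        else:
            axis_ratio = rng.uniform(0.85, 1.0)
        theta = rng.uniform(0.0, math.pi)
        brightness = rng.uniform(0.8, 1.2)
        steps = rng.normal(0.0, params.cell_drift_sd, size=(T - 1, 2)) if T > 1 else np.empty((0, 2))
        path = np.vstack([positions[cid], positions[cid] + np.cumsum(steps, axis=0)]) if T > 1 else positions[cid][None, :]
        path[:, 0] = np.clip(path[:, 0], margin * 0.5, h - margin * 0.5)
        path[:, 1] = np.clip(path[:, 1], margin * 0.5, w - margin * 0.5)

        window = None
        n_foci = 0
        offsets = np.empty((0, 2))
        body_eligible = cls in ("normal", "micronucleated")
        if body_eligible and rng.uniform() < params.late_s_fraction:
            if params.foci_count_fixed is not None:
                n_foci = int(params.foci_count_fixed)
            else:
                n_foci = int(rng.poisson(params.foci_rate_lambda))
            life_min = rng.normal(params.foci_lifetime_mean, params.foci_lifetime_sd)
            life = max(1, int(round(life_min / params.frame_interval)))
            life = min(life, T)
            start = int(rng.integers(0, T - life + 1))
            if n_foci > 0:
                window = (start, start + life - 1)
                offsets = _sample_focus_offsets(
                    rng, n_foci, 0.62 * radius * axis_ratio, 7.5 * params.focus_radius
                )
            else:
                n_foci = 0
        cells.append(
            CellTruth(
                cell_id=cid,
                viability=cls,
                centroids=path,
                radius=radius,
                axis_ratio=axis_ratio,
                theta=theta,
                brightness=brightness,
                window=window,
                n_foci=n_foci,
                foci_offsets=offsets,
            )
        )
    return cells


def _render_frames(
    params: SceneParams, cells: Sequence[CellTruth], rng: np.random.Generator
) -> np.ndarray:
    h, w = params.image_shape
    T = params.n_frames
    field = generate_illumination_field(
        (h, w), params.vignette_strength, params.vignette_asymmetry
    )
    frames = np.empty((T, h, w), dtype=np.float32)
    sig_f = 1.0 / _HALF_MAX      # focus sigma per unit half-max radius
    sig_n = 1.0 / _HALF_MAX_P2   # flat-top nucleus sigma per unit half-max radius
    for t in range(T):
        if math.isinf(params.bleach_halflife):
            bg = params.background_level
        else:
            bg = params.background_level * 2.0 ** (-t / params.bleach_halflife)
        img = np.full((h, w), bg, dtype=np.float64)
        for c in cells:
            cen = tuple(c.centroids[t])
            s_major = c.radius * sig_n
            s_minor = c.radius * c.axis_ratio * sig_n
            if c.viability in ("dead", "mitotic"):
                _add_gaussian(
                    img, cen, s_major, s_minor, c.theta,
                    2.2 * c.brightness * params.nucleus_amplitude, shape_power=2.0,
                )
                # internal speckle: drives up intensity SD and upper quartile
                for oy, ox in ((-0.4, 0.2), (0.3, -0.3), (0.1, 0.45)):
                    _add_gaussian(
                        img,
                        (cen[0] + oy * c.radius, cen[1] + ox * c.radius),
                        1.0,
                        1.0,
                        0.0,
                        1.2 * params.nucleus_amplitude,
                    )
            else:
                _add_gaussian(
                    img, cen, s_major, s_minor, c.theta,
                    c.brightness * params.nucleus_amplitude, shape_power=2.0,
                )
                if c.viability == "micronucleated":
                    my = cen[0] + 1.05 * c.radius * math.cos(c.theta)
                    mx = cen[1] + 1.05 * c.radius * math.sin(c.theta)
                    _add_gaussian(img, (my, mx), 2.0, 2.0, 0.0, params.nucleus_amplitude)
            for fy, fx in c.foci_positions(t):
                _add_gaussian(
                    img,
                    (fy, fx),
                    params.focus_radius * sig_f,
                    params.focus_radius * sig_f,
                    0.0,
                    params.focus_amplitude,
                )
        img *= field
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0.0, 1.0)
    return frames


def render_timelapse(
    params: SceneParams, seed: Optional[int] = None
) -> tuple[TimeLapse, GroundTruth]:
    """Render one field of view and return it with its ground truth.

    Deterministic given ``(params, seed)``; ``seed=None`` falls back to
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cells = _sample_cells(params, rng)
    frames = _render_frames(params, cells, rng)
    return (
        TimeLapse(frames=frames, pixel_size=params.pixel_size, frame_interval=params.frame_interval),
        GroundTruth(cells=cells, n_frames=params.n_frames),
    )


def sample_ground_truth(params: SceneParams, seed: Optional[int] = None) -> GroundTruth:
    """Ground truth only, skipping pixel rendering (fast path for scoring)."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return GroundTruth(cells=_sample_cells(params, rng), n_frames=params.n_frames)


# ---------------------------------------------------------------------------
# plates


@dataclass
class ScenePosition:
    replicate: int
    well: str
    position: int
    sirna: str
    role: str
    params: SceneParams
    truth: GroundTruth
    timelapse: Optional[TimeLapse] = None


@dataclass
class PlateDataset:
    positions: list[ScenePosition] = field(default_factory=list)

    def __iter__(self):
        return iter(self.positions)

    def __len__(self):
        return len(self.positions)


def generate_plate(
    layout,
    base: SceneParams,
    effects: Optional[Mapping[str, float]] = None,
    n_positions: int = 4,
    seed: int = 0,
    n_replicates: int = 1,
    render: bool = True,
) -> PlateDataset:
    """Simulate every non-empty well of ``layout`` at ``n_positions`` fields.

    ``effects`` maps siRNA id -> multiplier applied to ``foci_rate_lambda``
    (negative controls always use multiplier 1).  With ``render=False``
    only ground truth is produced, which is sufficient for score-level
    calibration and orders of magnitude faster.
    """
    effects = dict(effects or {})
    wells = layout.wells
    for well, info in wells.items():
        if info.role not in WELL_ROLES:
            raise ValueError(f"well {well}: unknown role {info.role!r}")
    known = {info.sirna for info in wells.values() if info.role != "empty"}
    unknown = set(effects) - known
    if unknown:
        raise ValueError(f"effects specified for siRNAs absent from layout: {sorted(unknown)}")

    root = np.random.SeedSequence(seed)
    dataset = PlateDataset()
    well_ids = sorted(w for w, info in wells.items() if info.role != "empty")
    children = root.spawn(n_replicates * len(well_ids) * n_positions)
    k = 0
    for rep in range(1, n_replicates + 1):
        for well in well_ids:
            info = wells[well]
            mult = 1.0 if info.role == "sNEG1" else effects.get(info.sirna, 1.0)
            params = replace(base, foci_rate_lambda=base.foci_rate_lambda * mult)
            for pos in range(1, n_positions + 1):
                child_seed = int(children[k].generate_state(1)[0])
                k += 1
                if render:
                    tl, truth = render_timelapse(params, seed=child_seed)
                else:
                    tl, truth = None, sample_ground_truth(params, seed=child_seed)
                dataset.positions.append(
                    ScenePosition(
                        replicate=rep,
                        well=well,
                        position=pos,
                        sirna=info.sirna,
                        role=info.role,
                        params=params,
                        truth=truth,
                        timelapse=tl,
                    )
                )
    return dataset


# ---------------------------------------------------------------------------
# FRAP curves


@dataclass
class FrapCurve:
    times: np.ndarray        # s, sorted, bleach at t = 0
    intensities: np.ndarray
    bleach_index: int        # first post-bleach sample

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.bleach_index :]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.bleach_index :]


def simulate_frap_curve(
    tau: float,
    plateau: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> FrapCurve:
    """Single-exponential recovery ``plateau * (1 - exp(-t/tau))`` after a
    bleach at t = 0, with pre-bleach samples at 1."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be a sorted 1-D vector")
    rng = np.random.default_rng(seed)
    y = np.where(t < 0, 1.0, plateau * (1.0 - np.exp(-np.clip(t, 0, None) / tau)))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    bleach_index = int(np.searchsorted(t, 0.0, side="left"))
    return FrapCurve(times=t, intensities=y, bleach_index=bleach_index)
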