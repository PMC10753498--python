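"""Track-level aggregation: single-frame gap closing of focus-count
series, longest positive run extraction, the mean-count main readout,
and position-level quality control."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tracking import Track

__all__ = [
    "TrackSummary",
    "PositionQC",
    "QCRules",
    "close_gaps",
    "longest_run",
    "summarize_counts",
    "summarize_track",
    "growth_slope",
    "qc_position",
]


@dataclass(frozen=True)
class TrackSummary:
    track_id: int
    track_length: int
    run_start: Optional[int]     # frame index within the track, inclusive
    run_end: Optional[int]
    run_length: int              # 0 if never positive / below persistence
    mean_db_count: float         # mean count within the longest run
    lifetime: float              # run_length * frame_interval, min


@dataclass(frozen=True)
class QCRules:
    """Thresholds for position-level QC; ``None`` disables a rule."""

    min_integrated_intensity: Optional[float] = None
    min_cell_count: Optional[float] = None
    min_growth_slope: Optional[float] = 0.0
    plls_range: Optional[tuple[float, float]] = None
    min_filtered_ratio: Optional[float] = None   # secondary screen only


@dataclass(frozen=True)
class PositionQC:
    position_id: str
    n_tracks: int
    mean_integrated_intensity: float
    mean_cell_count: float
    growth_slope: float
    plls_min: float
    plls_max: float
    filtered_ratio: float
    passed: bool
    failures: tuple[str, ...]


def close_gaps(counts: Sequence[int], fill: str = "previous") -> np.ndarray:
    """Fill single-frame zero gaps between positive focus counts.

    The positivity pattern of the result equals a binary morphological
    closing (two-element structuring element) of the input's positivity
    pattern: exactly the isolated zeros flanked by positive frames are
    filled, and runs separated by two or more empty frames stay separate.
    Filled frames receive the count of the adjacent originally-positive
    frame chosen by ``fill`` ("previous" or "next"); original counts are
    never changed.
    """
    if fill not in ("previous", "next"):
        raise ValueError("fill must be 'previous' or 'next'")
    c = np.asarray(counts, dtype=int)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D sequence")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    out = c.copy()
    for i in range(1, len(c) - 1):
        if c[i] == 0 and c[i - 1] > 0 and c[i + 1] > 0:
            out[i] = c[i - 1] if fill == "previous" else c[i + 1]
    return out


def longest_run(counts: Sequence[int]) -> Optional[tuple[int, int]]:
    """Inclusive (start, end) of the longest run of positive entries.

    Ties are broken toward the earliest start; all-zero input returns
    ``None``.
    """
    c = np.asarray(counts, dtype=int)
    best: Optional[tuple[int, int]] = None
    best_len = 0
    start = None
    for i, v in enumerate(c):
        if v > 0 and start is None:
            start = i
        if (v <= 0 or i == len(c) - 1) and start is not None:
            end = i if (v > 0 and i == len(c) - 1) else i - 1
            if end - start + 1 > best_len:
                best = (start, end)
                best_len = end - start + 1
            start = None
    return best


def summarize_counts(
    counts: Sequence[int],
    frame_interval: float,
    min_persistence: int = 2,
    fill: str = "previous",
) -> tuple[Optional[tuple[int, int]], float, float]:
    """Gap-close, take the longest run, and compute the mean-count readout.

    Returns ``(run, mean_count, lifetime)`` where ``run`` is None (and
    the readout 0) when the longest run is shorter than
    ``min_persistence`` frames.
    """
    closed = close_gaps(counts, fill=fill)
    run = longest_run(closed)
    if run is None or (run[1] - run[0] + 1) < min_persistence:
        return None, 0.0, 0.0
    lo, hi = run
    mean_count = float(closed[lo : hi + 1].mean())
    lifetime = (hi - lo + 1) * frame_interval
    return run, mean_count, lifetime


def summarize_track(
    track: Track,
    frame_interval: float,
    min_persistence: int = 2,
    fill: str = "previous",
) -> TrackSummary:
    if track.length == 0:
        raise ValueError("cannot summarize an empty track")
    run, mean_count, lifetime = summarize_counts(
        track.focus_counts, frame_interval, min_persistence=min_persistence, fill=fill
    )
    if run is None:
        return TrackSummary(
            track_id=track.track_id,
            track_length=track.length,
            run_start=None,
            run_end=None,
            run_length=0,
            mean_db_count=0.0,
            lifetime=0.0,
        )
    return TrackSummary(
        track_id=track.track_id,
        track_length=track.length,
        run_start=run[0],
        run_end=run[1],
        run_length=run[1] - run[0] + 1,
        mean_db_count=mean_count,
        lifetime=lifetime,
    )


def growth_slope(cell_counts: Sequence[float]) -> float:
    """Ordinary least-squares slope of cell count vs frame index."""
    y = np.asarray(cell_counts, dtype=float)
    if y.size < 2:
        raise ValueError("growth slope needs at least 2 frames")
    x = np.arange(y.size, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def qc_position(
    position_id: str,
    n_tracks: int,
    integrated_intensities: Sequence[float],
    cell_counts: Sequence[float],
    plls_values: Sequence[float],
    rules: QCRules,
    filtered_ratio: float = 1.0,
) -> PositionQC:
    """Evaluate the enabled QC rules; ``passed`` is their conjunction."""
    mean_int = float(np.mean(integrated_intensities)) if len(integrated_intensities) else 0.0
    mean_cells = float(np.mean(cell_counts)) if len(cell_counts) else 0.0
    slope = growth_slope(cell_counts) if len(cell_counts) >= 2 else float("nan")
    plls = np.asarray(plls_values, dtype=float)
    plls = plls[~np.isnan(plls)] if plls.size else plls
    plls_min = float(plls.min()) if plls.size else float("nan")
    plls_max = float(plls.max()) if plls.size else float("nan")

    failures: list[str] = []
    if rules.min_integrated_intensity is not None and not (
        mean_int >= rules.min_integrated_intensity
    ):
        failures.append("integrated_intensity")
    if rules.min_cell_count is not None and not (mean_cells >= rules.min_cell_count):
        failures.append("cell_count")
    if rules.min_growth_slope is not None and not (slope >= rules.min_growth_slope):
        failures.append("growth_slope")
    if rules.plls_range is not None:
        lo, hi = rules.plls_range
        if not (lo <= plls_min and plls_max <= hi):
            failures.append("plls")
    if rules.min_filtered_ratio is not None and not (
        filtered_ratio >= rules.min_filtered_ratio
    ):
        failures.append("filtered_ratio")
    return PositionQC(
        position_id=position_id,
        n_tracks=n_tracks,
        mean_integrated_intensity=mean_int,
        mean_cell_count=mean_cells,
        growth_slope=slope,
        plls_min=plls_min,
        plls_max=plls_max,
        filtered_ratio=filtered_ratio,
        passed=not failures,
        failures=tuple(failures),
    )
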