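"""Replicate-wise Z-scoring of position readouts against negative
controls, per-siRNA aggregation, ranking and hit calling.

The readout ``x`` of a position is the mean over its tracks of the
mean-count-in-longest-run statistic.  Per replicate, ``m`` and ``s`` are
the mean and sample standard deviation of ``log2(x + eps)`` over the
negative-control (sNEG1) positions, and every scored position receives
``Z = (log2(x + eps) - m) / s`` using its own replicate's statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionResult",
    "ControlStats",
    "DEFAULT_PSEUDOCOUNT",
    "position_readout",
    "control_stats",
    "zscore_positions",
    "summarize_sirna",
    "call_hits",
]

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0 / 64.0

NEGATIVE_CONTROL_ROLE = "sNEG1"


@dataclass(frozen=True)
class PositionResult:
    replicate: int
    well: str
    position: int
    sirna: str
    role: str
    x: float            # mean over tracks of mean_db_count
    n_tracks: int
    qc_pass: bool

    def __post_init__(self):
        if self.qc_pass and self.x < 0:
            raise ValueError("readout must be non-negative")


@dataclass(frozen=True)
class ControlStats:
    replicate: int
    m: float            # mean of log2(x + eps) over sNEG1 positions
    s: float            # sample (n-1) standard deviation of the same
    n: int


def position_readout(mean_db_counts: Sequence[float]) -> float:
    """Mean over tracks of the per-track mean focus count.

    Tracks without a positive run contribute 0.  An empty input is
    undefined (the position is dropped upstream).
    """
    vals = np.asarray(mean_db_counts, dtype=float)
    if vals.size == 0:
        raise ValueError("position readout undefined with zero tracks")
    return float(vals.mean())


def control_stats(
    positions: Iterable[PositionResult],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[int, ControlStats]:
    """Per-replicate mean/sd of log2 control readouts.

    Replicates with fewer than 2 QC-passing sNEG1 positions, or with zero
    spread, are rejected (omitted with a warning); their positions cannot
    be scored.
    """
    by_rep: dict[int, list[float]] = {}
    for p in positions:
        if p.role == NEGATIVE_CONTROL_ROLE and p.qc_pass:
            by_rep.setdefault(p.replicate, []).append(p.x)
    stats: dict[int, ControlStats] = {}
    for rep, xs in sorted(by_rep.items()):
        if len(xs) < 2:
            log.warning("replicate %s: <2 usable control positions; rejected", rep)
            continue
        logs = np.log2(np.asarray(xs) + pseudocount)
        s = float(logs.std(ddof=1))
        if s == 0:
            log.warning("replicate %s: zero control spread; rejected", rep)
            continue
        stats[rep] = ControlStats(replicate=rep, m=float(logs.mean()), s=s, n=len(xs))
    return stats


def zscore_positions(
    positions: Iterable[PositionResult],
    stats: Mapping[int, ControlStats],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """One row per scored position with its replicate-wise Z-score.

    QC-failing positions and positions from replicates without valid
    control statistics are excluded.
    """
    rows = []
    for p in positions:
        if not p.qc_pass:
            continue
        st = stats.get(p.replicate)
        if st is None:
            log.info("position %s/%s/%s: no control stats for replicate; skipped",
                     p.replicate, p.well, p.position)
            continue
        z = (np.log2(p.x + pseudocount) - st.m) / st.s
        rows.append(
            {
                "replicate": p.replicate,
                "well": p.well,
                "position": p.position,
                "sirna": p.sirna,
                "role": p.role,
                "x": p.x,
                "n_tracks": p.n_tracks,
                "z": float(z),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["replicate", "well", "position", "sirna", "role", "x", "n_tracks", "z"],
    )


def summarize_sirna(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean Z per siRNA over all scored positions across replicates.

    Returns a table sorted by mean Z (descending) with the number of
    contributing Z-scores and a dense rank.
    """
    if rows.empty:
        return pd.DataFrame(columns=["sirna", "role", "mean_z", "n_z", "rank"])
    grp = rows.groupby("sirna", sort=False)
    out = grp.agg(role=("role", "first"), mean_z=("z", "mean"), n_z=("z", "size"))
    out = out.reset_index().sort_values("mean_z", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def call_hits(
    table: pd.DataFrame,
    up_threshold: float = 3.0,
    down_threshold: float = -2.0,
    genes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Classify each siRNA as up / down / none by its mean Z-score.

    Up hits satisfy ``mean_z >= up_threshold``; down hits
    ``mean_z <= down_threshold``.  When ``genes`` maps siRNA -> gene
    symbol, a gene column is attached so callers can roll hits up to
    gene level (a gene qualifies through any of its siRNAs).
    """
    if not up_threshold > down_threshold:
        raise ValueError("up_threshold must exceed down_threshold")
    out = table.copy()
    out["hit"] = "none"
    out.loc[out["mean_z"] >= up_threshold, "hit"] = "up"
    out.loc[out["mean_z"] <= down_threshold, "hit"] = "down"
    if genes is not None:
        out["gene"] = out["sirna"].map(dict(genes))
    return out
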