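"""Frame-to-frame nucleus linking by the simple overlap method."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .foci import FocusObject
from .nuclei import NucleusObject

__all__ = ["Track", "link_frames", "build_tracks"]


@dataclass
class Track:
    """One nucleus followed over strictly consecutive frames."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    nuclei: list[NucleusObject] = field(default_factory=list)
    focus_counts: list[int] = field(default_factory=list)

    def append(self, frame: int, nucleus: NucleusObject, n_foci: int) -> None:
        if self.frames and frame != self.frames[-1] + 1:
            raise ValueError("track frames must be consecutive")
        self.frames.append(frame)
        self.nuclei.append(nucleus)
        self.focus_counts.append(n_foci)

    @property
    def length(self) -> int:
        return len(self.frames)


def _overlap(a: NucleusObject, b: NucleusObject) -> int:
    return int(np.intersect1d(a.pixel_indices(), b.pixel_indices(), assume_unique=True).size)


def link_frames(
    prev: Sequence[NucleusObject],
    curr: Sequence[NucleusObject],
    max_distance: float = 15.0,
) -> dict[int, int]:
    """Greedy one-to-one matching of ``prev`` onto ``curr``.

    Candidate pairs require centroid distance <= ``max_distance`` *and*
    nonzero pixel-set overlap; pairs are consumed in decreasing overlap
    area, ties broken by smaller centroid distance, then by (prev label,
    curr label).  Returns a mapping prev-index -> curr-index.
    """
    candidates = []
    for i, a in enumerate(prev):
        for j, b in enumerate(curr):
            d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
            if d > max_distance:
                continue
            ov = _overlap(a, b)
            if ov == 0:
                continue
            candidates.append((-ov, d, a.label, b.label, i, j))
    candidates.sort()
    matched: dict[int, int] = {}
    used_curr: set[int] = set()
    for _, _, _, _, i, j in candidates:
        if i in matched or j in used_curr:
            continue
        matched[i] = j
        used_curr.add(j)
    return matched


def build_tracks(
    frames: Sequence[Sequence[NucleusObject]],
    foci: Optional[Sequence[Sequence[FocusObject]]] = None,
    max_distance: float = 15.0,
) -> list[Track]:
    """Chain per-frame nuclei into tracks; unmatched nuclei start new ones.

    ``foci`` is an optional per-frame list of detected foci whose
    ``parent_nucleus`` labels are counted into each track's per-frame
    focus count (0 when absent).
    """
    tracks: list[Track] = []
    next_id = 0
    active: dict[int, Track] = {}  # index into previous frame's object list -> track

    def focus_count(t: int, nucleus: NucleusObject) -> int:
        if foci is None:
            return 0
        return sum(1 for f in foci[t] if f.parent_nucleus == nucleus.label)

    prev_objs: list[NucleusObject] = []
    for t, objs in enumerate(frames):
        objs = list(objs)
        if t == 0:
            matching = {}
        else:
            matching = link_frames(prev_objs, objs, max_distance=max_distance)
        new_active: dict[int, Track] = {}
        inv = {j: i for i, j in matching.items()}
        for j, obj in enumerate(objs):
            if j in inv and inv[j] in active:
                tr = active[inv[j]]
            else:
                tr = Track(track_id=next_id)
                next_id += 1
                tracks.append(tr)
            tr.append(t, obj, focus_count(t, obj))
            new_active[j] = tr
        active = new_active
        prev_objs = objs
    return tracks
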