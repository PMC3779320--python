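"""Cell tracking and budding detection on label-mask sequences.

Tracking is greedy nearest-centroid bipartite matching between consecutive
frames: candidate (old, new) region pairs within ``max_displacement`` are
accepted in order of increasing centroid distance, with ties broken by
smaller area difference and then by lower region label.  Unmatched regions
start new tracks.  A new track whose first region is small relative to an
adjacent established cell is recorded as a budding event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

__all__ = ["CellTrack", "BudEvent", "track", "detect_budding",
           "tracks_to_frame", "bud_events_to_frame"]


@dataclass
class CellTrack:
    """One tracked cell: per-frame (frame, label, centroid, area) entries."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)

    def add(self, frame, label, centroid, area):
        self.frames.append(int(frame))
        self.labels.append(int(label))
        self.centroids.append((float(centroid[0]), float(centroid[1])))
        self.areas.append(int(area))

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    def label_at(self, frame: int):
        try:
            return self.labels[self.frames.index(frame)]
        except ValueError:
            return None

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class BudEvent:
    mother_track_id: int
    bud_track_id: int
    frame: int


def _frame_regions(mask: np.ndarray):
    return [(r.label, r.centroid, r.area) for r in regionprops(mask)]


def track(masks: np.ndarray, max_displacement: float = 10.0) -> list[CellTrack]:
    """Track labeled regions through a (n_frames, H, W) mask sequence."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.shape[0] < 1:
        raise ValueError("need at least one frame")

    tracks: list[CellTrack] = []
    # active: list of (track, centroid, area) present in the previous frame
    active: list[tuple[CellTrack, tuple[float, float], int]] = []
    for f in range(masks.shape[0]):
        regions = _frame_regions(masks[f])
        pairs = []
        for ai, (_tr, cen, area) in enumerate(active):
            for ri, (lab, rcen, rarea) in enumerate(regions):
                d = float(np.hypot(cen[0] - rcen[0], cen[1] - rcen[1]))
                if d <= max_displacement:
                    pairs.append((d, abs(area - rarea), lab, ai, ri))
        pairs.sort()
        used_a: set[int] = set()
        used_r: set[int] = set()
        next_active = []
        for d, _da, _lab, ai, ri in pairs:
            if ai in used_a or ri in used_r:
                continue
            used_a.add(ai)
            used_r.add(ri)
            tr = active[ai][0]
            lab, cen, area = regions[ri]
            tr.add(f, lab, cen, area)
            next_active.append((tr, cen, area))
        for ri, (lab, cen, area) in enumerate(regions):
            if ri in used_r:
                continue
            tr = CellTrack(track_id=len(tracks) + 1)
            tr.add(f, lab, cen, area)
            tracks.append(tr)
            next_active.append((tr, cen, area))
        active = next_active
    return tracks


def _region_coords(mask: np.ndarray, label: int) -> np.ndarray:
    return np.column_stack(np.nonzero(mask == label))


def _boundary_distance(mask, label_a, label_b) -> float:
    """Boundary-to-boundary distance between two disjoint regions.

    Computed as the minimum pixel-center distance minus one (touching
    pixels have center distance 1 but boundary distance 0)."""
    a = _region_coords(mask, label_a)
    b = _region_coords(mask, label_b)
    if a.size == 0 or b.size == 0:
        return np.inf
    # regions are small (a few thousand pixels); brute force in blocks
    best = np.inf
    for chunk in np.array_split(a, max(1, a.shape[0] // 512)):
        d2 = ((chunk[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        best = min(best, float(d2.min()))
    return max(0.0, float(np.sqrt(best)) - 1.0)


def detect_budding(tracks: list[CellTrack], masks: np.ndarray,
                   adjacency_distance: float = 3.0,
                   area_ratio: float = 0.3) -> list[BudEvent]:
    """Detect budding events: a new track appearing adjacent to an older,
    larger cell.  The event is timestamped at the bud's first frame."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    events: list[BudEvent] = []
    for tr in tracks:
        f0 = tr.start_frame
        if f0 == 0:
            continue        # present from the start: not a bud
        bud_area = tr.areas[0]
        bud_label = tr.labels[0]
        best = None
        for other in tracks:
            if other is tr or other.start_frame >= f0:
                continue
            lab = other.label_at(f0)
            if lab is None:
                continue
            mother_area = other.areas[other.frames.index(f0)]
            if bud_area >= area_ratio * mother_area:
                continue
            d = _boundary_distance(masks[f0], bud_label, lab)
            if d <= adjacency_distance and (best is None or d < best[0]):
                best = (d, other.track_id)
        if best is not None:
            events.append(BudEvent(best[1], tr.track_id, f0))
    return events


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, lab, (r, c), area in zip(tr.frames, tr.labels, tr.centroids, tr.areas):
            rows.append((tr.track_id, f, lab, r, c, area))
    return pd.DataFrame(rows, columns=["track_id", "frame", "label",
                                       "row", "col", "area"])


def bud_events_to_frame(events: list[BudEvent]) -> pd.DataFrame:
    return pd.DataFrame([(e.mother_track_id, e.bud_track_id, e.frame)
                         for e in events],
                        columns=["mother_track_id", "bud_track_id", "frame"])
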