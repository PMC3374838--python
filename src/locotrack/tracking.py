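"""Frame-to-frame assembly of centroid detections into per-animal tracks.

Each frame, open track heads are matched to the frame's detections by
minimum-total-distance bipartite assignment, gated at ``max_disp``: among
matchings that pair as many admissible (distance <= max_disp) head/detection
pairs as possible, the one with smallest total distance is chosen.  This is
deterministic and order-independent, unlike greedy nearest-neighbour, and
coincides with it whenever animals are far apart.  Unmatched detections
seed new tracks; tracks unmatched for more than ``max_gap`` consecutive
frames are closed.  A bridged gap leaves missing frames inside the track;
kinematics interpolates them before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["Track", "assignment_step", "link_tracks", "filter_tracks"]


@dataclass
class Track:
    """One animal's centroid path.

    ``frames`` are the observed frame indices (strictly increasing, possibly
    with bridged gaps); ``times`` = frames * dt.  ``genotype`` is filled in
    when ground truth or an annotation step provides it.
    """

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    genotype: str | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])


def assignment_step(
    heads: np.ndarray, detections: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """One linking iteration: match track heads to a frame's detections.

    Returns (head_index, detection_index) pairs forming a one-to-one
    matching of maximal admissible cardinality and, among those, minimal
    total Euclidean distance.  Pairs farther apart than ``max_disp`` are
    never matched.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    heads = np.atleast_2d(np.asarray(heads, dtype=float)) if len(heads) else np.empty((0, 2))
    detections = (
        np.atleast_2d(np.asarray(detections, dtype=float)) if len(detections) else np.empty((0, 2))
    )
    if heads.shape[0] == 0 or detections.shape[0] == 0:
        return []
    d = cdist(heads, detections)
    # A forbidden-pair cost exceeding any possible total admissible cost makes
    # linear_sum_assignment first maximize admissible cardinality, then
    # minimize total distance.
    big = (min(d.shape) + 1) * max_disp + 1.0
    cost = np.where(d <= max_disp, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if d[r, c] <= max_disp]


class _OpenTrack:
    __slots__ = ("frames", "xy", "gap")

    def __init__(self, frame: int, xy: np.ndarray):
        self.frames = [frame]
        self.xy = [xy]
        self.gap = 0


def link_tracks(
    frame_detections: list[np.ndarray],
    max_disp: float = 0.5,
    max_gap: int = 2,
    dt: float = 1.0,
    with_diagnostics: bool = False,
):
    """Assemble per-frame detections into tracks.

    ``frame_detections`` is a time-ordered list of (k, 2) centroid arrays
    (mm).  Defaults: ``max_disp`` 0.5 mm per 1 s frame, comfortably above
    the ~0.3 mm/s speed ceiling observed in crawling assays, and
    ``max_gap`` 2 frames.  Tracks shorter than 2 observations are dropped
    (counted as singletons in the diagnostics).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for t, dets in enumerate(frame_detections):
        dets = np.atleast_2d(np.asarray(dets, dtype=float)) if len(dets) else np.empty((0, 2))
        heads = (
            np.array([ot.xy[-1] for ot in open_tracks]) if open_tracks else np.empty((0, 2))
        )
        matches = assignment_step(heads, dets, max_disp)
        matched_heads = {i for i, _ in matches}
        matched_dets = {j for _, j in matches}
        for i, j in matches:
            ot = open_tracks[i]
            ot.frames.append(t)
            ot.xy.append(dets[j])
            ot.gap = 0
        survivors = []
        for i, ot in enumerate(open_tracks):
            if i in matched_heads:
                survivors.append(ot)
                continue
            ot.gap += 1
            if ot.gap > max_gap:
                closed.append(ot)
            else:
                survivors.append(ot)
        open_tracks = survivors
        for j in range(len(dets)):
            if j not in matched_dets:
                open_tracks.append(_OpenTrack(t, dets[j]))
    closed.extend(open_tracks)

    closed.sort(key=lambda ot: (ot.frames[0], ot.xy[0][1], ot.xy[0][0]))
    tracks: list[Track] = []
    n_singletons = 0
    for ot in closed:
        if len(ot.frames) < 2:
            n_singletons += 1
            continue
        frames = np.asarray(ot.frames)
        xy = np.asarray(ot.xy)
        tracks.append(
            Track(
                track_id=len(tracks),
                frames=frames,
                times=frames * dt,
                xs=xy[:, 0],
                ys=xy[:, 1],
            )
        )
    if with_diagnostics:
        total = sum(len(np.atleast_2d(d)) if len(d) else 0 for d in frame_detections)
        diag = {
            "n_detections": total,
            "n_in_tracks": sum(len(tr) for tr in tracks),
            "n_singletons": n_singletons,
            "n_tracks": len(tracks),
        }
        return tracks, diag
    return tracks


def filter_tracks(tracks: list[Track], min_duration_s: float = 30.0) -> list[Track]:
    """Keep exactly the tracks whose duration is >= ``min_duration_s``,
    preserving order.  The 30 s default matches the minimum amount of
    recorded data required for within-track fluctuation statistics."""
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    return [t for t in tracks if t.duration_s >= min_duration_s]
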