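"""Speed/acceleration kinematics and acceleration-event segmentation.

A track's raw speed is the path distance between consecutive centroids
divided by the frame interval.  The working "speed recording" is the mean
over a 5-sample (5 s at 1 Hz) sliding window, which suppresses centroid
jitter; only full windows are emitted.  Acceleration is the first
difference of the smoothed speed.  An acceleration event is a maximal run
of strictly same-sign acceleration samples: its duration is the run length
times dt and its peak is the signed extreme of the run; exact zeros belong
to no event.  Per-track summary statistics (mean speed, intra-track SD,
CV, RMS acceleration, mean event duration, mean peak accel/decel) are the
per-animal quantities the population analysis bins and compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "DEFAULT_WINDOW",
    "AccelEvent",
    "TrackStats",
    "interpolate_gaps",
    "raw_speed",
    "smooth_speed",
    "acceleration",
    "segment_events",
    "track_stats",
    "stats_table",
    "stats_from_speed_trace",
]

DEFAULT_WINDOW = 5  # samples; 5 s at the 1 Hz frame rate


class TrackTooShortError(ValueError):
    """Track has too few samples for the requested computation."""


@dataclass(frozen=True)
class AccelEvent:
    """A maximal same-sign acceleration run."""

    sign: int  # +1 acceleration, -1 deceleration
    start_s: float
    end_s: float
    duration: float  # seconds, run length * dt
    peak: float  # mm/s^2, signed extreme


@dataclass
class TrackStats:
    """Per-track scalar summaries.  Fields that need events (or a nonzero
    mean speed, for the CV) are ``None`` when undefined, never zero."""

    track_id: int
    genotype: str | None
    duration_s: float
    avg_speed: float
    speed_sd: float
    speed_cv: float | None
    rms_accel: float
    mean_event_duration: float | None
    mean_peak_accel: float | None
    mean_peak_decel: float | None
    n_events_pos: int
    n_events_neg: int


def interpolate_gaps(track: Track, dt: float = 1.0) -> Track:
    """Fill bridged dropout gaps by linear interpolation onto the uniform
    frame grid, so that differencing sees a constant dt."""
    frames = track.frames
    full = np.arange(frames[0], frames[-1] + 1)
    if len(full) == len(frames):
        return track
    xs = np.interp(full, frames, track.xs)
    ys = np.interp(full, frames, track.ys)
    return Track(
        track_id=track.track_id,
        frames=full,
        times=full * dt,
        xs=xs,
        ys=ys,
        genotype=track.genotype,
    )


def _uniform_dt(times: np.ndarray) -> float:
    d = np.diff(times)
    if len(d) == 0:
        raise TrackTooShortError("track needs >= 2 positions")
    if not np.allclose(d, d[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform timestamps; interpolate or split the track first")
    return float(d[0])


def raw_speed(track: Track) -> np.ndarray:
    """Per-interval speed: |p(i+1) - p(i)| / dt, mm/s."""
    dt = _uniform_dt(track.times)
    disp = np.hypot(np.diff(track.xs), np.diff(track.ys))
    return disp / dt


def smooth_speed(raw: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sliding-window mean over ``window`` samples, full windows only."""
    raw = np.asarray(raw, dtype=float)
    if len(raw) < window:
        raise TrackTooShortError(
            f"need >= {window} raw speed samples, got {len(raw)}"
        )
    kernel = np.full(window, 1.0 / window)
    return np.convolve(raw, kernel, mode="valid")


def acceleration(smooth: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """First difference of the smoothed speed over dt, mm/s^2."""
    smooth = np.asarray(smooth, dtype=float)
    if len(smooth) < 2:
        raise TrackTooShortError("need >= 2 smoothed samples")
    return np.diff(smooth) / dt


def segment_events(
    accel: np.ndarray, dt: float = 1.0, t0: float = 0.0, zero_tol: float = 1e-12
) -> list[AccelEvent]:
    """Segment an acceleration series into maximal same-sign runs.

    Strictly positive runs are acceleration events, strictly negative runs
    deceleration events; exact zeros terminate runs and belong to neither.
    Samples within ``zero_tol`` of zero (differencing round-off on an
    mm-per-second scale) are treated as exact zeros.  Events are returned
    in start-time order.
    """
    accel = np.asarray(accel, dtype=float).copy()
    accel[np.abs(accel) <= zero_tol] = 0.0
    events: list[AccelEvent] = []
    i, n = 0, len(accel)
    while i < n:
        s = np.sign(accel[i])
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and np.sign(accel[j]) == s:
            j += 1
        run = accel[i:j]
        peak = run.max() if s > 0 else run.min()
        events.append(
            AccelEvent(
                sign=int(s),
                start_s=t0 + i * dt,
                end_s=t0 + j * dt,
                duration=(j - i) * dt,
                peak=float(peak),
            )
        )
        i = j
    return events


def track_stats(
    track: Track,
    window: int = DEFAULT_WINDOW,
    min_duration_s: float = 30.0,
) -> TrackStats:
    """Compute per-track kinematic summaries.

    The track must span at least ``min_duration_s``; bridged gaps are
    interpolated first.  All statistics are computed on the smoothed speed
    (and its first difference); the SD uses the n-1 denominator.
    """
    if track.duration_s < min_duration_s:
        raise TrackTooShortError(
            f"track {track.track_id} spans {track.duration_s:.1f} s < {min_duration_s} s"
        )
    span = track.frames[-1] - track.frames[0]
    dt = float(track.times[-1] - track.times[0]) / span if span else 1.0
    track = interpolate_gaps(track, dt=dt)
    _uniform_dt(track.times)
    v = smooth_speed(raw_speed(track), window)
    a = acceleration(v, dt)
    return _stats_from_series(track.track_id, track.genotype, track.duration_s, v, a, dt)


def _stats_from_series(track_id, genotype, duration_s, v, a, dt) -> TrackStats:
    avg = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    events = segment_events(a, dt)
    pos = [e for e in events if e.sign > 0]
    neg = [e for e in events if e.sign < 0]
    return TrackStats(
        track_id=track_id,
        genotype=genotype,
        duration_s=float(duration_s),
        avg_speed=avg,
        speed_sd=sd,
        speed_cv=(sd / avg) if avg > 0 else None,
        rms_accel=float(np.sqrt(np.mean(a**2))),
        mean_event_duration=float(np.mean([e.duration for e in events])) if events else None,
        mean_peak_accel=float(np.mean([e.peak for e in pos])) if pos else None,
        mean_peak_decel=float(np.mean([e.peak for e in neg])) if neg else None,
        n_events_pos=len(pos),
        n_events_neg=len(neg),
    )


def stats_from_speed_trace(
    speeds: np.ndarray,
    dt: float = 1.0,
    window: int = DEFAULT_WINDOW,
    track_id: int = 0,
    genotype: str | None = None,
) -> TrackStats:
    """Per-track statistics straight from a raw speed series (e.g. a
    simulated ground-truth trace), bypassing positions."""
    v = smooth_speed(np.asarray(speeds, dtype=float), window)
    a = acceleration(v, dt)
    return _stats_from_series(track_id, genotype, len(speeds) * dt, v, a, dt)


def stats_table(stats: list[TrackStats]) -> pd.DataFrame:
    """Tabulate TrackStats for TSV export / population analysis."""
    return pd.DataFrame(
        [
            {
                "track_id": s.track_id,
                "genotype": s.genotype,
                "duration_s": s.duration_s,
                "avg_speed": s.avg_speed,
                "speed_sd": s.speed_sd,
                "speed_cv": s.speed_cv,
                "rms_accel": s.rms_accel,
                "mean_event_duration": s.mean_event_duration,
                "mean_peak_accel": s.mean_peak_accel,
                "mean_peak_decel": s.mean_peak_decel,
                "n_events_pos": s.n_events_pos,
                "n_events_neg": s.n_events_neg,
            }
            for s in stats
        ]
    )
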