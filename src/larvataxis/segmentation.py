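"""Segmentation of midline trajectories into runs, reorientations and pauses.

A track is a time series of body midlines (tail→head, cm).  Frames where the
body is aligned (bend below the start threshold) and the smoothed centroid
speed exceeds a per-animal threshold form run candidates; maximal candidate
intervals at least ``min_run_s`` long become :class:`Run` events, everything
else becomes a :class:`Reorientation`.  Within a reorientation, head sweeps
are tracked with a hysteresis state machine on the signed body-bend angle: a
sweep starts when |bend| exceeds ``bend_start_deg`` and ends when |bend|
drops below ``bend_end_deg``, the head swings to the other side of the body,
or a new run starts.  The last sweep of a reorientation that is immediately
followed by a run is labeled ``accepted``; other sweeps are ``rejected``.  A
sweep cut off by the end of the track is labeled ``truncated`` and is
excluded from acceptance-rate statistics.

Headings are arena-frame angles in degrees (CCW from +x); conversion to the
light-relative compass happens in :mod:`larvataxis.metrics`.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Union

import numpy as np

from .stimulus import wrap_angle

__all__ = [
    "SegmentationError",
    "DegenerateMidlineError",
    "TrackPoint",
    "Track",
    "SegmentationParams",
    "Run",
    "HeadSweep",
    "Reorientation",
    "body_bend_angle",
    "bend_angles",
    "smoothed_speed",
    "estimate_speed_threshold",
    "segment_track",
    "filter_tracks",
]


class SegmentationError(ValueError):
    pass


class DegenerateMidlineError(SegmentationError):
    """All midline points coincide; no body axis can be fitted."""


@dataclass
class TrackPoint:
    """One frame of one animal: time and the body midline (tail→head, cm)."""

    t: float
    midline: np.ndarray  # (m, 2)

    def __post_init__(self):
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 2 or self.midline.shape[0] < 3 or self.midline.shape[1] != 2:
            raise SegmentationError("midline must be an (m>=3, 2) array")
        if not np.all(np.isfinite(self.midline)):
            raise SegmentationError("midline points must be finite")

    @property
    def centroid(self) -> np.ndarray:
        return self.midline.mean(axis=0)


@dataclass
class Track:
    """Time-ordered midline samples of one animal.

    Attributes
    ----------
    id : str
    t : ndarray (n,)
        Frame times in seconds, strictly increasing.
    midline : ndarray (n, m, 2)
        Midline points per frame, tail→head, cm.
    experiment_id : str
    """

    id: str
    t: np.ndarray
    midline: np.ndarray
    experiment_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 3 or self.midline.shape[0] != self.t.shape[0]:
            raise SegmentationError("midline must be (n_frames, m_points, 2)")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise SegmentationError(f"track {self.id}: time not strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def centroid(self) -> np.ndarray:
        return self.midline.mean(axis=1)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def path_length_cm(self) -> float:
        c = self.centroid
        return float(np.sum(np.hypot(*(np.diff(c, axis=0).T)))) if len(c) > 1 else 0.0

    def point(self, i: int) -> TrackPoint:
        return TrackPoint(float(self.t[i]), self.midline[i])

    def sliced(self, mask_or_slice) -> "Track":
        return Track(self.id, self.t[mask_or_slice], self.midline[mask_or_slice],
                     self.experiment_id)


@dataclass
class SegmentationParams:
    """Thresholds for event segmentation and track-level filtering."""

    bend_start_deg: float = 20.0
    bend_end_deg: float = 10.0
    min_run_s: float = 1.0
    min_track_len_cm: float = 0.5
    min_track_dur_s: float = 30.0
    discard_initial_s: float = 60.0
    # per-animal speed-threshold estimation
    threshold_window_s: float = 0.5
    threshold_scale: float = 0.5
    threshold_refine_scale: float = 0.5
    threshold_max_iter: int = 3
    speed_smooth_frames: int = 5
    # heading estimation window at run endpoints
    endpoint_window_s: float = 0.5

    def __post_init__(self):
        if not (0 < self.bend_end_deg < self.bend_start_deg):
            raise SegmentationError("need 0 < bend_end_deg < bend_start_deg")
        for name in ("min_run_s", "min_track_len_cm", "min_track_dur_s",
                     "threshold_window_s", "threshold_scale",
                     "threshold_refine_scale", "endpoint_window_s"):
            if getattr(self, name) <= 0:
                raise SegmentationError(f"{name} must be positive")
        if self.discard_initial_s < 0:
            raise SegmentationError("discard_initial_s must be >= 0")


@dataclass
class Run:
    """Forward locomotion with head and body aligned, above the speed threshold."""

    t_start: float
    t_end: float
    i_start: int
    i_end: int
    start_heading: float
    end_heading: float
    mean_heading: float
    path_length_cm: float
    mean_speed: float
    mean_velocity: tuple
    n_frames: int

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class HeadSweep:
    """One lateral head excursion within a reorientation."""

    t_start: float
    t_end: float
    side: str  # 'left' | 'right'
    max_bend_deg: float
    outcome: str  # 'accepted' | 'rejected' | 'truncated'
    ordinal: int
    heading_before: float  # arena deg (NaN if no preceding run)
    max_heading: float  # arena deg of the anterior body half at peak bend


@dataclass
class Reorientation:
    """Slow/no locomotion; a turn if it contains head sweeps, else a pause."""

    t_start: float
    t_end: float
    i_start: int
    i_end: int
    sweeps: List[HeadSweep] = dc_field(default_factory=list)
    prior_heading: float = float("nan")
    new_heading: float = float("nan")

    @property
    def kind(self) -> str:
        return "turn" if self.sweeps else "pause"

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


Event = Union[Run, Reorientation]


def _tls_direction(points: np.ndarray) -> np.ndarray:
    """Total-least-squares direction of (n_frames, k, 2) point sets.

    Closed-form orientation of the principal axis of each frame's points,
    oriented to agree with the first→last point ordering (tail→head).
    """
    c = points.mean(axis=1, keepdims=True)
    x = points - c
    sxx = np.sum(x[..., 0] ** 2, axis=1)
    syy = np.sum(x[..., 1] ** 2, axis=1)
    sxy = np.sum(x[..., 0] * x[..., 1], axis=1)
    ang = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    d = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    ref = points[:, -1, :] - points[:, 0, :]
    flip = np.sum(d * ref, axis=-1) < 0
    d[flip] *= -1.0
    return d


def bend_angles(track: Track):
    """Signed body-bend angle and half-axis angles for every frame.

    Returns ``(signed_bend, anterior_angle, posterior_angle)`` in degrees;
    bend is positive when the head points to the animal's left of the body
    axis.  The midline is split at the middle sample (shared vertex for an
    odd point count) and each half gets a total-least-squares line fit.
    """
    m = track.midline.shape[1]
    if m < 3:
        raise SegmentationError("need >= 3 midline points")
    half = m // 2
    post = track.midline[:, : half + 1 if m % 2 else half, :]
    ant = track.midline[:, half:, :]
    dp = _tls_direction(post)
    da = _tls_direction(ant)
    cross = dp[:, 0] * da[:, 1] - dp[:, 1] * da[:, 0]
    dot = np.sum(dp * da, axis=-1)
    signed = np.degrees(np.arctan2(cross, dot))
    ant_ang = np.degrees(np.arctan2(da[:, 1], da[:, 0]))
    post_ang = np.degrees(np.arctan2(dp[:, 1], dp[:, 0]))
    return signed, ant_ang, post_ang


def body_bend_angle(point: TrackPoint, signed: bool = False) -> float:
    """Body-bend angle of a single frame, degrees in [0, 180).

    With ``signed=True`` the angle is positive when the head deviates to the
    animal's left.  Raises :class:`DegenerateMidlineError` if all midline
    points coincide.
    """
    mid = point.midline
    if np.allclose(mid, mid[0]):
        raise DegenerateMidlineError("all midline points coincide")
    tr = Track("_", np.array([0.0]), mid[None, :, :])
    s, _, _ = bend_angles(tr)
    return float(s[0]) if signed else float(abs(s[0]))


def smoothed_speed(track: Track, params: SegmentationParams) -> np.ndarray:
    """Centroid speed (cm/s) per frame, moving-average smoothed."""
    c = track.centroid
    n = len(c)
    if n < 2:
        return np.zeros(n)
    d = np.hypot(*(np.diff(c, axis=0).T))
    sp = np.empty(n)
    sp[:-1] = d / np.diff(track.t)
    sp[-1] = sp[-2]
    k = max(1, int(params.speed_smooth_frames))
    if k > 1:
        kernel = np.ones(k) / k
        # edge-padded so constant-speed tracks stay exactly constant
        padded = np.concatenate([np.full(k // 2, sp[0]), sp, np.full(k - 1 - k // 2, sp[-1])])
        sp = np.convolve(padded, kernel, mode="valid")
    return sp


def _true_intervals(mask: np.ndarray):
    """Maximal [i0, i1] (inclusive) intervals where mask is True."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _window_heading(c: np.ndarray, t: np.ndarray, i0: int, i1: int,
                    window_s: float, from_start: bool) -> float:
    """Heading (arena deg) of net displacement over the first/last window of [i0, i1]."""
    if from_start:
        j = int(np.searchsorted(t, t[i0] + window_s, side="right") - 1)
        j = min(max(j, i0 + 1), i1)
        v = c[j] - c[i0]
    else:
        j = int(np.searchsorted(t, t[i1] - window_s, side="left"))
        j = max(min(j, i1 - 1), i0)
        v = c[i1] - c[j]
    if np.hypot(v[0], v[1]) == 0:
        v = c[i1] - c[i0]
    if np.hypot(v[0], v[1]) == 0:
        return float("nan")
    return math.degrees(math.atan2(v[1], v[0]))


def _posterior_centroid(track: Track) -> np.ndarray:
    """Mean of the posterior-half midline points per frame.

    Headings are derived from this point rather than the full-body centroid:
    the rear half barely moves during head sweeps, so run endpoint headings
    are not dragged toward the side of an incipient sweep.
    """
    m = track.midline.shape[1]
    half = m // 2
    return track.midline[:, : half + 1 if m % 2 else half, :].mean(axis=1)


def _build_run(track: Track, params: SegmentationParams, i0: int, i1: int) -> Run:
    c = track.centroid
    pc = _posterior_centroid(track)
    t = track.t
    d = np.diff(c[i0:i1 + 1], axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    path = float(steps.sum())
    dur = float(t[i1] - t[i0])
    disp = c[i1] - c[i0]
    dp = np.diff(pc[i0:i1 + 1], axis=0)
    psteps = np.hypot(dp[:, 0], dp[:, 1])
    nz = psteps > 0
    if nz.any():
        ux = (dp[nz, 0] / psteps[nz]).mean()
        uy = (dp[nz, 1] / psteps[nz]).mean()
        mean_heading = math.degrees(math.atan2(uy, ux))
    else:
        mean_heading = float("nan")
    return Run(
        t_start=float(t[i0]), t_end=float(t[i1]), i_start=i0, i_end=i1,
        start_heading=_window_heading(pc, t, i0, i1, params.endpoint_window_s, True),
        end_heading=_window_heading(pc, t, i0, i1, params.endpoint_window_s, False),
        mean_heading=mean_heading,
        path_length_cm=path,
        mean_speed=path / dur if dur > 0 else 0.0,
        mean_velocity=(float(disp[0] / dur), float(disp[1] / dur)) if dur > 0 else (0.0, 0.0),
        n_frames=i1 - i0 + 1,
    )


def _detect_sweeps(signed_bend, ant_ang, t, i0, i1, params) -> List[HeadSweep]:
    sweeps: List[HeadSweep] = []
    cur_start = cur_side = None
    cur_max = 0.0
    cur_max_i = -1

    def close(end_i):
        sweeps.append(HeadSweep(
            t_start=float(t[cur_start]), t_end=float(t[end_i]),
            side="left" if cur_side > 0 else "right",
            max_bend_deg=float(cur_max),
            outcome="rejected", ordinal=len(sweeps) + 1,
            heading_before=float("nan"),
            max_heading=float(ant_ang[cur_max_i]),
        ))

    for i in range(i0, i1 + 1):
        b = signed_bend[i]
        ab = abs(b)
        if cur_start is None:
            if ab > params.bend_start_deg:
                cur_start, cur_side, cur_max, cur_max_i = i, (1 if b > 0 else -1), ab, i
        else:
            if ab < params.bend_end_deg:
                close(i)
                cur_start = None
            elif (b > 0) != (cur_side > 0):
                # head swings to the other side of the body
                close(i)
                cur_start = None
                if ab > params.bend_start_deg:
                    cur_start, cur_side, cur_max, cur_max_i = i, (1 if b > 0 else -1), ab, i
            elif ab > cur_max:
                cur_max, cur_max_i = ab, i
    if cur_start is not None:
        close(i1)
    return sweeps


def segment_track(track: Track, params: Optional[SegmentationParams] = None,
                  threshold: Optional[float] = None) -> List[Event]:
    """Partition a track into Run and Reorientation events.

    Every frame belongs to exactly one event.  ``threshold`` is the
    per-animal run speed threshold (cm/s); if omitted it is estimated with
    :func:`estimate_speed_threshold`.
    """
    params = params or SegmentationParams()
    n = len(track)
    if n == 0:
        return []
    if threshold is None:
        threshold = estimate_speed_threshold(track, params)
    signed_bend, ant_ang, _ = bend_angles(track)
    sp = smoothed_speed(track, params)
    eligible = (np.abs(signed_bend) < params.bend_start_deg) & (sp >= threshold)

    run_ivs = [(a, b) for a, b in _true_intervals(eligible)
               if track.t[b] - track.t[a] >= params.min_run_s - 1e-9]

    events: List[Event] = []
    pos = 0
    for (a, b) in run_ivs:
        if a > pos:
            events.append(_build_reorientation(track, params, signed_bend, ant_ang, pos, a - 1))
        events.append(_build_run(track, params, a, b))
        pos = b + 1
    if pos <= n - 1:
        events.append(_build_reorientation(track, params, signed_bend, ant_ang, pos, n - 1))

    _label_neighbors_and_outcomes(events, track, params)
    return events


def _build_reorientation(track, params, signed_bend, ant_ang, i0, i1) -> Reorientation:
    sweeps = _detect_sweeps(signed_bend, ant_ang, track.t, i0, i1, params)
    return Reorientation(
        t_start=float(track.t[i0]), t_end=float(track.t[i1]),
        i_start=i0, i_end=i1, sweeps=sweeps,
    )


def _label_neighbors_and_outcomes(events: List[Event], track: Track,
                                  params: SegmentationParams) -> None:
    for k, ev in enumerate(events):
        if not isinstance(ev, Reorientation):
            continue
        prev_run = events[k - 1] if k > 0 and isinstance(events[k - 1], Run) else None
        next_run = events[k + 1] if k + 1 < len(events) and isinstance(events[k + 1], Run) else None
        ev.prior_heading = prev_run.end_heading if prev_run else float("nan")
        ev.new_heading = next_run.start_heading if next_run else float("nan")
        for sw in ev.sweeps:
            sw.heading_before = ev.prior_heading
        if ev.sweeps:
            last = ev.sweeps[-1]
            if next_run is not None:
                last.outcome = "accepted"
            elif (k == len(events) - 1
                  and track.t[-1] - last.t_end < params.min_run_s):
                # acceptance requires observing a following run, which needs
                # at least min_run_s of data after the sweep — undecidable
                last.outcome = "truncated"


def estimate_speed_threshold(track: Track, params: Optional[SegmentationParams] = None) -> float:
    """Per-animal run/turn speed threshold (cm/s).

    Iterative scheme: a provisional threshold (``threshold_scale`` × median
    smoothed speed) seeds a segmentation; the threshold is then re-estimated
    as ``threshold_refine_scale`` × the mean smoothed speed in windows of
    ``threshold_window_s`` immediately before and after each detected
    reorientation, and the loop repeats up to ``threshold_max_iter`` times.
    Falls back to the provisional value (with a warning) when no
    reorientations are found.
    """
    params = params or SegmentationParams()
    sp = smoothed_speed(track, params)
    if len(sp) == 0:
        return 0.0
    provisional = params.threshold_scale * float(np.median(sp))
    thr = provisional
    t = track.t
    for _ in range(params.threshold_max_iter):
        events = segment_track(track, params, thr)
        reos = [e for e in events if isinstance(e, Reorientation)]
        if not reos:
            if thr == provisional:
                warnings.warn(
                    f"track {track.id}: no reorientations found; "
                    "falling back to provisional speed threshold")
            return thr
        sel = np.zeros(len(t), dtype=bool)
        w = params.threshold_window_s
        for r in reos:
            sel |= (t >= r.t_start - w) & (t < r.t_start)
            sel |= (t > r.t_end) & (t <= r.t_end + w)
        if not sel.any():
            return thr
        new = params.threshold_refine_scale * float(sp[sel].mean())
        if abs(new - thr) < 1e-12:
            return new
        thr = new
    return thr


def filter_tracks(tracks: List[Track], params: Optional[SegmentationParams] = None) -> List[Track]:
    """Apply track-level filters.

    Drops all data before ``discard_initial_s`` of the experiment, then
    removes tracks shorter than ``min_track_len_cm`` of path or
    ``min_track_dur_s`` of duration.
    """
    params = params or SegmentationParams()
    out = []
    for tr in tracks:
        kept = tr.sliced(tr.t >= params.discard_initial_s)
        if len(kept) < 2:
            continue
        if kept.duration_s < params.min_track_dur_s:
            continue
        if kept.path_length_cm < params.min_track_len_cm:
            continue
        out.append(kept)
    return out
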