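"""Navigational parameters computed from segmented events plus a stimulus.

All functions accept the event lists produced by
:func:`larvataxis.segmentation.segment_track`.  Directional metrics need a
:class:`~larvataxis.stimulus.DirectionalField` to map arena-frame headings
onto the light-relative compass; temporal metrics need a
:class:`~larvataxis.stimulus.TemporalRamp` for phase assignment.  Binary
outcomes are reported as :class:`BinaryRate` (percentage with the binomial
SEM sqrt(p·(100−p))/sqrt(n)).

Continuous metrics are aggregated per experiment first; grand means across
experiments are means of the per-experiment means.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .segmentation import HeadSweep, Reorientation, Run, Track
from .stimulus import (DirectionalField, TemporalRamp, bin2, bin4,
                       compass_from_arena_angle, wrap_angle)

__all__ = [
    "MetricsError",
    "UndefinedIndexError",
    "BinaryRate",
    "binary_sem",
    "navigation_index",
    "first_sweep_direction",
    "first_sweep_left_rate",
    "turn_direction",
    "run_heading_change",
    "mean_run_heading_change",
    "combined_away_steering",
    "steering_magnitude_by_phase",
    "acceptance_rate",
    "turn_size",
    "turn_size_by_phase",
    "turn_size_delta",
    "turn_rate",
    "turn_rate_delta",
    "head_sweep_size",
    "mean_sweep_size_by_outcome",
    "run_speed",
    "mean_run_speed",
    "mirror_tracks",
    "MetricsReport",
    "compute_report",
]


class MetricsError(ValueError):
    pass


class UndefinedIndexError(MetricsError):
    """Navigation index is undefined (zero mean run speed)."""


def binary_sem(p_percent: float, n: int) -> float:
    """SEM of binary choice data, in percentage points: sqrt(p(100−p))/sqrt(n)."""
    if n <= 0:
        raise MetricsError("n must be positive")
    return math.sqrt(p_percent * (100.0 - p_percent)) / math.sqrt(n)


@dataclass(frozen=True)
class BinaryRate:
    """Count of focal events ``k`` out of ``n``, as a percentage with SEM."""

    k: int
    n: int

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise MetricsError("need 0 <= k <= n")

    @property
    def p(self) -> float:
        return 100.0 * self.k / self.n if self.n else float("nan")

    @property
    def sem(self) -> float:
        return binary_sem(self.p, self.n) if self.n else float("nan")


def _turns(events: Iterable) -> List[Reorientation]:
    return [e for e in events if isinstance(e, Reorientation) and e.kind == "turn"]


def _runs(events: Iterable) -> List[Run]:
    return [e for e in events if isinstance(e, Run)]


def navigation_index(runs: Iterable[Run], field: DirectionalField) -> float:
    """Mean run velocity component toward the light ÷ mean run speed.

    +1 when all runs head straight toward the light, −1 straight away, 0 for
    unbiased navigation.  Frame-weighted across runs (equivalently, each run
    contributes its displacement and path length).
    """
    runs = list(runs)
    if not runs:
        raise UndefinedIndexError("no runs")
    u = field.light_direction
    num = 0.0
    den = 0.0
    for r in runs:
        dur = r.duration_s
        num += dur * (r.mean_velocity[0] * u[0] + r.mean_velocity[1] * u[1])
        den += dur * r.mean_speed
    if den == 0.0:
        raise UndefinedIndexError("zero mean run speed")
    return num / den


def first_sweep_direction(events: Iterable, field: DirectionalField,
                          bin_mode: str = "perpendicular_bins",
                          ) -> Tuple[BinaryRate, int]:
    """Away-from-light rate of first head sweeps.

    ``perpendicular_bins``: only turns whose prior heading lies in the ±90°
    bins count; heading +90° a left sweep is away from the light, heading
    −90° a right sweep is away.  ``half_disks``: prior heading in the
    positive half disk makes a left sweep away; the negative half inverts.
    Returns ``(away_rate, n_skipped)`` where skipped counts events whose
    prior heading falls outside the admissible bins or is unknown.
    """
    if bin_mode not in ("perpendicular_bins", "half_disks"):
        raise MetricsError("bin_mode must be 'perpendicular_bins' or 'half_disks'")
    k_away = n = skipped = 0
    for reo in _turns(events):
        sweep = reo.sweeps[0]
        if math.isnan(reo.prior_heading):
            skipped += 1
            continue
        theta = compass_from_arena_angle(reo.prior_heading, field)
        if bin_mode == "perpendicular_bins":
            b = bin4(theta)
            if b == "plus90":
                away = sweep.side == "left"
            elif b == "minus90":
                away = sweep.side == "right"
            else:
                skipped += 1
                continue
        else:
            away = (sweep.side == "left") == (bin2(theta) == "positive_half")
        n += 1
        k_away += int(away)
    return BinaryRate(k_away, n), skipped


def first_sweep_left_rate(events: Iterable, field: DirectionalField,
                          prior_bin: str = "toward") -> Tuple[BinaryRate, int]:
    """Left-sweep rate of first head sweeps whose prior heading is in a bin.

    Used for lateralized comparisons (e.g. unilateral eye ablation) where
    the question is left vs right rather than toward vs away.
    """
    k_left = n = skipped = 0
    for reo in _turns(events):
        if math.isnan(reo.prior_heading):
            skipped += 1
            continue
        theta = compass_from_arena_angle(reo.prior_heading, field)
        if bin4(theta) != prior_bin:
            skipped += 1
            continue
        n += 1
        k_left += int(reo.sweeps[0].side == "left")
    return BinaryRate(k_left, n), skipped


def turn_direction(events: Iterable, field: DirectionalField,
                   prior_bin: str = "perpendicular") -> Tuple[BinaryRate, int]:
    """Turn-direction rate.

    ``perpendicular``: for turns whose prior heading is in the ±90° bins,
    returns the away-from-light rate (heading +90° a counterclockwise turn
    is away; heading −90° a clockwise turn is away).  ``toward``: for turns
    whose prior heading is in the toward bin, returns the left-turn rate.
    Turns with zero net heading change are excluded (counted as skipped).
    """
    if prior_bin not in ("perpendicular", "toward"):
        raise MetricsError("prior_bin must be 'perpendicular' or 'toward'")
    k = n = skipped = 0
    for reo in _turns(events):
        if math.isnan(reo.prior_heading) or math.isnan(reo.new_heading):
            skipped += 1
            continue
        dtheta = wrap_angle(reo.new_heading - reo.prior_heading)
        if dtheta == 0.0:
            skipped += 1
            continue
        theta = compass_from_arena_angle(reo.prior_heading, field)
        b = bin4(theta)
        if prior_bin == "perpendicular":
            if b == "plus90":
                focal = dtheta > 0  # counterclockwise = away
            elif b == "minus90":
                focal = dtheta < 0  # clockwise = away
            else:
                skipped += 1
                continue
        else:
            if b != "toward":
                skipped += 1
                continue
            focal = dtheta > 0  # left turns
        n += 1
        k += int(focal)
    return BinaryRate(k, n), skipped


def run_heading_change(run: Run) -> float:
    """Signed heading change over a run, degrees, left (CCW) positive."""
    return wrap_angle(run.end_heading - run.start_heading)


def _runs_in_bin(runs, field, bin_label):
    out = []
    for r in runs:
        if math.isnan(r.mean_heading) or math.isnan(r.start_heading) or math.isnan(r.end_heading):
            continue
        if bin4(compass_from_arena_angle(r.mean_heading, field)) == bin_label:
            out.append(r)
    return out


def mean_run_heading_change(runs: Iterable[Run], field: DirectionalField,
                            bin_label: str) -> Tuple[float, int]:
    """Mean signed heading change of runs whose mean heading lies in a compass bin."""
    sel = _runs_in_bin(runs, field, bin_label)
    if not sel:
        return float("nan"), 0
    vals = [run_heading_change(r) for r in sel]
    return float(np.mean(vals)), len(vals)


def combined_away_steering(runs: Iterable[Run], field: DirectionalField) -> Tuple[float, int]:
    """Run steering pooled over the ±90° bins with away-from-light positive.

    In the +90° bin a leftward (positive) change is away from the light; in
    the −90° bin the sign is flipped before pooling.
    """
    runs = list(runs)
    vals = [run_heading_change(r) for r in _runs_in_bin(runs, field, "plus90")]
    vals += [-run_heading_change(r) for r in _runs_in_bin(runs, field, "minus90")]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def steering_magnitude_by_phase(runs: Iterable[Run], ramp: TemporalRamp,
                                ) -> Dict[str, Tuple[float, int]]:
    """Mean |heading change| of runs per ramp phase (runs binned by start time)."""
    by_phase = {"increase": [], "decrease": []}
    for r in runs:
        if math.isnan(r.start_heading) or math.isnan(r.end_heading):
            continue
        ph = ramp.phase(r.t_start) if r.t_start < ramp.total_s else "excluded"
        if ph in by_phase:
            by_phase[ph].append(abs(run_heading_change(r)))
    return {ph: (float(np.mean(v)) if v else float("nan"), len(v))
            for ph, v in by_phase.items()}


def _first_sweeps(events) -> List[HeadSweep]:
    return [reo.sweeps[0] for reo in _turns(events)]


def acceptance_rate(events: Iterable, ramp: TemporalRamp) -> Dict[str, BinaryRate]:
    """Per-phase acceptance rate of first head sweeps.

    Phase is assigned from the sweep start time; sweeps in excluded windows
    (hold plateaus ± margin) and truncated sweeps are dropped.
    """
    counts = {"increase": [0, 0], "decrease": [0, 0]}
    for sw in _first_sweeps(events):
        if sw.outcome == "truncated":
            continue
        if not (0.0 <= sw.t_start < ramp.total_s):
            continue
        ph = ramp.phase(sw.t_start)
        if ph not in counts:
            continue
        counts[ph][1] += 1
        counts[ph][0] += int(sw.outcome == "accepted")
    return {ph: BinaryRate(k, n) for ph, (k, n) in counts.items()}


def turn_size(reorientation: Reorientation) -> float:
    """|wrapped heading difference| between the pre-turn and post-turn run, deg."""
    if math.isnan(reorientation.prior_heading) or math.isnan(reorientation.new_heading):
        return float("nan")
    return abs(wrap_angle(reorientation.new_heading - reorientation.prior_heading))


def turn_size_by_phase(events: Iterable, ramp: TemporalRamp) -> Dict[str, Tuple[float, int]]:
    """Mean turn size per ramp phase (turns binned by their start time)."""
    by_phase = {"increase": [], "decrease": []}
    for reo in _turns(events):
        ts = turn_size(reo)
        if math.isnan(ts):
            continue
        if not (0.0 <= reo.t_start < ramp.total_s):
            continue
        ph = ramp.phase(reo.t_start)
        if ph in by_phase:
            by_phase[ph].append(ts)
    return {ph: (float(np.mean(v)) if v else float("nan"), len(v))
            for ph, v in by_phase.items()}


def turn_size_delta(events: Iterable, ramp: TemporalRamp) -> float:
    """Mean turn size in the increase phase minus the decrease phase, deg."""
    by_phase = turn_size_by_phase(events, ramp)
    return by_phase["increase"][0] - by_phase["decrease"][0]


def _phase_seconds(ramp: TemporalRamp, t0: float, t1: float, dt: float = 0.05) -> Dict[str, float]:
    """Total seconds labeled increase/decrease within [t0, t1)."""
    t1 = min(t1, ramp.total_s)
    if t1 <= t0:
        return {"increase": 0.0, "decrease": 0.0}
    grid = np.arange(t0, t1 - 1e-9, dt)
    codes = ramp.phase_code(grid)
    return {"increase": float(np.sum(codes == 1) * dt),
            "decrease": float(np.sum(codes == -1) * dt)}


def _mean_animals_in_phase(tracks: List[Track], ramp: TemporalRamp, phase: str,
                           t0: float, t1: float, dt: float = 0.05) -> float:
    secs = _phase_seconds(ramp, t0, t1, dt)[phase]
    if secs == 0.0:
        return float("nan")
    want = 1 if phase == "increase" else -1
    total = 0.0
    for tr in tracks:
        lo, hi = max(tr.t[0], t0), min(tr.t[-1], min(t1, ramp.total_s))
        if hi <= lo:
            continue
        grid = np.arange(lo, hi - 1e-9, dt)
        total += float(np.sum(ramp.phase_code(grid) == want) * dt)
    return total / secs


def turn_rate(events: Iterable, tracks: List[Track], ramp: TemporalRamp, phase: str,
              t0: float = 0.0, t1: Optional[float] = None) -> float:
    """Turns per minute per animal within one ramp phase.

    Counts turns starting in the phase across all tracks, divided by the
    phase duration in minutes within the analysis window [t0, t1) and by the
    time-averaged number of animals present during that phase.
    """
    if phase not in ("increase", "decrease"):
        raise MetricsError("phase must be 'increase' or 'decrease'")
    t1 = ramp.total_s if t1 is None else t1
    n_turns = 0
    for reo in _turns(events):
        if 0.0 <= reo.t_start < ramp.total_s and ramp.phase(reo.t_start) == phase:
            n_turns += 1
    phase_min = _phase_seconds(ramp, t0, t1)[phase] / 60.0
    if phase_min == 0.0:
        return float("nan")
    n_animals = _mean_animals_in_phase(tracks, ramp, phase, t0, t1)
    if not n_animals or math.isnan(n_animals) or n_animals == 0.0:
        return float("nan")
    return n_turns / phase_min / n_animals


def turn_rate_delta(events: Iterable, tracks: List[Track], ramp: TemporalRamp,
                    t0: float = 0.0, t1: Optional[float] = None) -> float:
    """turn_rate(increase) − turn_rate(decrease)."""
    return (turn_rate(events, tracks, ramp, "increase", t0, t1)
            - turn_rate(events, tracks, ramp, "decrease", t0, t1))


def head_sweep_size(sweep: HeadSweep) -> float:
    """|wrapped difference| between the pre-turn heading and the sweep's
    maximal heading, degrees."""
    if math.isnan(sweep.heading_before) or math.isnan(sweep.max_heading):
        return float("nan")
    return abs(wrap_angle(sweep.max_heading - sweep.heading_before))


def mean_sweep_size_by_outcome(events: Iterable) -> Dict[str, Tuple[float, int]]:
    """Mean head-sweep size pooled separately for accepted and rejected sweeps."""
    acc, rej = [], []
    for reo in _turns(events):
        for sw in reo.sweeps:
            sz = head_sweep_size(sw)
            if math.isnan(sz):
                continue
            if sw.outcome == "accepted":
                acc.append(sz)
            elif sw.outcome == "rejected":
                rej.append(sz)
    return {"accepted": (float(np.mean(acc)) if acc else float("nan"), len(acc)),
            "rejected": (float(np.mean(rej)) if rej else float("nan"), len(rej))}


def run_speed(run: Run) -> float:
    """Run path length divided by run duration, cm/s."""
    return run.path_length_cm / run.duration_s if run.duration_s > 0 else 0.0


def mean_run_speed(runs: Iterable[Run]) -> Tuple[float, int]:
    vals = [run_speed(r) for r in runs]
    return (float(np.mean(vals)) if vals else float("nan"), len(vals))


def mirror_tracks(tracks: List[Track], field: DirectionalField) -> List[Track]:
    """Reflect trajectories across the light axis through the arena center.

    Used for achiral pooling of lateralized groups (e.g. left- vs
    right-ablated animals): mirroring one group makes laterality cancel.
    """
    u = field.light_direction
    cx, cy = field.arena_cm[0] / 2.0, field.arena_cm[1] / 2.0
    out = []
    for tr in tracks:
        p = tr.midline - np.array([cx, cy])
        along = p @ u
        perp = p[..., 0] * (-u[1]) + p[..., 1] * u[0]
        mirrored = (along[..., None] * u
                    + (-perp)[..., None] * np.array([-u[1], u[0]])
                    + np.array([cx, cy]))
        out.append(Track(tr.id + "_mirrored", tr.t.copy(), mirrored, tr.experiment_id))
    return out


@dataclass
class MetricsReport:
    """Per-experiment navigational parameters."""

    experiment_id: str = ""
    n_tracks: int = 0
    n_runs: int = 0
    n_turns: int = 0
    navigation_index: Optional[float] = None
    first_sweep_away: Optional[BinaryRate] = None
    first_sweep_skipped: int = 0
    turn_away: Optional[BinaryRate] = None
    turn_left_toward_bin: Optional[BinaryRate] = None
    steering_plus90: Tuple[float, int] = (float("nan"), 0)
    steering_minus90: Tuple[float, int] = (float("nan"), 0)
    steering_away: Tuple[float, int] = (float("nan"), 0)
    acceptance: Dict[str, BinaryRate] = dc_field(default_factory=dict)
    turn_size_mean: Dict[str, Tuple[float, int]] = dc_field(default_factory=dict)
    turn_size_delta: Optional[float] = None
    turn_rate_mean: Dict[str, float] = dc_field(default_factory=dict)
    turn_rate_delta: Optional[float] = None
    steering_mag: Dict[str, Tuple[float, int]] = dc_field(default_factory=dict)
    run_speed_mean: Tuple[float, int] = (float("nan"), 0)
    sweep_size: Dict[str, Tuple[float, int]] = dc_field(default_factory=dict)

    def to_rows(self) -> List[dict]:
        """Flatten to one row per metric/stratum for the delimited report."""
        rows = []

        def add(metric, stratum, value, k=None, n=None, sem=None):
            rows.append({"experiment_id": self.experiment_id, "metric": metric,
                         "stratum": stratum, "value": value, "k": k, "n": n,
                         "sem": sem})

        add("n_tracks", "", self.n_tracks)
        add("n_runs", "", self.n_runs)
        add("n_turns", "", self.n_turns)
        if self.navigation_index is not None:
            add("navigation_index", "", self.navigation_index)
        for name, br in (("first_sweep_away", self.first_sweep_away),
                         ("turn_away", self.turn_away),
                         ("turn_left_toward_bin", self.turn_left_toward_bin)):
            if br is not None and br.n:
                add(name, "", br.p, k=br.k, n=br.n, sem=br.sem)
        for ph, br in self.acceptance.items():
            if br.n:
                add("acceptance_rate", ph, br.p, k=br.k, n=br.n, sem=br.sem)
        for stratum, (v, n) in (("plus90", self.steering_plus90),
                                ("minus90", self.steering_minus90),
                                ("away_combined", self.steering_away)):
            if n:
                add("run_heading_change", stratum, v, n=n)
        for ph, (v, n) in self.turn_size_mean.items():
            if n:
                add("turn_size", ph, v, n=n)
        if self.turn_size_delta is not None and not math.isnan(self.turn_size_delta):
            add("turn_size_delta", "", self.turn_size_delta)
        for ph, v in self.turn_rate_mean.items():
            if not math.isnan(v):
                add("turn_rate", ph, v)
        if self.turn_rate_delta is not None and not math.isnan(self.turn_rate_delta):
            add("turn_rate_delta", "", self.turn_rate_delta)
        for ph, (v, n) in self.steering_mag.items():
            if n:
                add("steering_magnitude", ph, v, n=n)
        if self.run_speed_mean[1]:
            add("run_speed", "", self.run_speed_mean[0], n=self.run_speed_mean[1])
        for outcome, (v, n) in self.sweep_size.items():
            if n:
                add("sweep_size", outcome, v, n=n)
        return rows


def compute_report(tracks: List[Track], events_per_track: List[List],
                   stimulus=None, bin_mode: str = "perpendicular_bins",
                   experiment_id: str = "", analysis_window=None) -> MetricsReport:
    """Compute every applicable navigational parameter for one experiment.

    Spatial metrics require a :class:`DirectionalField`; temporal metrics a
    :class:`TemporalRamp`.  Metrics whose stimulus is absent are left unset.
    """
    all_events = [e for evs in events_per_track for e in evs]
    runs = _runs(all_events)
    rep = MetricsReport(experiment_id=experiment_id, n_tracks=len(tracks),
                        n_runs=len(runs), n_turns=len(_turns(all_events)))
    rep.run_speed_mean = mean_run_speed(runs)
    rep.sweep_size = mean_sweep_size_by_outcome(all_events)

    if isinstance(stimulus, DirectionalField):
        try:
            rep.navigation_index = navigation_index(runs, stimulus)
        except UndefinedIndexError:
            rep.navigation_index = None
        rep.first_sweep_away, rep.first_sweep_skipped = first_sweep_direction(
            all_events, stimulus, bin_mode)
        rep.turn_away, _ = turn_direction(all_events, stimulus, "perpendicular")
        rep.turn_left_toward_bin, _ = turn_direction(all_events, stimulus, "toward")
        rep.steering_plus90 = mean_run_heading_change(runs, stimulus, "plus90")
        rep.steering_minus90 = mean_run_heading_change(runs, stimulus, "minus90")
        rep.steering_away = combined_away_steering(runs, stimulus)
    elif isinstance(stimulus, TemporalRamp):
        t0, t1 = analysis_window if analysis_window else (0.0, stimulus.total_s)
        rep.acceptance = acceptance_rate(all_events, stimulus)
        rep.turn_size_mean = turn_size_by_phase(all_events, stimulus)
        inc, dec = rep.turn_size_mean["increase"][0], rep.turn_size_mean["decrease"][0]
        rep.turn_size_delta = inc - dec
        rep.turn_rate_mean = {
            ph: turn_rate(all_events, tracks, stimulus, ph, t0, t1)
            for ph in ("increase", "decrease")}
        rep.turn_rate_delta = (rep.turn_rate_mean["increase"]
                               - rep.turn_rate_mean["decrease"])
        rep.steering_mag = steering_magnitude_by_phase(runs, stimulus)
    return rep
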