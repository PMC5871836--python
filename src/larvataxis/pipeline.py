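"""End-to-end orchestration: filter → threshold → segment → metrics → stats."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

from .metrics import MetricsReport, compute_report
from .segmentation import (Reorientation, Run, SegmentationParams,
                           estimate_speed_threshold, filter_tracks,
                           segment_track, Track)
from .stats import (DegenerateVarianceError, StatsError, TestResult,
                    adjust_family, exact_binomial, fisher_exact_2x2,
                    one_sample_t, two_sample_t)
from .stimulus import DirectionalField, TemporalRamp

log = logging.getLogger("larvataxis")

__all__ = ["ExperimentBundle", "PipelineResult", "run_pipeline", "run_stats"]


@dataclass
class ExperimentBundle:
    """Input of one analysis: tracks grouped by experiment, plus the stimulus."""

    tracks: List[Track]
    stimulus: object = None  # DirectionalField | TemporalRamp | None
    params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    bin_mode: str = "perpendicular_bins"
    metadata: dict = dc_field(default_factory=dict)

    def by_experiment(self) -> Dict[str, List[Track]]:
        groups: Dict[str, List[Track]] = {}
        for tr in self.tracks:
            groups.setdefault(tr.experiment_id or "exp0", []).append(tr)
        return groups


@dataclass
class PipelineResult:
    reports: List[MetricsReport]
    tests: List[TestResult]
    events: Dict[str, list]  # track id -> event list
    thresholds: Dict[str, float]


def run_pipeline(bundle: ExperimentBundle) -> PipelineResult:
    """Run the full analysis on a bundle; deterministic given its inputs."""
    params = bundle.params
    reports: List[MetricsReport] = []
    all_events: Dict[str, list] = {}
    thresholds: Dict[str, float] = {}
    groups = bundle.by_experiment()
    log.info("pipeline: %d experiments, %d tracks total",
             len(groups), len(bundle.tracks))
    for exp_id, tracks in sorted(groups.items()):
        kept = filter_tracks(tracks, params)
        log.info("%s: %d/%d tracks pass filters", exp_id, len(kept), len(tracks))
        events_per_track = []
        for tr in kept:
            thr = estimate_speed_threshold(tr, params)
            thresholds[tr.id] = thr
            events = segment_track(tr, params, thr)
            all_events[tr.id] = events
            events_per_track.append(events)
        n_runs = sum(isinstance(e, Run) for evs in events_per_track for e in evs)
        n_reo = sum(isinstance(e, Reorientation) for evs in events_per_track for e in evs)
        log.info("%s: %d runs, %d reorientations", exp_id, n_runs, n_reo)
        window = None
        if isinstance(bundle.stimulus, TemporalRamp):
            window = (params.discard_initial_s, bundle.stimulus.total_s)
        reports.append(compute_report(
            kept, events_per_track, bundle.stimulus, bundle.bin_mode,
            experiment_id=exp_id, analysis_window=window))
    if not any(r.n_tracks for r in reports):
        log.warning("pipeline: no tracks survived filtering")
    if bundle.stimulus is None:
        log.warning("no stimulus configured; spatial/temporal metrics skipped")
    tests = run_stats(reports, bundle.stimulus)
    log.info("stats: %d tests in family", len(tests))
    return PipelineResult(reports=reports, tests=tests, events=all_events,
                          thresholds=thresholds)


def _pooled(reports: List[MetricsReport], attr: str):
    k = n = 0
    for r in reports:
        br = getattr(r, attr)
        if br is not None and br.n:
            k += br.k
            n += br.n
    return k, n


def run_stats(reports: List[MetricsReport], stimulus) -> List[TestResult]:
    """The paper-style test battery over per-experiment reports, BH-adjusted.

    Directional stimuli: one-sample t of the navigation index and of the
    combined away-steering against 0, exact binomial tests of first-sweep
    and turn direction against chance.  Temporal stimuli: Fisher's exact
    test of acceptance/rejection between phases, two-sample t of
    per-experiment turn size, turn rate and steering magnitude between
    phases.  Tests that cannot run (too few experiments, zero variance,
    empty counts) are skipped.
    """
    tests: List[TestResult] = []

    def _try(fn, *a, **kw):
        try:
            tests.append(fn(*a, **kw))
        except (StatsError, DegenerateVarianceError) as err:
            log.warning("skipping %s: %s", kw.get("comparison", fn.__name__), err)

    if isinstance(stimulus, DirectionalField):
        nav = [r.navigation_index for r in reports if r.navigation_index is not None]
        if len(nav) >= 2:
            _try(one_sample_t, nav, 0.0, comparison="navigation_index vs 0")
        k, n = _pooled(reports, "first_sweep_away")
        if n:
            _try(exact_binomial, k, n, 0.5, comparison="first_sweep_direction vs chance")
        k, n = _pooled(reports, "turn_away")
        if n:
            _try(exact_binomial, k, n, 0.5, comparison="turn_direction vs chance")
        steer = [r.steering_away[0] for r in reports if r.steering_away[1]]
        steer = [s for s in steer if not math.isnan(s)]
        if len(steer) >= 2:
            _try(one_sample_t, steer, 0.0, comparison="away_steering vs 0")
    elif isinstance(stimulus, TemporalRamp):
        inc = [0, 0]
        dec = [0, 0]
        for r in reports:
            for ph, tally in (("increase", inc), ("decrease", dec)):
                br = r.acceptance.get(ph)
                if br is not None and br.n:
                    tally[0] += br.k
                    tally[1] += br.n
        if inc[1] and dec[1]:
            table = [[inc[0], inc[1] - inc[0]], [dec[0], dec[1] - dec[0]]]
            _try(fisher_exact_2x2, table, comparison="acceptance increase vs decrease")
        for metric, getter in (
                ("turn_size", lambda r, ph: r.turn_size_mean.get(ph, (float("nan"), 0))[0]),
                ("turn_rate", lambda r, ph: r.turn_rate_mean.get(ph, float("nan"))),
                ("steering_magnitude", lambda r, ph: r.steering_mag.get(ph, (float("nan"), 0))[0])):
            a = [getter(r, "increase") for r in reports]
            b = [getter(r, "decrease") for r in reports]
            a = [v for v in a if not math.isnan(v)]
            b = [v for v in b if not math.isnan(v)]
            if len(a) >= 2 and len(b) >= 2:
                _try(two_sample_t, a, b, comparison=f"{metric} increase vs decrease")
    return adjust_family(tests)
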