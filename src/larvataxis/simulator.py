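"""Agent-based synthetic larva generator.

Each agent alternates runs and reorientations.  During a run it advances at a
fixed crawl speed and can curve toward the darker side (tropotaxis channel,
``steer_gain``); runs terminate with a hazard that depends on the sign of the
sensed intensity change (``turn_rate_dec`` / ``turn_rate_inc``).  During a
reorientation the agent performs head sweeps: the first sweep's side is
biased by the instantaneous left–right eye intensity difference
(``spatial_dir_gain``), and each sweep is accepted with a probability that
depends on whether the intensity sensed during the sweep decreased or
increased (klinotaxis channel, ``p_accept_dec`` / ``p_accept_inc``) — a
two-point comparison of the intensity at sweep start versus sweep peak.  An
accepted sweep sets the new run heading; a rejected one is followed by
another sweep, preferentially on the other side.

All sign conventions follow a single "darker is preferred" rule: a positive
left-minus-right dark bias steers and sweeps toward the animal's left.

The simulator emits midline trajectories in the same dialect the
segmentation stage consumes plus a ground-truth event log, so it doubles as
the test oracle for the analysis pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import List, Optional, Tuple

import numpy as np

from .segmentation import Track
from .stimulus import DirectionalField, TemporalRamp, wrap_angle

__all__ = [
    "SimulatorError",
    "AgentParams",
    "SimConfig",
    "TruthEvent",
    "GroundTruthLog",
    "AgentState",
    "eye_intensity",
    "step_agent",
    "synthesize_midline",
    "straight_track",
    "simulate_agent",
    "simulate_experiment",
]

_SWEEP_HALF_FRAC = 0.5  # peak of the half-cosine profile at half the sweep duration


class SimulatorError(ValueError):
    pass


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth behavioral bias parameters of a synthetic larva.

    Probabilities/rates are split by the sign of the sensed intensity change
    (the temporal channel); ``spatial_dir_gain`` and ``steer_gain`` act on
    the left–right eye difference (the spatial channel).  Defaults are tuned
    for statistical test power, not fitted to real animals.
    """

    p_accept_dec: float = 0.55
    p_accept_inc: float = 0.55
    turn_rate_dec: float = 3.0  # per min
    turn_rate_inc: float = 3.0  # per min
    sweep_amp_mean_deg: float = 40.0
    sweep_amp_sd_deg: float = 8.0
    sweep_amp_min_deg: float = 25.0
    sweep_amp_max_deg: float = 120.0
    extra_turn_gain_deg: float = 0.0
    spatial_dir_gain: float = 0.0  # logistic slope per µW/cm² on (L-R) dark bias
    steer_gain: float = 0.0  # deg/s per unit normalized dark bias
    run_speed_cm_per_min: float = 4.0
    eye_state: str = "both"  # both | left_only | right_only | none
    eye_acceptance_halfwidth_deg: float = 90.0
    eye_forward_offset_deg: float = 45.0
    turn_speed_fraction: float = 0.1
    min_run_s: float = 1.5
    sweep_duration_s: float = 0.7
    p_switch_after_reject: float = 0.8
    p_pause: float = 0.0

    def __post_init__(self):
        for name in ("p_accept_dec", "p_accept_inc", "p_switch_after_reject", "p_pause"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulatorError(f"{name} must be in [0, 1]")
        for name in ("turn_rate_dec", "turn_rate_inc", "run_speed_cm_per_min",
                     "sweep_amp_mean_deg", "turn_speed_fraction"):
            if getattr(self, name) < 0:
                raise SimulatorError(f"{name} must be >= 0")
        if self.eye_state not in ("both", "left_only", "right_only", "none"):
            raise SimulatorError("bad eye_state")
        if self.sweep_duration_s <= 0:
            raise SimulatorError("sweep_duration_s must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Arena / protocol settings for one batch of simulated experiments."""

    arena_cm: Tuple[float, float] = (24.5, 24.5)
    n_agents: int = 30
    duration_s: float = 660.0
    fps: float = 13.0
    n_experiments: int = 1
    seed: int = 0
    stimulus: object = None  # DirectionalField | TemporalRamp | None
    midline_points: int = 5
    body_length_cm: float = 0.4

    def __post_init__(self):
        if self.n_agents < 0 or self.duration_s <= 0 or self.fps <= 0:
            raise SimulatorError("n_agents >= 0, duration_s > 0, fps > 0 required")
        if self.midline_points < 3:
            raise SimulatorError("midline_points must be >= 3")


@dataclass
class TruthEvent:
    kind: str  # run | sweep | turn | pause
    agent: str
    t_start: float
    t_end: float
    side: str = ""
    outcome: str = ""
    ordinal: int = 0
    heading_start: float = float("nan")
    heading_end: float = float("nan")
    d_sign: int = 0  # sign of the sensed intensity change at the decision


@dataclass
class GroundTruthLog:
    events: List[TruthEvent] = dc_field(default_factory=list)
    eye_traces: dict = dc_field(default_factory=dict)  # agent -> (n, 2) [L, R]

    def of_kind(self, kind: str, agent: Optional[str] = None) -> List[TruthEvent]:
        return [e for e in self.events
                if e.kind == kind and (agent is None or e.agent == agent)]


@dataclass
class AgentState:
    x: float
    y: float
    heading: float  # arena deg
    t: float = 0.0
    head_angle: float = 0.0  # deg, left positive
    mode: str = "run"  # run | sweep_out | sweep_back | pause
    run_start_t: float = 0.0
    run_start_heading: float = 0.0
    run_age: float = 0.0
    turn_start_t: float = 0.0
    turn_prior_heading: float = float("nan")
    sweep_ordinal: int = 0
    sweep_side: int = 1  # +1 left, -1 right
    sweep_amp: float = 0.0
    sweep_tau: float = 0.0
    sweep_start_t: float = 0.0
    sweep_s0: float = 0.0
    pause_left: float = 0.0
    s_prev: float = float("nan")
    events: List[TruthEvent] = dc_field(default_factory=list)
    agent_id: str = "0"


def _eye_weight(axis_deg: float, light_angle_deg: float, halfwidth_deg: float) -> float:
    delta = abs(wrap_angle(axis_deg - light_angle_deg))
    x = delta * 90.0 / halfwidth_deg
    if x >= 90.0:
        return 0.0
    return math.cos(math.radians(x))


def eye_intensity(position, heading_deg: float, side: str, stimulus, params: AgentParams,
                  t: float = 0.0) -> float:
    """Intensity (µW/cm²) received by one eye.

    For a directional field the local intensity is scaled by a raised-cosine
    directional acceptance about the eye's outward-lateral axis (heading
    rotated by ±(90° − forward offset)).  A spatially uniform temporal ramp
    reaches both eyes equally; an ablated eye returns 0, as does darkness.
    """
    if side not in ("left", "right"):
        raise SimulatorError("side must be 'left' or 'right'")
    if params.eye_state == "none":
        return 0.0
    if params.eye_state == "left_only" and side == "right":
        return 0.0
    if params.eye_state == "right_only" and side == "left":
        return 0.0
    if stimulus is None:
        return 0.0
    if isinstance(stimulus, TemporalRamp):
        return stimulus._intensity_scalar(t)
    sgn = 1.0 if side == "left" else -1.0
    axis = heading_deg + sgn * (90.0 - params.eye_forward_offset_deg)
    w = _eye_weight(axis, stimulus.light_angle_deg, params.eye_acceptance_halfwidth_deg)
    return stimulus.intensity(np.asarray(position, dtype=float)) * w


def _make_sensor(stimulus, params: AgentParams, arena):
    """Build a fast scalar (x, y, heading, t) -> (L, R) closure."""
    left_on = params.eye_state in ("both", "left_only")
    right_on = params.eye_state in ("both", "right_only")
    if stimulus is None or params.eye_state == "none" or not (left_on or right_on):
        return lambda x, y, h, t: (0.0, 0.0)
    if isinstance(stimulus, TemporalRamp):
        scalar = stimulus._intensity_scalar

        def sense(x, y, h, t):
            i = scalar(t)
            return (i if left_on else 0.0, i if right_on else 0.0)
        return sense

    # directional field: closed-form intensity, raised-cosine eyes
    edge, grad = stimulus.edge_intensity, stimulus.gradient
    la = stimulus.light_angle_deg
    ua, va = math.cos(math.radians(la)), math.sin(math.radians(la))
    lx, ly = arena
    s_max = max(cx * ua + cy * va for cx in (0.0, lx) for cy in (0.0, ly))
    hw = params.eye_acceptance_halfwidth_deg
    off = 90.0 - params.eye_forward_offset_deg

    def sense(x, y, h, t):
        base = edge - grad * (s_max - (x * ua + y * va))
        if base < 0.0:
            base = 0.0
        lval = rval = 0.0
        if left_on:
            lval = base * _eye_weight(h + off, la, hw)
        if right_on:
            rval = base * _eye_weight(h - off, la, hw)
        return (lval, rval)
    return sense


def _start_sweep(state: AgentState, L: float, R: float, params: AgentParams, rng,
                 first: bool) -> None:
    # darker side preferred: surplus light on the right biases sweeps left
    z = params.spatial_dir_gain * (R - L)
    if not first:
        # after a rejection, add a bias away from the rejected side
        p_switch = min(max(params.p_switch_after_reject, 1e-9), 1 - 1e-9)
        base = p_switch if state.sweep_side < 0 else 1.0 - p_switch
        z += math.log(base / (1.0 - base))
    p_left = 1.0 / (1.0 + math.exp(-z)) if abs(z) < 40 else (1.0 if z > 0 else 0.0)
    state.sweep_side = 1 if rng.random() < p_left else -1
    amp = rng.normal(params.sweep_amp_mean_deg, params.sweep_amp_sd_deg)
    state.sweep_amp = float(min(max(amp, params.sweep_amp_min_deg), params.sweep_amp_max_deg))
    state.sweep_tau = 0.0
    state.sweep_start_t = state.t
    state.sweep_s0 = L + R
    state.sweep_ordinal += 1
    state.mode = "sweep_out"


def _begin_run(state: AgentState) -> None:
    state.mode = "run"
    state.run_start_t = state.t
    state.run_start_heading = state.heading
    state.run_age = 0.0
    state.head_angle = 0.0


def step_agent(state: AgentState, stimulus, params: AgentParams, dt: float, rng,
               _sense=None, _arena=(24.5, 24.5)) -> AgentState:
    """Advance one agent by ``dt`` seconds (mutates and returns ``state``)."""
    if dt <= 0:
        raise SimulatorError("dt must be positive")
    sense = _sense or _make_sensor(stimulus, params, _arena)
    v = params.run_speed_cm_per_min / 60.0
    lx, ly = _arena

    L, R = sense(state.x, state.y, state.heading, state.t)

    if state.mode == "run":
        tot = L + R
        if params.steer_gain != 0.0 and tot > 0.0:
            # steer toward the darker side (left positive)
            state.heading += params.steer_gain * ((R - L) / tot) * dt
        hr = math.radians(state.heading)
        state.x += v * dt * math.cos(hr)
        state.y += v * dt * math.sin(hr)
        _reflect(state, lx, ly)
        s = L + R
        ds = s - state.s_prev if not math.isnan(state.s_prev) else 0.0
        state.s_prev = s
        state.run_age += dt
        state.t += dt
        if state.run_age >= params.min_run_s:
            if ds < 0.0:
                rate = params.turn_rate_dec
            elif ds > 0.0:
                rate = params.turn_rate_inc
            else:
                rate = 0.5 * (params.turn_rate_dec + params.turn_rate_inc)
            if rng.random() < rate / 60.0 * dt:
                state.events.append(TruthEvent(
                    "run", state.agent_id, state.run_start_t, state.t,
                    heading_start=state.run_start_heading, heading_end=state.heading))
                if rng.random() < params.p_pause:
                    state.mode = "pause"
                    state.pause_left = rng.uniform(1.0, 3.0)
                    state.turn_start_t = state.t
                else:
                    state.turn_start_t = state.t
                    state.turn_prior_heading = state.heading
                    state.sweep_ordinal = 0
                    L2, R2 = sense(state.x, state.y, state.heading, state.t)
                    _start_sweep(state, L2, R2, params, rng, first=True)
        return state

    if state.mode == "pause":
        hr = math.radians(state.heading)
        crawl = params.turn_speed_fraction * v * dt
        state.x += crawl * math.cos(hr)
        state.y += crawl * math.sin(hr)
        _reflect(state, lx, ly)
        state.pause_left -= dt
        state.t += dt
        if state.pause_left <= 0.0:
            state.events.append(TruthEvent(
                "pause", state.agent_id, state.turn_start_t, state.t,
                heading_start=state.heading, heading_end=state.heading))
            _begin_run(state)
        return state

    # sweep modes: slow crawl while the head describes a half-cosine excursion
    hr = math.radians(state.heading)
    crawl = params.turn_speed_fraction * v * dt
    state.x += crawl * math.cos(hr)
    state.y += crawl * math.sin(hr)
    _reflect(state, lx, ly)
    state.sweep_tau += dt
    state.t += dt
    dur = params.sweep_duration_s
    half = _SWEEP_HALF_FRAC * dur

    if state.mode == "sweep_out":
        tau = min(state.sweep_tau, half)
        state.head_angle = state.sweep_side * state.sweep_amp * math.sin(math.pi * tau / dur)
        if state.sweep_tau >= half:
            # decision at peak deflection: two-point temporal comparison
            L1, R1 = sense(state.x, state.y, state.heading + state.head_angle, state.t)
            d = (L1 + R1) - state.sweep_s0
            d_sign = 1 if d > 0 else (-1 if d < 0 else 0)
            if d_sign < 0:
                p = params.p_accept_dec
            elif d_sign > 0:
                p = params.p_accept_inc
            else:
                p = 0.5 * (params.p_accept_dec + params.p_accept_inc)
            if rng.random() < p:
                amp_eff = state.sweep_amp
                if d_sign > 0:
                    amp_eff += params.extra_turn_gain_deg
                state.events.append(TruthEvent(
                    "sweep", state.agent_id, state.sweep_start_t, state.t,
                    side="left" if state.sweep_side > 0 else "right",
                    outcome="accepted", ordinal=state.sweep_ordinal, d_sign=d_sign))
                state.heading = wrap_angle(state.heading + state.sweep_side * amp_eff)
                state.events.append(TruthEvent(
                    "turn", state.agent_id, state.turn_start_t, state.t,
                    heading_start=state.turn_prior_heading, heading_end=state.heading))
                state.s_prev = float("nan")
                _begin_run(state)
            else:
                state._pending_d_sign = d_sign
                state.mode = "sweep_back"
        return state

    # sweep_back: head returns to the body axis, then another sweep starts
    tau = min(state.sweep_tau, dur)
    state.head_angle = state.sweep_side * state.sweep_amp * math.sin(math.pi * tau / dur)
    if state.sweep_tau >= dur:
        state.head_angle = 0.0
        state.events.append(TruthEvent(
            "sweep", state.agent_id, state.sweep_start_t, state.t,
            side="left" if state.sweep_side > 0 else "right",
            outcome="rejected", ordinal=state.sweep_ordinal,
            d_sign=getattr(state, "_pending_d_sign", 0)))
        L1, R1 = sense(state.x, state.y, state.heading, state.t)
        _start_sweep(state, L1, R1, params, rng, first=False)
    return state


def _reflect(state: AgentState, lx: float, ly: float) -> None:
    """Specular reflection at the arena walls."""
    bounced = False
    if state.x < 0.0:
        state.x = -state.x
        bounced = True
        state.heading = wrap_angle(180.0 - state.heading)
    elif state.x > lx:
        state.x = 2 * lx - state.x
        bounced = True
        state.heading = wrap_angle(180.0 - state.heading)
    if state.y < 0.0:
        state.y = -state.y
        bounced = True
        state.heading = wrap_angle(-state.heading)
    elif state.y > ly:
        state.y = 2 * ly - state.y
        bounced = True
        state.heading = wrap_angle(-state.heading)
    if bounced:
        state.run_start_heading = state.heading


def synthesize_midline(state: AgentState, params_or_config, n_points: int = 5,
                       body_length_cm: float = 0.4) -> np.ndarray:
    """Midline points (tail→head, cm) of a two-segment body.

    The posterior half lies along the body axis and the anterior half is
    deflected by the current head angle, so the emitted frame's body-bend
    angle reproduces the agent's head angle.
    """
    if isinstance(params_or_config, SimConfig):
        n_points = params_or_config.midline_points
        body_length_cm = params_or_config.body_length_cm
    if body_length_cm <= 0:
        raise SimulatorError("body_length_cm must be positive")
    return _midlines(
        np.array([state.x]), np.array([state.y]),
        np.array([state.heading]), np.array([state.head_angle]),
        n_points, body_length_cm)[0]


def _midlines(x, y, heading_deg, head_angle_deg, n_points: int,
              body_length_cm: float) -> np.ndarray:
    """Vectorized midline synthesis for whole trajectories: (n, m, 2)."""
    n = len(x)
    hb = np.radians(heading_deg)
    hh = np.radians(heading_deg + head_angle_deg)
    neck = np.stack([x, y], axis=-1)
    half_len = body_length_cm / 2.0
    u_body = np.stack([np.cos(hb), np.sin(hb)], axis=-1)
    u_head = np.stack([np.cos(hh), np.sin(hh)], axis=-1)
    tail = neck - half_len * u_body
    # sample n_points evenly by arc length along tail -> neck -> head
    s = np.linspace(0.0, body_length_cm, n_points)
    pts = np.empty((n, n_points, 2))
    for j, sj in enumerate(s):
        if sj <= half_len:
            pts[:, j, :] = tail + sj * u_body
        else:
            pts[:, j, :] = neck + (sj - half_len) * u_head
    return pts


def straight_track(start, heading_deg: float, speed_cm_s: float, duration_s: float,
                   fps: float = 13.0, track_id: str = "straight",
                   n_points: int = 5, body_length_cm: float = 0.4) -> Track:
    """Deterministic straight constant-speed track with an aligned body."""
    n = int(round(duration_s * fps)) + 1
    t = np.arange(n) / fps
    hr = math.radians(heading_deg)
    x = start[0] + speed_cm_s * t * math.cos(hr)
    y = start[1] + speed_cm_s * t * math.sin(hr)
    midline = _midlines(x, y, np.full(n, heading_deg), np.zeros(n),
                        n_points, body_length_cm)
    return Track(id=track_id, t=t, midline=midline)


def simulate_agent(config: SimConfig, params: AgentParams, rng,
                   agent_id: str = "0", start=None, start_heading=None):
    """Simulate one agent; returns (Track, events, eye_trace)."""
    n_frames = int(round(config.duration_s * config.fps))
    dt = 1.0 / config.fps
    lx, ly = config.arena_cm
    if start is None:
        cx, cy = lx / 2.0, ly / 2.0
        ang = rng.uniform(0, 2 * math.pi)
        rad = 3.0 * math.sqrt(rng.random())
        start = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
    if start_heading is None:
        start_heading = rng.uniform(-180.0, 180.0)
    state = AgentState(x=start[0], y=start[1], heading=float(start_heading),
                       agent_id=agent_id)
    state.run_start_heading = state.heading
    sense = _make_sensor(config.stimulus, params, config.arena_cm)

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    heads = np.empty(n_frames)
    bends = np.empty(n_frames)
    trace = np.empty((n_frames, 2))
    for k in range(n_frames):
        xs[k], ys[k] = state.x, state.y
        heads[k] = state.heading
        bends[k] = state.head_angle
        trace[k] = sense(state.x, state.y, state.heading, state.t)
        step_agent(state, config.stimulus, params, dt, rng,
                   _sense=sense, _arena=config.arena_cm)

    # close any open event at the end of the recording
    t_end = n_frames * dt
    if state.mode == "run":
        state.events.append(TruthEvent(
            "run", agent_id, state.run_start_t, t_end,
            heading_start=state.run_start_heading, heading_end=state.heading))
    elif state.mode == "pause":
        state.events.append(TruthEvent("pause", agent_id, state.turn_start_t, t_end,
                                       heading_start=state.heading,
                                       heading_end=state.heading))
    else:
        state.events.append(TruthEvent(
            "sweep", agent_id, state.sweep_start_t, t_end,
            side="left" if state.sweep_side > 0 else "right",
            outcome="truncated", ordinal=state.sweep_ordinal))
        state.events.append(TruthEvent(
            "turn", agent_id, state.turn_start_t, t_end,
            heading_start=state.turn_prior_heading, heading_end=float("nan")))

    t = np.arange(n_frames) * dt
    midline = _midlines(xs, ys, heads, bends, config.midline_points,
                        config.body_length_cm)
    track = Track(id=agent_id, t=t, midline=midline)
    return track, state.events, trace


def simulate_experiment(config: SimConfig, params: AgentParams,
                        seed: Optional[int] = None,
                        experiment_id: str = "exp0"):
    """Simulate one experiment of ``n_agents`` independent agents.

    Returns ``(tracks, GroundTruthLog)``.  Reproducible: the same seed gives
    bit-identical output.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(config.n_agents, 1))
    tracks: List[Track] = []
    log = GroundTruthLog()
    for i in range(config.n_agents):
        rng = np.random.default_rng(children[i])
        agent_id = f"{experiment_id}:{i}"
        track, events, trace = simulate_agent(config, params, rng, agent_id=agent_id)
        track.experiment_id = experiment_id
        tracks.append(track)
        log.events.extend(events)
        log.eye_traces[agent_id] = trace
    return tracks, log
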