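"""Lightscapes, the navigational compass and heading bins.

Two stimulus models are supported:

* :class:`DirectionalField` — a planar light gradient produced by a source on
  one side of the arena.  Intensity falls off linearly with distance from the
  arena edge nearest the source and is clipped at zero.
* :class:`TemporalRamp` — a spatially uniform triangular intensity ramp with
  hold plateaus between the linear segments, repeated for a fixed number of
  cycles.  Analysis windows around the plateaus can be excluded.

Headings are expressed on a compass where 0° points toward the light source,
180° points away, and angles grow counterclockwise (to the animal's left), so
at +90° the right body half faces the light.  All angles are degrees wrapped
to the half-open interval (-180, 180].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusError",
    "OutOfBoundsError",
    "UndefinedHeadingError",
    "wrap_angle",
    "DirectionalField",
    "TemporalRamp",
    "directional_intensity",
    "sensed_rate_of_change",
    "temporal_intensity",
    "phase_of",
    "to_compass",
    "compass_from_arena_angle",
    "bin4",
    "bin2",
    "BIN4_LABELS",
    "BIN2_LABELS",
]

BIN4_LABELS = ("toward", "plus90", "away", "minus90")
BIN2_LABELS = ("positive_half", "negative_half")


class StimulusError(ValueError):
    """Invalid stimulus query."""


class OutOfBoundsError(StimulusError):
    """Position outside the arena."""


class UndefinedHeadingError(StimulusError):
    """Zero-length heading vector has no compass angle."""


def wrap_angle(deg):
    """Wrap angle(s) in degrees to (-180, 180]."""
    w = np.mod(deg, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.ndim(deg) == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class DirectionalField:
    """Linear planar light gradient from one side of a square arena.

    Parameters
    ----------
    edge_intensity : float
        Intensity in µW/cm² at the arena edge nearest the light source.
    gradient : float
        Intensity decrease in µW/cm² per cm of distance from that edge.
    light_angle_deg : float
        Direction, in arena coordinates (degrees CCW from +x), of the unit
        vector pointing from the arena toward the light source.  The default
        puts the source beyond the x = 0 edge.
    arena_cm : tuple of float
        Arena side lengths (x, y) in cm.
    """

    edge_intensity: float = 4331.0
    gradient: float = 103.0
    light_angle_deg: float = 180.0
    arena_cm: tuple = (24.5, 24.5)

    def __post_init__(self):
        if self.edge_intensity < 0:
            raise StimulusError("edge_intensity must be >= 0")
        if self.gradient < 0:
            raise StimulusError("gradient must be >= 0")

    @property
    def light_direction(self):
        """Unit vector pointing from the arena toward the light source."""
        a = math.radians(self.light_angle_deg)
        return np.array([math.cos(a), math.sin(a)])

    def distance_from_light_edge(self, position):
        """Distance (cm) of ``position`` from the arena edge nearest the light."""
        p = np.asarray(position, dtype=float)
        u = self.light_direction
        lx, ly = self.arena_cm
        corners = np.array([[0, 0], [lx, 0], [0, ly], [lx, ly]], dtype=float)
        s_max = float(np.max(corners @ u))
        return s_max - p @ u

    def intensity(self, position):
        """Light intensity (µW/cm²) at an arena position; see module docs."""
        p = np.asarray(position, dtype=float)
        lx, ly = self.arena_cm
        x, y = p[..., 0], p[..., 1]
        tol = 1e-9
        inside = (x >= -tol) & (x <= lx + tol) & (y >= -tol) & (y <= ly + tol)
        if not np.all(inside):
            raise OutOfBoundsError(f"position {position!r} outside arena {self.arena_cm}")
        val = self.edge_intensity - self.gradient * self.distance_from_light_edge(p)
        val = np.maximum(val, 0.0)
        if p.ndim == 1:
            return float(val)
        return val


def directional_intensity(field: DirectionalField, position):
    """Intensity of a :class:`DirectionalField` at an arena position."""
    return field.intensity(position)


def sensed_rate_of_change(field: DirectionalField, speed_cm_per_min: float) -> float:
    """Intensity change per second sensed while running straight toward the light.

    ``speed`` is in cm/min; the result is µW/cm² per s.
    """
    if speed_cm_per_min < 0:
        raise StimulusError("speed must be >= 0")
    return speed_cm_per_min / 60.0 * field.gradient


@dataclass(frozen=True)
class TemporalRamp:
    """Spatially uniform triangular intensity ramp with hold plateaus.

    One cycle is ramp → hold → ramp → hold; ``phase_order`` selects whether
    the first linear segment rises (``up_first``) or falls (``down_first``).
    The intensity profile is continuous and piecewise linear in [0, i_max],
    so the light dose delivered during rising and falling segments is equal.
    """

    i_max: float = 380.0
    t_ramp_s: float = 25.5
    t_hold_s: float = 4.5
    n_cycles: int = 11
    exclusion_margin_s: float = 1.0
    phase_order: str = "up_first"

    def __post_init__(self):
        if self.i_max < 0 or self.t_ramp_s <= 0 or self.t_hold_s < 0:
            raise StimulusError("ramp parameters must be positive")
        if self.n_cycles < 1:
            raise StimulusError("n_cycles must be >= 1")
        if self.phase_order not in ("up_first", "down_first"):
            raise StimulusError("phase_order must be 'up_first' or 'down_first'")
        if self.exclusion_margin_s < 0:
            raise StimulusError("exclusion_margin_s must be >= 0")

    @property
    def period_s(self) -> float:
        return 2.0 * (self.t_ramp_s + self.t_hold_s)

    @property
    def total_s(self) -> float:
        return self.n_cycles * self.period_s

    @property
    def slope(self) -> float:
        """Magnitude of dI/dt on the linear segments, µW/cm² per s."""
        return self.i_max / self.t_ramp_s

    def detectable_change(self, window_s: float = 1.0) -> float:
        """Intensity change over ``window_s`` seconds of a linear segment."""
        return self.slope * window_s

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t >= self.total_s + 1e-9):
            raise StimulusError(
                f"time outside protocol [0, {self.total_s}) s"
            )
        return t

    def intensity(self, t):
        """Intensity (µW/cm²) at protocol time ``t`` (s)."""
        t = self._check_domain(t)
        tau = np.mod(t, self.period_s)
        tr, th, imax = self.t_ramp_s, self.t_hold_s, self.i_max
        up = np.clip(tau / tr, 0.0, 1.0) * imax
        down_start = tr + th
        down = imax * (1.0 - np.clip((tau - down_start) / tr, 0.0, 1.0))
        val = np.where(tau < down_start, up, down)
        if self.phase_order == "down_first":
            val = imax - val
        if np.ndim(t) == 0:
            return float(val)
        return val

    def _intensity_scalar(self, t: float) -> float:
        """Fast scalar path used by the simulator inner loop (no domain check)."""
        tau = t % self.period_s
        tr, th, imax = self.t_ramp_s, self.t_hold_s, self.i_max
        if tau < tr:
            val = imax * tau / tr
        elif tau < tr + th:
            val = imax
        elif tau < 2 * tr + th:
            val = imax * (1.0 - (tau - tr - th) / tr)
        else:
            val = 0.0
        if self.phase_order == "down_first":
            val = imax - val
        return val

    def phase(self, t):
        """Phase label at time ``t``: ``increase``, ``decrease`` or ``excluded``.

        Hold plateaus, dilated by the exclusion margin on each side, are
        labeled ``excluded``; remaining times take the sign of the ramp slope.
        """
        code = self.phase_code(t)
        labels = np.array(["decrease", "excluded", "increase"])
        out = labels[np.asarray(code) + 1]
        if np.ndim(t) == 0:
            return str(out)
        return out

    def phase_code(self, t):
        """Vectorized phase: +1 increase, -1 decrease, 0 excluded."""
        t = self._check_domain(t)
        tau = np.mod(t, self.period_s)
        tr, th, m = self.t_ramp_s, self.t_hold_s, self.exclusion_margin_s
        # hold intervals within a cycle: [tr, tr+th] and [2tr+th, period];
        # the second one wraps into the start of the next cycle.
        in_seg1 = (tau > m) & (tau < tr - m)
        in_seg2 = (tau > tr + th + m) & (tau < 2 * tr + th - m)
        code = np.zeros(np.shape(tau), dtype=int)
        if self.phase_order == "up_first":
            code = np.where(in_seg1, 1, code)
            code = np.where(in_seg2, -1, code)
        else:
            code = np.where(in_seg1, -1, code)
            code = np.where(in_seg2, 1, code)
        if np.ndim(t) == 0:
            return int(code)
        return code


def temporal_intensity(ramp: TemporalRamp, t):
    """Intensity of a :class:`TemporalRamp` at protocol time ``t`` (s)."""
    return ramp.intensity(t)


def phase_of(ramp: TemporalRamp, t):
    """Phase label of a :class:`TemporalRamp` at time ``t``."""
    return ramp.phase(t)


def to_compass(heading_vector, light) -> float:
    """Signed compass angle (deg) of a heading vector relative to the light.

    ``light`` may be a :class:`DirectionalField` or a light angle in arena
    degrees.  0° is toward the light, counterclockwise (the animal's left) is
    positive; the result lies in (-180, 180].
    """
    h = np.asarray(heading_vector, dtype=float)
    norm = math.hypot(h[0], h[1])
    if norm == 0 or not np.all(np.isfinite(h)):
        raise UndefinedHeadingError("zero or non-finite heading vector")
    ang = math.degrees(math.atan2(h[1], h[0]))
    light_angle = light.light_angle_deg if isinstance(light, DirectionalField) else float(light)
    return wrap_angle(ang - light_angle)


def compass_from_arena_angle(angle_deg, light) -> float:
    """Convert an arena-frame heading angle (deg CCW from +x) to compass degrees."""
    light_angle = light.light_angle_deg if isinstance(light, DirectionalField) else float(light)
    return wrap_angle(np.asarray(angle_deg, dtype=float) - light_angle)


def bin4(theta_deg: float) -> str:
    """4-bin compass partition, each bin 90° wide.

    Boundaries are half-open, closed on the counterclockwise edge:
    toward = [-45, 45), plus90 = [45, 135), minus90 = [-135, -45),
    away = the rest of (-180, 180].
    """
    w = wrap_angle(theta_deg)
    if -45.0 <= w < 45.0:
        return "toward"
    if 45.0 <= w < 135.0:
        return "plus90"
    if -135.0 <= w < -45.0:
        return "minus90"
    return "away"


def bin2(theta_deg: float) -> str:
    """2-bin compass partition: positive_half = (0, 180], negative_half = (-180, 0]."""
    w = wrap_angle(theta_deg)
    return "positive_half" if w > 0.0 else "negative_half"
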