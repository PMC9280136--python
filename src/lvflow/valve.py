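"""Planar parametric mitral-valve orifice model.

The mitral orifice is modelled in the annulus plane as two half ellipses
sharing a common long axis (the intercommissural line): an anterior half with
short semi-axis ``saa`` and a posterior half with short semi-axis ``sap``,
both spanning semi-long axis ``l``.  Valve opening and closing are driven by
time-varying scale factors applied to the two short axes, interpolated with a
monotone piecewise-cubic Hermite schedule between keyframes at the cardiac
landmarks (diastole start, E-wave peak, diastasis start/end, A-wave peak,
diastole end).  Negative scalings represent leaflet-edge projections crossing
the coaptation line; the orifice area is then clamped to zero (valve closed).

Edge-to-edge repair (MitraClip-style) is modelled by pinning a segment of the
coaptation line: the single orifice becomes two smaller double-half-ellipse
openings whose long axes are the unclipped segments.  Their short axes are
sized by requiring that (i) the anterior/posterior short-axis ratio matches
the untreated valve, (ii) short axes scale with their opening's long axis,
and (iii) the total leaflet free-edge length at E-wave peak (the sum of the
half-ellipse arcs) is conserved relative to the untreated orifice.  The last
condition fixes a single multiplier ``k`` found by root-finding on exact
ellipse arc-length integrals.

Coordinates: valve plane is 2D, origin at the annulus center, x along the
long axis, +y toward anterior.  Lengths are mm; areas are reported in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .tensors import FluidProperties

__all__ = [
    "ValveAxes",
    "ScalingSchedule",
    "ClipSpec",
    "ClippedGeometry",
    "interpolate_scalings",
    "opening_area",
    "area_at_time",
    "half_ellipse_arc",
    "size_clipped_valve",
    "clipped_area_at_time",
    "point_in_orifice",
    "jet_reynolds_number",
]

#: Default keyframes: (time s, anterior scale, posterior scale) at diastole
#: start, E-wave peak, diastasis start, diastasis end, A-wave peak, diastole
#: end.  The closed-valve scalings (0.40, -0.57) give a non-positive summed
#: projection, i.e. zero opening area.
DEFAULT_KNOTS = (
    (0.420, 0.40, -0.57),
    (0.525, 1.00, 1.00),
    (0.644, 0.50, 0.70),
    (0.711, 0.50, 0.70),
    (0.779, 0.85, 0.85),
    (0.830, 0.40, -0.57),
)


@dataclass(frozen=True)
class ValveAxes:
    """Untreated-orifice semi-axes, mm.

    ``l`` is the semi-long axis (half the intercommissural diameter), ``saa``
    and ``sap`` the anterior and posterior short semi-axes.
    """

    l: float = 12.8
    saa: float = 8.1
    sap: float = 11.6

    def __post_init__(self) -> None:
        if not (self.l > 0 and self.saa > 0 and self.sap > 0):
            raise ValueError("valve axes must be strictly positive")


@dataclass
class ScalingSchedule:
    """Short-axis scaling keyframes with monotone cubic Hermite interpolation.

    Monotone (Fritsch–Carlson) tangents avoid overshoot past the physical
    maximum scaling of 1.0 and keep the diastasis plateau exactly flat.
    """

    knots: tuple = DEFAULT_KNOTS
    _saa: PchipInterpolator = dc_field(init=False, repr=False)
    _sap: PchipInterpolator = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 2 or k.shape[1] != 3 or k.shape[0] < 2:
            raise ValueError("knots must be a sequence of (time, saa_scale, sap_scale)")
        if np.any(np.diff(k[:, 0]) <= 0):
            raise ValueError("knot times must be strictly increasing")
        self._saa = PchipInterpolator(k[:, 0], k[:, 1])
        self._sap = PchipInterpolator(k[:, 0], k[:, 2])

    @property
    def t_start(self) -> float:
        return float(np.asarray(self.knots)[0][0])

    @property
    def t_end(self) -> float:
        return float(np.asarray(self.knots)[-1][0])


@dataclass(frozen=True)
class ClipSpec:
    """Edge-to-edge clip: center at ``s * l`` along the long axis, occluding
    ``width`` mm of the coaptation line.  ``s < 0`` is anterolateral,
    ``s > 0`` posteromedial."""

    s: float = 0.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if not -1.0 < self.s < 1.0:
            raise ValueError("clip position scale s must lie in (-1, 1)")
        if self.width < 0:
            raise ValueError("clip width must be non-negative")

    def validate_against(self, axes: ValveAxes) -> None:
        if axes.l * (1.0 - abs(self.s)) - self.width / 2.0 <= 0:
            raise ValueError(
                "clip leaves a non-positive orifice segment: need l*(1-|s|) - width/2 > 0"
            )


@dataclass(frozen=True)
class ClippedGeometry:
    """Sized double-orifice geometry after clipping (all semi-axes, mm).

    Opening 1 is the segment on the negative-x (anterolateral) side of the
    clip, opening 2 on the positive-x side.  ``k`` is the common short-axis
    multiplier fixed by free-edge-length conservation at E-wave peak.
    """

    a1: float
    b_a1: float
    b_p1: float
    a2: float
    b_a2: float
    b_p2: float
    k: float


def interpolate_scalings(sched: ScalingSchedule, t) -> tuple:
    """Short-axis scale factors at time ``t`` (s) within diastole."""
    t = np.asarray(t, dtype=float)
    if np.any(t < sched.t_start) or np.any(t > sched.t_end):
        raise ValueError(
            f"t outside the diastole window [{sched.t_start}, {sched.t_end}] "
            "(the valve is closed in systole)"
        )
    return sched._saa(t)[()], sched._sap(t)[()]


def opening_area(axes: ValveAxes, saa_scale: float, sap_scale: float) -> float:
    """Orifice area in cm^2 for given short-axis scalings.

    The two half ellipses give area (pi/2) l (saa_scale*saa + sap_scale*sap);
    when the scaled leaflet projections overlap (negative sum) the valve is
    closed and the area is zero.
    """
    span = saa_scale * axes.saa + sap_scale * axes.sap
    return float((np.pi / 2.0) * axes.l * max(0.0, span) / 100.0)


def area_at_time(axes: ValveAxes, sched: ScalingSchedule, t: float) -> float:
    """Orifice area (cm^2) over the cycle; zero outside the diastole window."""
    if t < sched.t_start or t > sched.t_end:
        return 0.0
    sa, sp = interpolate_scalings(sched, t)
    return opening_area(axes, float(sa), float(sp))


def half_ellipse_arc(a: float, b: float) -> float:
    """Arc length of a half ellipse with semi-axes ``a``, ``b``.

    Adaptive quadrature of the exact integrand; relative tolerance 1e-10.
    """
    if a < 0 or b < 0:
        raise ValueError("semi-axes must be non-negative")
    val, _ = quad(
        lambda th: np.hypot(a * np.sin(th), b * np.cos(th)),
        0.0,
        np.pi,
        epsrel=1e-10,
        epsabs=1e-12,
        limit=200,
    )
    return float(val)


def _segments(axes: ValveAxes, clip: ClipSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """(center, semi-length) of the two unclipped long-axis segments."""
    left_hi = clip.s * axes.l - clip.width / 2.0
    right_lo = clip.s * axes.l + clip.width / 2.0
    c1 = (-axes.l + left_hi) / 2.0
    a1 = (left_hi + axes.l) / 2.0
    c2 = (right_lo + axes.l) / 2.0
    a2 = (axes.l - right_lo) / 2.0
    return (c1, a1), (c2, a2)


def size_clipped_valve(axes: ValveAxes, clip: ClipSpec) -> ClippedGeometry:
    """Size the two post-clip openings by free-edge-length conservation.

    The long semi-axes come directly from the unclipped segments.  Each
    opening keeps the untreated anterior/posterior short-axis ratio and short
    axes proportional to its own long axis: ``b_a,i = k a_i saa / l`` and
    ``b_p,i = k a_i sap / l``.  The multiplier ``k`` is the root of

        sum_i [arc(a_i, b_a,i) + arc(a_i, b_p,i)] = arc(l, saa) + arc(l, sap)

    bracketed on [1, k_max] and solved to 1e-10 (the total long-axis length
    shrinks by the clip width, so the short axes must grow, k >= 1).
    """
    clip.validate_against(axes)
    (_, a1), (_, a2) = _segments(axes, clip)
    target = half_ellipse_arc(axes.l, axes.saa) + half_ellipse_arc(axes.l, axes.sap)

    def edge_deficit(k: float) -> float:
        total = 0.0
        for a in (a1, a2):
            total += half_ellipse_arc(a, k * a * axes.saa / axes.l)
            total += half_ellipse_arc(a, k * a * axes.sap / axes.l)
        return total - target

    lo, hi = 1.0, 2.0
    f_lo = edge_deficit(lo)
    if f_lo > 1e-9:
        raise ValueError("degenerate clip: edge length already exceeds target at k=1")
    if abs(f_lo) <= 1e-9:
        k = 1.0
    else:
        while edge_deficit(hi) < 0:
            hi *= 2.0
            if hi > 1e3:
                raise ValueError("no edge-conserving multiplier k in bracket")
        k = float(brentq(edge_deficit, lo, hi, xtol=1e-10, rtol=1e-12))
    return ClippedGeometry(
        a1=a1,
        b_a1=k * a1 * axes.saa / axes.l,
        b_p1=k * a1 * axes.sap / axes.l,
        a2=a2,
        b_a2=k * a2 * axes.saa / axes.l,
        b_p2=k * a2 * axes.sap / axes.l,
        k=k,
    )


@lru_cache(maxsize=128)
def _sized(axes: ValveAxes, clip: ClipSpec) -> ClippedGeometry:
    return size_clipped_valve(axes, clip)


def clipped_area_at_time(
    axes: ValveAxes, sched: ScalingSchedule, clip: ClipSpec, t: float
) -> float:
    """Total area (cm^2) of the two post-clip openings at time ``t``.

    Both openings follow the untreated opening/closing schedule.
    """
    if t < sched.t_start or t > sched.t_end:
        return 0.0
    sa, sp = interpolate_scalings(sched, t)
    geom = _sized(axes, clip)
    total = 0.0
    for a, ba, bp in ((geom.a1, geom.b_a1, geom.b_p1), (geom.a2, geom.b_a2, geom.b_p2)):
        total += (np.pi / 2.0) * a * max(0.0, float(sa) * ba + float(sp) * bp)
    return total / 100.0


def point_in_orifice(
    axes: ValveAxes,
    sched: ScalingSchedule,
    clip: ClipSpec | None,
    point: tuple[float, float],
    t: float,
) -> bool:
    """Is a valve-plane point (x, y) in mm inside the open orifice at ``t``?

    The open region at long-axis coordinate x spans from the posterior edge
    ``-sap_scale * b_p * sqrt(1 - (x/a)^2)`` to the anterior edge
    ``saa_scale * b_a * sqrt(1 - (x/a)^2)`` of the relevant (sub-)opening.
    """
    if t < sched.t_start or t > sched.t_end:
        return False
    sa, sp = interpolate_scalings(sched, t)
    sa, sp = float(sa), float(sp)
    x, y = point
    if clip is None:
        openings = [(0.0, axes.l, axes.saa, axes.sap)]
    else:
        geom = _sized(axes, clip)
        (c1, _), (c2, _) = _segments(axes, clip)
        openings = [
            (c1, geom.a1, geom.b_a1, geom.b_p1),
            (c2, geom.a2, geom.b_a2, geom.b_p2),
        ]
    for c, a, ba, bp in openings:
        xi = (x - c) / a
        if abs(xi) >= 1.0:
            continue
        half = np.sqrt(1.0 - xi * xi)
        if -sp * bp * half < y < sa * ba * half:
            return True
    return False


def jet_reynolds_number(
    fluid: FluidProperties, peak_velocity: float, opening_area_cm2: float
) -> float:
    """Reynolds number of the inflow jet.

    Uses the diameter of the circle with the given opening area as length
    scale: ``D = sqrt(4 A / pi)``, ``Re = rho U D / mu``.
    """
    if peak_velocity <= 0 or opening_area_cm2 <= 0:
        raise ValueError("peak velocity and opening area must be positive")
    area_m2 = opening_area_cm2 * 1e-4
    d = float(np.sqrt(4.0 * area_m2 / np.pi))
    return fluid.density * peak_velocity * d / fluid.dynamic_viscosity
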