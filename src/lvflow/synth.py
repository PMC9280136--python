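"""Deterministic synthetic fixtures for every pipeline input.

Analytic velocity fields with closed-form gradients (plane Couette shear,
solid-body rotation, irrotational extensional flow, a Lamb–Oseen vortex and a
tanh-profile round jet), seeded random gradient tensors, and LV volume curves
with controlled E/A-wave landmark structure.  These stand in for patient CFD
data: they reproduce the canonical local flow structures (shear layers,
vortex cores, jets) and the diastolic filling morphology, but none of the
geometric complexity or turbulence of a real ventricle.

Every stochastic generator takes an explicit seed; fixtures are reproducible
bit-for-bit from their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import GridVelocityField
from .timing import PhaseTimings, VolumeCurve

__all__ = [
    "FieldSpec",
    "VolumeCurveSpec",
    "make_field",
    "make_volume_curve",
    "random_gradients",
    "random_orthogonal",
    "FIELD_CASES",
]

FIELD_CASES = (
    "couette",
    "solid_rotation",
    "extensional",
    "lamb_oseen",
    "round_jet",
    "superposition",
)

#: Default per-case parameters (SI units; rates 1/s, lengths m, velocity m/s).
_DEFAULTS = {
    "couette": {"k": 100.0},
    "solid_rotation": {"omega": 50.0},
    "extensional": {"a": 30.0, "b": 20.0},
    "lamb_oseen": {"gamma": 0.01, "rc": 0.02},
    "round_jet": {"u": 1.0, "r": 0.02, "delta": 0.004},
}


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for an analytic velocity-field fixture.

    The grid is cubic with ``n`` nodes per axis spanning ``[-extent/2,
    extent/2]`` in each direction (so the flow feature sits at the center).
    ``params`` overrides the per-case defaults; ``components`` lists the
    member specs of a ``superposition`` case.
    """

    case: str
    n: int = 64
    extent: float = 0.1
    time: float = 0.0
    params: tuple = ()
    components: tuple = ()

    def __post_init__(self) -> None:
        if self.case not in FIELD_CASES:
            raise ValueError(f"unknown case {self.case!r}; expected one of {FIELD_CASES}")
        if self.n < 3:
            raise ValueError("need at least 3 nodes per axis")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        p = dict(self.params)
        if self.case != "superposition":
            bad = set(p) - set(_DEFAULTS[self.case])
            if bad:
                raise ValueError(f"unknown parameters for {self.case}: {sorted(bad)}")
            if any(v <= 0 for k, v in p.items() if k in ("rc", "r", "delta")):
                raise ValueError("geometric scales must be positive")
        elif not self.components:
            raise ValueError("superposition requires component specs")

    def resolved_params(self) -> dict:
        out = dict(_DEFAULTS.get(self.case, {}))
        out.update(dict(self.params))
        return out


def _grid(spec: FieldSpec):
    half = spec.extent / 2.0
    axis = np.linspace(-half, half, spec.n)
    spacing = np.full(3, axis[1] - axis[0])
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
    return x, y, z, spacing, np.full(3, -half)


def _eval_case(case: str, p: dict, x, y, z):
    """Velocity (..., 3) and exact gradient (..., 3, 3) of one analytic case."""
    shape = x.shape
    u = np.zeros(shape + (3,))
    g = np.zeros(shape + (3, 3))
    if case == "couette":
        k = p["k"]
        u[..., 0] = k * y
        g[..., 0, 1] = k
    elif case == "solid_rotation":
        w = p["omega"]
        u[..., 0] = -w * y
        u[..., 1] = w * x
        g[..., 0, 1] = -w
        g[..., 1, 0] = w
    elif case == "extensional":
        a, b = p["a"], p["b"]
        u[..., 0] = a * x
        u[..., 1] = b * y
        u[..., 2] = -(a + b) * z
        g[..., 0, 0] = a
        g[..., 1, 1] = b
        g[..., 2, 2] = -(a + b)
    elif case == "lamb_oseen":
        gam, rc = p["gamma"], p["rc"]
        r2 = x**2 + y**2
        small = r2 < (1e-6 * rc) ** 2
        r2s = np.where(small, 1.0, r2)
        ex = np.exp(-r2 / rc**2)
        # f = u_theta / r;  u = (-f y, f x, 0)
        f = np.where(small, gam / (2 * np.pi * rc**2), gam / (2 * np.pi * r2s) * (1 - ex))
        # df/d(r^2)
        fp = np.where(
            small,
            -gam / (4 * np.pi * rc**4),
            gam / (2 * np.pi) * (-(1 - ex) / r2s**2 + ex / (r2s * rc**2)),
        )
        u[..., 0] = -f * y
        u[..., 1] = f * x
        g[..., 0, 0] = -2 * fp * x * y
        g[..., 0, 1] = -f - 2 * fp * y * y
        g[..., 1, 0] = f + 2 * fp * x * x
        g[..., 1, 1] = 2 * fp * x * y
    elif case == "round_jet":
        uu, rr, de = p["u"], p["r"], p["delta"]
        r = np.sqrt(x**2 + y**2)
        rs = np.where(r < 1e-12, 1.0, r)
        uz = uu / 2.0 * (1.0 - np.tanh((r - rr) / de))
        dudr = -uu / (2.0 * de) / np.cosh((r - rr) / de) ** 2
        u[..., 2] = uz
        g[..., 2, 0] = dudr * x / rs
        g[..., 2, 1] = dudr * y / rs
    else:  # pragma: no cover - guarded by FieldSpec validation
        raise ValueError(f"unknown case {case!r}")
    return u, g


def make_field(spec: FieldSpec) -> tuple[GridVelocityField, np.ndarray]:
    """Build the fixture field and its exact (closed-form) gradient field.

    Returns ``(field, grad)`` with ``grad`` of shape (n, n, n, 3, 3); for a
    superposition the velocities and gradients of the members are summed
    pointwise.
    """
    x, y, z, spacing, origin = _grid(spec)
    if spec.case == "superposition":
        u = np.zeros(x.shape + (3,))
        g = np.zeros(x.shape + (3, 3))
        for sub in spec.components:
            ui, gi = _eval_case(sub.case, sub.resolved_params(), x, y, z)
            u += ui
            g += gi
    else:
        u, g = _eval_case(spec.case, spec.resolved_params(), x, y, z)
    field = GridVelocityField(velocity=u, spacing=spacing, origin=origin, time=spec.time)
    return field, g


def random_gradients(n: int, scale: float = 100.0, seed: int = 0) -> np.ndarray:
    """Seeded batch of Gaussian random 3x3 velocity-gradient tensors (1/s)."""
    rng = np.random.default_rng(seed)
    return rng.normal(scale=scale, size=(n, 3, 3))


def random_orthogonal(n: int, seed: int = 0) -> np.ndarray:
    """Seeded batch of Haar-ish random orthogonal 3x3 matrices (QR method)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 3, 3))
    q, r = np.linalg.qr(a)
    # fix signs so the factorization is unique (diag(r) > 0)
    sgn = np.sign(np.einsum("nii->ni", r))
    sgn[sgn == 0] = 1.0
    return q * sgn[:, None, :]


@dataclass(frozen=True)
class VolumeCurveSpec:
    """Recipe for a synthetic LV volume curve over one cardiac cycle.

    dV/dt is a piecewise beta-shaped model: one negative systolic emptying
    bump on [0, diastole_start] integrating to -EDV*EF, an E-wave bump
    peaking exactly at ``e_peak`` and vanishing at the diastasis trough, and
    an A-wave bump from the trough to ``period``.  The E-wave carries
    fraction ``e_fraction`` of the filling volume.  Each bump is
    ``x^a (1-x)^b`` on its support; the rise exponent is a free shape
    parameter and the fall exponent follows from the peak position.  The
    E-wave rise exponent slightly above 1 makes the systole/diastole
    transition a transversal zero crossing of dV/dt (volume curvature jumps
    positive at E-wave onset, as in measured curves) rather than a
    degenerate tangency; the larger A-wave exponent reproduces the brief,
    peaked atrial kick.  Integration uses the exact (regularized incomplete
    beta) antiderivative, so the noise-free curve attains EDV and
    EDV*(1-EF) exactly.

    Defaults follow a typical adult LV at 72 bpm morphology: EDV 117 ml,
    EF 0.64, diastole spanning 0.420-0.830 s with E-peak at 0.525 s, the
    diastasis trough at 0.6775 s and A-peak at 0.779 s; 25 frames.
    """

    edv: float = 117.0
    ef: float = 0.64
    diastole_start: float = 0.420
    e_peak: float = 0.525
    trough: float = 0.6775
    a_peak: float = 0.779
    period: float = 0.830
    e_fraction: float = 0.78
    systole_exponents: tuple = (2.0, 1.0)
    e_rise_exponent: float = 1.3
    a_rise_exponent: float = 8.0
    frames: int = 25
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ef < 1.0:
            raise ValueError("ejection fraction must be in (0, 1)")
        if self.edv <= 0:
            raise ValueError("EDV must be positive")
        marks = (0.0, self.diastole_start, self.e_peak, self.trough, self.a_peak, self.period)
        if np.any(np.diff(marks) <= 0):
            raise ValueError("landmarks must satisfy 0 < diastole_start < e_peak < trough < a_peak < period")
        if not 0.0 < self.e_fraction < 1.0:
            raise ValueError("e_fraction must be in (0, 1)")
        if self.frames < 8:
            raise ValueError("need at least 8 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


class _BetaBump:
    """Unit-mass bump ``x^a (1-x)^b`` on [t0, t1] with exact CDF.

    ``pdf`` peaks at ``t0 + (t1 - t0) * a / (a + b)``.
    """

    def __init__(self, t0: float, t1: float, a: float, b: float):
        from scipy.special import beta as beta_fn

        self.t0, self.t1, self.a, self.b = t0, t1, a, b
        self._norm = beta_fn(a + 1.0, b + 1.0) * (t1 - t0)

    def _x(self, t):
        return np.clip((np.asarray(t, dtype=float) - self.t0) / (self.t1 - self.t0), 0.0, 1.0)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        x = self._x(t)
        inside = (t > self.t0) & (t < self.t1)
        return np.where(inside, x**self.a * (1.0 - x) ** self.b / self._norm, 0.0)

    def cdf(self, t):
        from scipy.special import betainc

        return betainc(self.a + 1.0, self.b + 1.0, self._x(t))

    @property
    def peak_height(self) -> float:
        a, b = self.a, self.b
        return float((a / (a + b)) ** a * (b / (a + b)) ** b / self._norm)


def volume_model(spec: VolumeCurveSpec):
    """Return callables ``(V, dVdt)`` of the noise-free volume model (ml, ml/s)."""
    sv = spec.edv * spec.ef
    ds, ep, tr, ap, T = (
        spec.diastole_start,
        spec.e_peak,
        spec.trough,
        spec.a_peak,
        spec.period,
    )
    sys_bump = _BetaBump(0.0, ds, *spec.systole_exponents)
    # fall exponents follow from the required peak positions
    ea = spec.e_rise_exponent
    e_bump = _BetaBump(ds, tr, ea, ea * (tr - ep) / (ep - ds))
    aa = spec.a_rise_exponent
    a_bump = _BetaBump(tr, T, aa, aa * (T - ap) / (ap - tr))
    m_e = spec.e_fraction * sv
    m_a = (1.0 - spec.e_fraction) * sv

    def v(t):
        return (spec.edv - sv * sys_bump.cdf(t) + m_e * e_bump.cdf(t) + m_a * a_bump.cdf(t))[()]

    def dvdt(t):
        return (-sv * sys_bump.pdf(t) + m_e * e_bump.pdf(t) + m_a * a_bump.pdf(t))[()]

    # E-peak filling rate must dominate the A-peak for E/A morphology
    if m_e * e_bump.peak_height <= m_a * a_bump.peak_height:
        raise ValueError("e_fraction too small: A-wave would dominate the E-wave")
    return v, dvdt


def make_volume_curve(spec: VolumeCurveSpec) -> tuple[VolumeCurve, PhaseTimings]:
    """Sample the volume model at ``frames`` uniform times over one cycle.

    Returns the (optionally noisy) sampled curve together with the
    ground-truth landmarks; diastasis start/end follow the frame-bracketing
    definition applied to the known trough time.
    """
    v, _ = volume_model(spec)
    t = np.linspace(0.0, spec.period, spec.frames)
    vol = np.asarray(v(t), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(scale=spec.noise_sd, size=vol.shape)
        vol = np.maximum(vol, 1e-3)
    truth = PhaseTimings(
        diastole_start=spec.diastole_start,
        e_peak=spec.e_peak,
        diastasis_start=float(t[t <= spec.trough][-1]),
        diastasis_end=float(t[t >= spec.trough][0]),
        a_peak=spec.a_peak,
        diastole_end=spec.period,
    )
    return VolumeCurve(times=t, volumes=vol), truth
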