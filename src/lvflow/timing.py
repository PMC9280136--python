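"""Cardiac-phase landmark detection from sampled LV volume curves.

A cubic smoothing spline V(t) is fitted to the frame-wise left-ventricular
volume samples; the six landmarks that anchor the valve schedule are read off
its derivative dV/dt:

* diastole start — the zero crossing where dV/dt turns from negative
  (contraction) to positive (expansion);
* E-wave and A-wave peaks — the two largest local maxima of dV/dt in
  diastole, the E-wave being the earlier and higher one;
* diastasis start/end — the two original frame times bracketing the local
  minimum of dV/dt between the two peaks;
* diastole end — the final sample time (isovolumetric phases are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "VolumeCurve",
    "PhaseTimings",
    "fit_volume_spline",
    "detect_phases",
    "ejection_fraction",
]

LANDMARK_NAMES = (
    "diastole_start",
    "e_peak",
    "diastasis_start",
    "diastasis_end",
    "a_peak",
    "diastole_end",
)


@dataclass
class VolumeCurve:
    """Sampled LV volume trace: times in s (strictly increasing), volumes in ml."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if len(self.times) < 8:
            raise ValueError("need at least 8 volume samples")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.volumes))):
            raise ValueError("volume curve contains non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")


@dataclass(frozen=True)
class PhaseTimings:
    """The six cardiac landmarks, s.  Landmarks that could not be detected
    (e.g. no A-wave) are None and listed in ``missing``."""

    diastole_start: float | None
    e_peak: float | None
    diastasis_start: float | None
    diastasis_end: float | None
    a_peak: float | None
    diastole_end: float | None
    missing: tuple = dc_field(default=())

    @property
    def complete(self) -> bool:
        return not self.missing

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def __post_init__(self) -> None:
        if self.complete:
            vals = [getattr(self, n) for n in LANDMARK_NAMES]
            if any(v is None for v in vals):
                raise ValueError("complete timings may not contain None")
            if np.any(np.diff(vals) < 0):
                raise ValueError(f"landmarks out of order: {vals}")


def fit_volume_spline(curve: VolumeCurve, smoothing="gcv") -> BSpline:
    """Cubic smoothing spline fit of the volume trace.

    ``smoothing`` is the roughness-penalty weight ``lam`` (0 gives the
    interpolating natural cubic spline); the default ``"gcv"`` selects it by
    generalized cross-validation.  Returns a ``BSpline`` (callable, with
    ``.derivative()``).
    """
    if isinstance(smoothing, str):
        if smoothing not in ("gcv", "auto"):
            raise ValueError("smoothing must be a non-negative number, 'gcv' or 'auto'")
        lam = None
    else:
        lam = float(smoothing)
        if lam < 0:
            raise ValueError("smoothing must be non-negative")
    return make_smoothing_spline(curve.times, curve.volumes, lam=lam)


def _refine_max(f, lo: float, hi: float) -> float:
    res = minimize_scalar(
        lambda t: -f(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def _refine_min(f, lo: float, hi: float) -> float:
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7})
    return float(res.x)


def detect_phases(v: BSpline, frame_times) -> PhaseTimings:
    """Detect the six cardiac landmarks from a fitted volume spline.

    ``frame_times`` are the original sample times; they bound the search and
    supply the frames bracketing the diastasis trough.  Extrema and zero
    crossings are refined to 1e-6 s.  If fewer than two dV/dt maxima exist in
    diastole (no distinguishable A-wave), a partial result is returned with
    the unresolved landmarks flagged in ``missing``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    t0, t1 = float(frame_times[0]), float(frame_times[-1])
    dv = v.derivative()
    tt = np.linspace(t0, t1, 4001)
    vv = v(tt)
    dd = dv(tt)

    # diastole start: first negative-to-positive crossing of dV/dt at/after
    # the global volume minimum (robust to small systolic oscillations)
    i_min = int(np.argmin(vv))
    sign = np.sign(dd)
    crossings = np.nonzero((sign[:-1] < 0) & (sign[1:] > 0))[0]
    crossings = crossings[crossings >= max(i_min - 1, 0)]
    if len(crossings) == 0:
        # fall back to any crossing before the volume minimum
        crossings = np.nonzero((sign[:-1] < 0) & (sign[1:] > 0))[0]
    if len(crossings) == 0:
        return PhaseTimings(None, None, None, None, None, t1, missing=LANDMARK_NAMES[:5])
    i = int(crossings[0])
    ds = float(brentq(dv, tt[i], tt[i + 1], xtol=1e-7))

    # local maxima of dV/dt in diastole
    dias = np.nonzero(tt > ds)[0]
    cand = [
        j
        for j in dias[1:-1]
        if dd[j] >= dd[j - 1] and dd[j] >= dd[j + 1] and dd[j] > 0
    ]
    peaks = []
    for j in cand:
        tp = _refine_max(dv, tt[j - 1], tt[j + 1])
        if not any(abs(tp - p) < 1e-4 for p, _ in peaks):
            peaks.append((tp, float(dv(tp))))
    peaks.sort(key=lambda p: -p[1])
    if len(peaks) < 2:
        e = peaks[0][0] if peaks else None
        missing = ("diastasis_start", "diastasis_end", "a_peak") + (
            ("e_peak",) if e is None else ()
        )
        return PhaseTimings(ds, e, None, None, None, t1, missing=tuple(sorted(missing)))
    (p1, _), (p2, _) = peaks[0], peaks[1]
    e, a = (p1, p2) if p1 < p2 else (p2, p1)

    # diastasis: frames bracketing the dV/dt trough between the peaks
    trough = _refine_min(dv, e, a)
    below = frame_times[frame_times <= trough]
    above = frame_times[frame_times >= trough]
    if len(below) == 0 or len(above) == 0:
        return PhaseTimings(
            ds, e, None, None, a, t1, missing=("diastasis_start", "diastasis_end")
        )
    d_start = float(below[-1])
    d_end = float(above[0])
    if d_end == d_start:  # trough exactly on a frame: take its neighbours
        k = int(np.searchsorted(frame_times, trough))
        d_start = float(frame_times[max(k - 1, 0)])
        d_end = float(frame_times[min(k + 1, len(frame_times) - 1)])
    return PhaseTimings(ds, e, d_start, d_end, a, t1)


def ejection_fraction(curve: VolumeCurve) -> tuple[float, float, float]:
    """(EDV ml, ESV ml, EF) from the raw samples: EF = (EDV - ESV) / EDV."""
    edv = float(np.max(curve.volumes))
    esv = float(np.min(curve.volumes))
    return edv, esv, (edv - esv) / edv
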