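"""Quasi-linear viscoelasticity on the incompressible uniaxial path.

The time-dependent second Piola-Kirchhoff stress is the instantaneous
elastic response minus a sum of viscous overstresses,

    S(t) = S_e(lam(t)) - sum_i Q_i(t),

where each internal variable obeys the linear evolution equation

    dQ_i/dt + Q_i / tau_i = (gamma_i / tau_i) S_e(lam(t)),    Q_i(-inf) = 0,

with gamma_i the relative stiffness of the i-th viscous process and
tau_i its relaxation time.  On the uniaxial path the tensorial
deviatoric bookkeeping reduces to this scalar form: the branches are
driven by the axial elastic stress with the hydrostatic term already
eliminated by the zero-transverse-stress condition, and constant
factors of the deviatoric projection are absorbed into gamma_i.

For a constant-strain hold the equations integrate in closed form to
the reduced relaxation function

    R(t) = S(t) / S(0) = 1 - sum_i gamma_i (1 - exp(-t / tau_i)),

which is independent of the strain level (quasi-linearity).  For
arbitrary strain histories a recursive exponential integrator is used:
over a step [t_n, t_n+1] with x = dt/tau_i and a piecewise-linear
elastic drive,

    Q_i^{n+1} = e^-x Q_i^n + gamma_i [ S_e^n (1 - e^-x)
                + (S_e^{n+1} - S_e^n) (1 - (1 - e^-x)/x) ],

which is the exact solution of the evolution equation for that drive,
is unconditionally stable, and converges to the closed-form hold
solution as dt -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .constitutive import (
    STRESS_MEASURES,
    HyperelasticParams,
    convert_stress,
    elastic_axial_stress,
)

__all__ = [
    "PronySeries",
    "ViscousState",
    "StressTrace",
    "reduced_relaxation",
    "step_relaxation",
    "integrate_history",
    "ramp_curve",
    "secant_modulus",
    "decay_rate",
    "default_hold_times",
    "REPORTING_INSTANTS",
]

REPORTING_INSTANTS = (0.1, 6.0, 72.0, 240.0)

_TRACE_MEASURES = STRESS_MEASURES + ("normalized",)


@dataclass(frozen=True)
class PronySeries:
    """Prony series: ordered (gamma_i, tau_i) viscous branches.

    gamma_i are dimensionless relative stiffnesses in (0, 1] with
    sum(gamma_i) <= 1; tau_i are relaxation times in seconds.  Branches
    are stored sorted by ascending tau.  An empty series (m = 0) is the
    purely elastic limit.
    """

    branches: tuple[tuple[float, float], ...]

    def __init__(self, branches: Iterable[Sequence[float]] = ()):
        pairs = sorted((float(g), float(t)) for g, t in branches)
        pairs = tuple(sorted(pairs, key=lambda p: p[1]))
        for g, t in pairs:
            if not 0.0 < g <= 1.0:
                raise ValueError(f"gamma must be in (0, 1], got {g}")
            if not t > 0.0:
                raise ValueError(f"tau must be positive, got {t}")
        total = sum(g for g, _ in pairs)
        if total > 1.0 + 1e-12:
            raise ValueError(f"sum of gamma exceeds 1: {total}")
        object.__setattr__(self, "branches", pairs)

    @property
    def m(self) -> int:
        return len(self.branches)

    @property
    def gammas(self) -> np.ndarray:
        return np.array([g for g, _ in self.branches])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.branches])

    @property
    def gamma_total(self) -> float:
        return float(sum(g for g, _ in self.branches))

    def to_dict(self) -> dict:
        return {
            "gamma": [g for g, _ in self.branches],
            "tau_s": [t for _, t in self.branches],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PronySeries":
        return cls(zip(d["gamma"], d["tau_s"]))


@dataclass
class ViscousState:
    """Per-branch internal overstress (axial second-PK component, MPa)."""

    q: np.ndarray
    t: float = 0.0


@dataclass(eq=False)
class StressTrace:
    """Sampled axial stress history with its strain history and metadata."""

    times: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    measure: str = "nominal"
    sample_id: str | None = None
    donor_id: str | None = None
    strain_level: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if not (len(self.times) == len(self.stress) == len(self.strain)):
            raise ValueError("times, stress and strain must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.measure not in _TRACE_MEASURES:
            raise ValueError(
                f"unknown measure {self.measure!r}; expected one of {_TRACE_MEASURES}"
            )

    def __len__(self) -> int:
        return len(self.times)

    def stress_at(self, t) -> np.ndarray | float:
        """Linear interpolation of the stress at time(s) ``t``."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.times[0]) or np.any(t_arr > self.times[-1]):
            raise ValueError("requested time outside trace support")
        out = np.interp(t_arr, self.times, self.stress)
        return out if out.ndim else float(out)


def default_hold_times(
    hold_duration: float = 240.0,
    t_start: float = 0.01,
    n_per_decade: int = 25,
) -> np.ndarray:
    """Log-spaced sampling grid for a relaxation hold.

    Covers [t_start, hold_duration] with ``n_per_decade`` points per
    decade plus the reporting instants 0.1, 6, 72 and 240 s.
    """
    decades = math.log10(hold_duration / t_start)
    n = max(int(round(decades * n_per_decade)), 2)
    grid = np.geomspace(t_start, hold_duration, n)
    extra = [t for t in REPORTING_INSTANTS if t_start <= t <= hold_duration]
    return np.unique(np.concatenate([grid, extra]))


def reduced_relaxation(ps: PronySeries, t) -> np.ndarray | float:
    """Reduced relaxation function R(t) = 1 - sum_i gamma_i (1 - e^(-t/tau_i)).

    R(0) = 1, R is non-increasing, and R(inf) = 1 - sum gamma_i.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.ones_like(t_arr)
    for g, tau in ps.branches:
        out = out - g * (-np.expm1(-t_arr / tau))
    return out if out.ndim else float(out)


def step_relaxation(
    hp: HyperelasticParams,
    ps: PronySeries,
    strain: float,
    times,
    measure: str = "nominal",
) -> StressTrace:
    """Closed-form stress during an ideal step-and-hold relaxation test.

    The strain jumps instantaneously to ``strain`` (nominal) at t = 0
    from a virgin state and is held; S(t) = R(t) * S_elastic.  The
    normalized trace S(t)/S(0) is independent of the hyperelastic
    parameters and of the strain level.
    """
    if strain < 0:
        raise ValueError("strain must be non-negative")
    times = np.asarray(times, dtype=float)
    lam = 1.0 + strain
    s_el = getattr(elastic_axial_stress(hp, lam), measure)
    stress = s_el * np.asarray(reduced_relaxation(ps, times), dtype=float)
    return StressTrace(
        times=times,
        stress=stress,
        strain=np.full_like(times, strain),
        measure=measure,
        strain_level=strain,
    )


def _integrate_on_grid(
    hp: HyperelasticParams,
    ps: PronySeries,
    strain: np.ndarray,
    times: np.ndarray,
    measure: str,
) -> StressTrace:
    """Exponential recursive integration of the viscous branches on a
    (possibly non-uniform) time grid with piecewise-linear elastic drive."""
    gammas = ps.gammas
    taus = ps.taus
    lam = 1.0 + strain
    # drive: axial second-PK elastic stress (hydrostatic term eliminated)
    s_el = np.array([elastic_axial_stress(hp, l).second_pk for l in lam])
    n = len(times)
    total = np.empty(n)
    q = np.zeros(ps.m)
    total[0] = s_el[0] - q.sum()
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        if ps.m:
            x = dt / taus
            a = np.exp(-x)
            w = -np.expm1(-x)  # 1 - e^-x
            q = a * q + gammas * (s_el[i - 1] * w + (s_el[i] - s_el[i - 1]) * (1.0 - w / x))
        total[i] = s_el[i] - q.sum()
    stress = convert_stress(total, lam, "second_pk", measure)
    return StressTrace(times=times, stress=stress, strain=strain, measure=measure)


def integrate_history(
    hp: HyperelasticParams,
    ps: PronySeries,
    strain_history: Callable[[np.ndarray], np.ndarray],
    t_end: float,
    dt: float | None = None,
    times=None,
    measure: str = "nominal",
) -> StressTrace:
    """Integrate the QLV stress response for an arbitrary strain history.

    ``strain_history`` maps time (array-valued, t >= 0) to nominal
    strain.  The material is virgin before t = 0 (all internal
    variables zero); a nonzero strain_history(0) is treated as an
    instantaneous step applied at t = 0.  Either a uniform step ``dt``
    or an explicit strictly increasing grid ``times`` must be given;
    the per-step exponential update is exact for piecewise-linear
    drives, so a non-uniform grid (fine over a ramp, coarse over a
    hold) loses no accuracy.
    """
    if times is None:
        if dt is None or dt <= 0:
            raise ValueError("dt must be positive (or pass an explicit times grid)")
        n = max(int(round(t_end / dt)), 1)
        times = np.linspace(0.0, t_end, n + 1)
    else:
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
    strain = np.asarray(strain_history(times), dtype=float)
    return _integrate_on_grid(hp, ps, strain, times, measure)


def ramp_curve(
    hp: HyperelasticParams,
    ps: PronySeries,
    strain_rate: float,
    target_strain: float,
    dt: float | None = None,
    measure: str = "cauchy",
) -> StressTrace:
    """Stress-strain curve for a constant-strain-rate tensile ramp.

    Integrates from the virgin state to ``target_strain`` at
    ``strain_rate`` (nominal strain per second).  By default the stress
    is reported in the Cauchy measure and dt is 1/500 of the ramp
    duration.
    """
    if strain_rate <= 0:
        raise ValueError("strain_rate must be positive")
    if target_strain <= 0:
        raise ValueError("target_strain must be positive")
    duration = target_strain / strain_rate
    if dt is None:
        dt = duration / 500.0
    return integrate_history(
        hp,
        ps,
        lambda t: np.minimum(strain_rate * t, target_strain),
        t_end=duration,
        dt=dt,
        measure=measure,
    )


def secant_modulus(trace: StressTrace, strain: float) -> float:
    """Secant modulus stress(strain)/strain (MPa), in the trace's measure.

    The stress at the requested nominal strain is found by linear
    interpolation along the trace's (monotone) strain history.
    """
    s = np.asarray(trace.strain)
    if strain < s.min() or strain > s.max():
        raise ValueError(
            f"strain {strain} outside trace range [{s.min()}, {s.max()}]"
        )
    if strain == 0:
        raise ValueError("secant modulus undefined at zero strain")
    # keep only the monotone loading part
    idx = np.argmax(s >= strain) if np.any(s >= strain) else len(s) - 1
    stress = np.interp(strain, s[: idx + 1], trace.stress[: idx + 1])
    return float(stress) / strain


def decay_rate(trace: StressTrace, t: float) -> float:
    """Normalized stress decay rate -d(S/S0)/dt * 100 (percent per second).

    S0 is the stress at the trace's first sample; the derivative is a
    local finite difference on the trace grid evaluated at ``t``
    (interior points only).
    """
    times = trace.times
    if t <= times[0] or t > times[-1]:
        raise ValueError("t must lie inside the trace support, past the first sample")
    s0 = trace.stress[0]
    if s0 == 0:
        raise ValueError("zero initial stress; normalization undefined")
    norm = trace.stress / s0
    grad = np.gradient(norm, times)
    return float(-np.interp(t, times, grad) * 100.0)
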