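"""Seeded generator of virtual stress-relaxation experiments.

Emulates the laboratory protocol on human plantar aponeurosis strips:
24 samples from 3 donors (7, 8 and 9 samples respectively), rectangular
strips of ~5 mm width and ~2.4-2.6 mm thickness at 10 mm gauge length,
each subjected to three consecutive relaxation tests at 4, 6 and 8 %
nominal strain.  The strain is ramped at 120 %/s, held for 240 s, and
the nominal stress (force / undeformed cross-section) is recorded on a
log-spaced grid.  Consecutive tests are independent: the rest period
between them lets the viscous state recover fully, so every test starts
from a virgin material.

Variability enters at two levels:

* between samples, through a log-normal perturbation of the relative
  stiffnesses gamma_i (relaxation-shape scatter, re-projected onto
  sum gamma <= 1) and of the strip geometry;
* within a trace, through multiplicative Gaussian stress noise
  (coefficient of variation ``stress_cv``) plus quantization of force
  and displacement at the testing machine's resolution (0.2 N,
  0.001 mm).

All randomness flows from explicit integer seeds via numpy Generators,
so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constitutive import HyperelasticParams
from .viscoelastic import (
    PronySeries,
    StressTrace,
    default_hold_times,
    integrate_history,
    step_relaxation,
)

__all__ = [
    "SampleGeometry",
    "Protocol",
    "NoiseModel",
    "SampleSpec",
    "RelaxationDataset",
    "generate_population",
    "simulate_experiment",
]

_DONOR_THICKNESS_MM = (2.40, 2.41, 2.57)  # per-donor mean strip thickness


@dataclass(frozen=True)
class SampleGeometry:
    """Rectangular strip geometry (mm)."""

    width_mm: float = 5.0
    thickness_mm: float = 2.45
    gauge_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.thickness_mm, self.gauge_length_mm) <= 0:
            raise ValueError("all geometry dimensions must be positive")

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.thickness_mm


@dataclass(frozen=True)
class Protocol:
    """Relaxation-test protocol.

    strain_levels: nominal strains applied consecutively to each sample;
    ramp_rate: nominal strain rate of the loading ramp, 1/s (1.2 = 120 %/s);
    hold_duration: length of the constant-strain hold, s;
    ideal_step: if True the ramp is replaced by an instantaneous step
    (closed-form traces); t_first/n_per_decade define the log-spaced
    hold sampling grid.
    """

    strain_levels: tuple[float, ...] = (0.04, 0.06, 0.08)
    ramp_rate: float = 1.2
    hold_duration: float = 240.0
    ideal_step: bool = False
    t_first: float = 0.01
    n_per_decade: int = 25
    rest_between_tests: bool = True

    def __post_init__(self) -> None:
        if any(not 0.0 < s <= 0.1 for s in self.strain_levels):
            raise ValueError("strain levels must lie in (0, 0.1]")
        if self.ramp_rate <= 0 or self.hold_duration <= 0:
            raise ValueError("ramp_rate and hold_duration must be positive")

    def hold_times(self) -> np.ndarray:
        return default_hold_times(self.hold_duration, self.t_first, self.n_per_decade)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and between-sample noise magnitudes.

    stress_cv: multiplicative Gaussian coefficient of variation per
    stress sample; sample_scatter: SD (log scale) of the per-sample
    log-normal perturbation of each gamma_i; tau_scatter: same for
    tau_i (off by default); force/displacement resolutions are the
    testing machine's quantization steps.
    """

    stress_cv: float = 0.03
    sample_scatter: float = 0.15
    tau_scatter: float = 0.0
    force_resolution_N: float = 0.2
    displacement_resolution_mm: float = 0.001
    geometry_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("stress_cv", "sample_scatter", "tau_scatter",
                     "force_resolution_N", "displacement_resolution_mm",
                     "geometry_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All noise sources off: generated traces equal the model exactly."""
        return cls(stress_cv=0.0, sample_scatter=0.0, tau_scatter=0.0,
                   force_resolution_N=0.0, displacement_resolution_mm=0.0,
                   geometry_cv=0.0)


@dataclass(frozen=True)
class SampleSpec:
    """One virtual tissue strip: geometry plus its true material parameters."""

    sample_id: str
    donor_id: str
    geometry: SampleGeometry
    hp: HyperelasticParams
    ps: PronySeries


@dataclass
class RelaxationDataset:
    """Collection of relaxation traces with the generating ground truth."""

    traces: list[StressTrace]
    population: list[SampleSpec] = field(default_factory=list)
    protocol: Protocol | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def by_strain(self, level: float) -> list[StressTrace]:
        return [tr for tr in self.traces
                if tr.strain_level is not None
                and abs(tr.strain_level - level) < 1e-9]

    @property
    def strain_levels(self) -> list[float]:
        return sorted({tr.strain_level for tr in self.traces
                       if tr.strain_level is not None})


def _perturb_gammas(ps: PronySeries, scatter: float, tau_scatter: float,
                    rng: np.random.Generator) -> PronySeries:
    g = ps.gammas * np.exp(rng.normal(0.0, scatter, ps.m)) if scatter > 0 \
        else ps.gammas.copy()
    t = ps.taus * np.exp(rng.normal(0.0, tau_scatter, ps.m)) if tau_scatter > 0 \
        else ps.taus.copy()
    total = g.sum()
    if total > 1.0:
        g *= (1.0 - 1e-9) / total
    return PronySeries(zip(g, t))


def generate_population(
    true_hp: HyperelasticParams,
    true_ps: PronySeries,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_donors: int = 3,
    samples_per_donor: Sequence[int] = (7, 8, 9),
) -> list[SampleSpec]:
    """Draw a seeded population of virtual samples.

    Defaults reproduce the study's sample structure: 3 donors
    contributing 7, 8 and 9 strips (24 samples).  Each sample carries a
    log-normally perturbed copy of the true Prony series (re-projected
    onto sum gamma <= 1) and a geometry drawn around the donor's mean
    thickness and 5 mm width.  With all noise off every sample carries
    exactly the true parameters and the default geometry.
    """
    if noise is None:
        noise = NoiseModel()
    if n_donors < 1 or len(samples_per_donor) != n_donors:
        raise ValueError("samples_per_donor must list one count per donor")
    if any(c < 1 for c in samples_per_donor):
        raise ValueError("each donor must contribute at least one sample")
    rng = np.random.default_rng(seed)
    population = []
    for d in range(n_donors):
        donor_id = f"D{d + 1}"
        thick0 = _DONOR_THICKNESS_MM[d % len(_DONOR_THICKNESS_MM)]
        for s in range(samples_per_donor[d]):
            if noise.geometry_cv > 0:
                width = 5.0 * float(np.exp(rng.normal(0.0, noise.geometry_cv)))
                thick = thick0 * float(np.exp(rng.normal(0.0, noise.geometry_cv)))
            else:
                width, thick = 5.0, thick0
            geom = SampleGeometry(width_mm=width, thickness_mm=thick)
            ps = _perturb_gammas(true_ps, noise.sample_scatter,
                                 noise.tau_scatter, rng)
            population.append(SampleSpec(
                sample_id=f"{donor_id}S{s + 1}",
                donor_id=donor_id,
                geometry=geom,
                hp=true_hp,
                ps=ps,
            ))
    return population


def _quantize(values: np.ndarray, resolution: float) -> np.ndarray:
    if resolution <= 0:
        return values
    return np.round(values / resolution) * resolution


def _simulate_trace(
    spec: SampleSpec,
    strain_level: float,
    protocol: Protocol,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> StressTrace:
    # displacement quantization acts on the commanded elongation
    applied = strain_level
    if noise.displacement_resolution_mm > 0:
        elong = strain_level * spec.geometry.gauge_length_mm
        applied = _quantize(np.array([elong]), noise.displacement_resolution_mm)[0] \
            / spec.geometry.gauge_length_mm
    hold_times = protocol.hold_times()
    if protocol.ideal_step:
        trace = step_relaxation(spec.hp, spec.ps, applied, hold_times,
                                measure="nominal")
        times, stress = trace.times, trace.stress
    else:
        ramp_t = applied / protocol.ramp_rate
        ramp_grid = np.linspace(0.0, ramp_t, 201)
        grid = np.concatenate([ramp_grid, ramp_t + hold_times])
        full = integrate_history(
            spec.hp, spec.ps,
            lambda t: np.minimum(t * protocol.ramp_rate, applied),
            t_end=grid[-1], times=grid, measure="nominal",
        )
        # record the hold only; clock restarts at the end of the ramp
        times = full.times[len(ramp_grid):] - ramp_t
        stress = full.stress[len(ramp_grid):]
    # nominal stress -> force, quantize, add multiplicative noise, back
    area = spec.geometry.area_mm2  # MPa * mm^2 = N
    force = stress * area
    force = _quantize(force, noise.force_resolution_N)
    if noise.stress_cv > 0:
        force = force * (1.0 + rng.normal(0.0, noise.stress_cv, force.shape))
    return StressTrace(
        times=times,
        stress=force / area,
        strain=np.full_like(times, applied),
        measure="nominal",
        sample_id=spec.sample_id,
        donor_id=spec.donor_id,
        strain_level=strain_level,
    )


def simulate_experiment(
    population: Sequence[SampleSpec],
    protocol: Protocol | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> RelaxationDataset:
    """Run the full virtual protocol on a population.

    For every sample and strain level: ramp at the protocol rate (or
    ideal step), hold, sample the hold on the log grid with t = 0 at
    the end of the ramp, convert to force through the strip geometry,
    quantize at the machine resolutions and apply multiplicative
    stress noise.  The viscous state is reset between consecutive
    tests (full recovery during the rest period).
    """
    if protocol is None:
        protocol = Protocol()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    traces = []
    for spec in population:
        for level in protocol.strain_levels:
            traces.append(_simulate_trace(spec, level, protocol, noise, rng))
    return RelaxationDataset(
        traces=traces,
        population=list(population),
        protocol=protocol,
        seed=seed,
    )
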