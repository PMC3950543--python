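"""Prony-series fitting of normalized relaxation traces.

Experimental traces are normalized to the stress at the first hold
instant, pooled into a mean relaxation ratio R_exp(t), and compared to
the model's reduced relaxation R(eta, t) through the error functional

    chi = sqrt( (1/N) * sum_i [1 - R_exp(t_i) / R(eta, t_i)]^2 ),

a root-mean of squared *relative* residuals evaluated at N log-spaced
instants t_i.  The parameter vector eta = (gamma_1..gamma_m,
tau_1..tau_m) is found by a stochastic-deterministic procedure: a
seeded simulated-annealing global search (log-uniform tau proposals,
gamma proposals projected onto the simplex {gamma_i >= 0,
sum gamma_i <= 1}) followed by derivative-free Nelder-Mead refinement
from the global best.  Branch-count selection fits m = 1..4 with
warm starts (the m+1 search seeded from the m optimum plus one tiny
extra branch, which makes chi non-increasing in m) and recommends the
smallest m beyond which the improvement is marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .viscoelastic import PronySeries, StressTrace, reduced_relaxation

__all__ = [
    "FitConfig",
    "FitResult",
    "normalize_trace",
    "pooled_relaxation",
    "chi_error",
    "fit_prony",
    "select_model",
]


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the Prony-series fit.

    eval_times: the N instants at which chi is evaluated; default 40
    log-spaced instants in [0.05, 240] s, covering each relaxation
    decade uniformly.  tau is searched in [tau_min, tau_max] seconds on
    a log scale; gamma on the simplex.  The stochastic stage runs
    ``sa_iterations`` proposals with geometric cooling
    (``sa_cooling`` per iteration); the deterministic stage is
    Nelder-Mead with tolerance ``local_tol``.
    """

    m: int = 3
    eval_times: tuple[float, ...] = tuple(np.geomspace(0.05, 240.0, 40))
    tau_min: float = 1e-2
    tau_max: float = 1e3
    sa_iterations: int = 1500
    sa_initial_temp: float = 0.1
    sa_cooling: float = 0.997
    local_tol: float = 1e-12
    local_maxiter: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.m > 4:
            raise ValueError(f"branch count m must be in 0..4, got {self.m}")
        if not (0 < self.tau_min < self.tau_max):
            raise ValueError("require 0 < tau_min < tau_max")
        if len(self.eval_times) < 2 * self.m:
            raise ValueError(
                f"need at least 2m = {2 * self.m} evaluation instants for "
                f"identifiability, got {len(self.eval_times)}"
            )


@dataclass(frozen=True)
class FitResult:
    """Optimal Prony series with its chi error and fit provenance."""

    prony: PronySeries
    chi: float
    m: int
    seed: int
    n_restarts_used: int
    converged: bool
    config: FitConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "prony": self.prony.to_dict(),
            "chi": self.chi,
            "m": self.m,
            "seed": self.seed,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
        }
        if self.config is not None:
            d["config"] = {
                "m": self.config.m,
                "eval_times_s": list(self.config.eval_times),
                "tau_bounds_s": [self.config.tau_min, self.config.tau_max],
                "sa_iterations": self.config.sa_iterations,
                "sa_initial_temp": self.config.sa_initial_temp,
                "sa_cooling": self.config.sa_cooling,
                "local_tol": self.config.local_tol,
                "seed": self.config.seed,
            }
        return d


def normalize_trace(trace: StressTrace) -> StressTrace:
    """Normalize a relaxation hold to its first sample: R_exp(t) = S(t)/S(0).

    The first stress sample must be positive.  Output is tagged with
    the 'normalized' measure; normalization is scale invariant.
    """
    s0 = trace.stress[0]
    if not s0 > 0:
        raise ValueError(f"non-positive initial stress {s0}; cannot normalize")
    return StressTrace(
        times=trace.times,
        stress=trace.stress / s0,
        strain=trace.strain,
        measure="normalized",
        sample_id=trace.sample_id,
        donor_id=trace.donor_id,
        strain_level=trace.strain_level,
    )


def pooled_relaxation(traces: Sequence[StressTrace], eval_times) -> np.ndarray:
    """Mean normalized relaxation ratio over traces at the given instants.

    Traces not already normalized are normalized first; each is linearly
    interpolated onto ``eval_times`` and the pointwise mean is returned.
    """
    if not traces:
        raise ValueError("no traces to pool")
    eval_times = np.asarray(eval_times, dtype=float)
    rows = []
    for tr in traces:
        ntr = tr if tr.measure == "normalized" else normalize_trace(tr)
        rows.append(ntr.stress_at(eval_times))
    return np.mean(rows, axis=0)


def chi_error(
    ps: PronySeries,
    traces: Sequence[StressTrace],
    eval_times=None,
    t_ref: float | None = None,
) -> float:
    """Root-mean squared relative residual between pooled data and model.

    chi = sqrt((1/N) sum_i [1 - R_exp(t_i)/R(t_i)]^2); zero iff the
    pooled data equal the model ratio at every evaluation instant.

    Experimental traces are normalized to their first recorded hold
    sample, which lies slightly after the true start of the hold; for a
    consistent comparison the model ratio is referenced to the same
    instant, R(t)/R(t_ref), with ``t_ref`` defaulting to the earliest
    first-sample time of the traces (zero for a trace that starts at
    t = 0, where the reference drops out).
    """
    if eval_times is None:
        eval_times = FitConfig().eval_times
    eval_times = np.asarray(eval_times, dtype=float)
    if t_ref is None:
        t_ref = min(float(tr.times[0]) for tr in traces)
    r_exp = pooled_relaxation(traces, eval_times)
    r_mod = np.asarray(reduced_relaxation(ps, eval_times), dtype=float)
    r_mod = r_mod / reduced_relaxation(ps, t_ref)
    if np.any(r_mod <= 0):
        raise ValueError("model relaxation ratio non-positive at an evaluation instant")
    resid = 1.0 - r_exp / r_mod
    return float(np.sqrt(np.mean(resid * resid)))


# ---------------------------------------------------------------------------
# optimizer internals


def _project_gamma(g: np.ndarray) -> np.ndarray:
    """Project onto {gamma_i >= 1e-6, sum gamma_i <= 1}."""
    g = np.clip(g, 1e-6, 1.0)
    total = g.sum()
    if total > 1.0:
        g = g * (1.0 - 1e-9) / total
    return g


def _chi_of(g: np.ndarray, log_tau: np.ndarray, r_exp: np.ndarray,
            eval_times: np.ndarray, t_ref: float = 0.0) -> float:
    taus = np.exp(log_tau)
    r_mod = np.ones_like(eval_times)
    r_at_ref = 1.0
    for gi, ti in zip(g, taus):
        r_mod = r_mod - gi * (-np.expm1(-eval_times / ti))
        r_at_ref -= gi * (-math.expm1(-t_ref / ti))
    if np.any(r_mod <= 1e-9) or r_at_ref <= 1e-9:
        return np.inf
    resid = 1.0 - r_exp * (r_at_ref / r_mod)
    return float(np.sqrt(np.mean(resid * resid)))


def _anneal(r_exp, eval_times, cfg: FitConfig, rng: np.random.Generator,
            start: tuple[np.ndarray, np.ndarray] | None, t_ref: float = 0.0):
    m = cfg.m
    lo, hi = math.log(cfg.tau_min), math.log(cfg.tau_max)
    if start is not None:
        g, lt = start
    else:
        g = _project_gamma(rng.uniform(0.0, 0.5, m))
        lt = np.sort(rng.uniform(lo, hi, m))
    cur = _chi_of(g, lt, r_exp, eval_times, t_ref)
    best_g, best_lt, best = g.copy(), lt.copy(), cur
    temp = cfg.sa_initial_temp
    for _ in range(cfg.sa_iterations):
        g_new = _project_gamma(g + rng.normal(0.0, 0.05, m))
        lt_new = np.clip(lt + rng.normal(0.0, 0.25, m), lo, hi)
        # occasional global tau jump to escape local basins
        if rng.random() < 0.05:
            j = rng.integers(m)
            lt_new[j] = rng.uniform(lo, hi)
        new = _chi_of(g_new, lt_new, r_exp, eval_times, t_ref)
        if new < cur or rng.random() < math.exp(min((cur - new) / max(temp, 1e-12), 0.0)):
            g, lt, cur = g_new, lt_new, new
            if cur < best:
                best_g, best_lt, best = g.copy(), lt.copy(), cur
        temp *= cfg.sa_cooling
    return best_g, best_lt, best


def _local_refine(g0, lt0, r_exp, eval_times, cfg: FitConfig, t_ref: float = 0.0):
    m = cfg.m
    lo, hi = math.log(cfg.tau_min), math.log(cfg.tau_max)

    def objective(x):
        g, lt = x[:m], x[m:]
        if np.any(g < 0) or g.sum() > 1.0 or np.any(lt < lo) or np.any(lt > hi):
            return 1e3 + float(np.sum(np.maximum(-g, 0)) + max(g.sum() - 1, 0))
        return _chi_of(g, lt, r_exp, eval_times, t_ref)

    x0 = np.concatenate([g0, lt0])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": cfg.local_tol,
            "fatol": cfg.local_tol,
            "maxiter": cfg.local_maxiter,
            "maxfev": cfg.local_maxiter,
        },
    )
    g = _project_gamma(res.x[:m])
    lt = np.clip(res.x[m:], lo, hi)
    return g, lt, _chi_of(g, lt, r_exp, eval_times, t_ref), bool(res.success)


def fit_prony(
    traces: Sequence[StressTrace] | StressTrace,
    cfg: FitConfig,
    warm_start: PronySeries | None = None,
    n_restarts: int = 3,
) -> FitResult:
    """Fit an m-branch Prony series to normalized relaxation traces.

    Runs ``n_restarts`` independent simulated-annealing searches (one
    seeded from ``warm_start`` when given), refines the global best by
    Nelder-Mead, and returns the constraint-satisfying optimum with
    branches sorted by ascending tau.  Deterministic given cfg.seed.
    """
    if isinstance(traces, StressTrace):
        traces = [traces]
    if not traces:
        raise ValueError("no traces to fit")
    eval_times = np.asarray(cfg.eval_times, dtype=float)
    r_exp = pooled_relaxation(traces, eval_times)
    t_ref = min(float(tr.times[0]) for tr in traces)

    if cfg.m == 0:
        chi = _chi_of(np.empty(0), np.empty(0), r_exp, eval_times, t_ref)
        return FitResult(PronySeries(), chi, 0, cfg.seed, 0, True, cfg)

    rng = np.random.default_rng(cfg.seed)
    lo, hi = math.log(cfg.tau_min), math.log(cfg.tau_max)
    starts: list[tuple[np.ndarray, np.ndarray] | None] = [None] * n_restarts
    if warm_start is not None:
        g0 = np.clip(warm_start.gammas, 1e-6, 1.0)[: cfg.m]
        lt0 = np.clip(np.log(warm_start.taus), lo, hi)[: cfg.m]
        while len(g0) < cfg.m:
            g0 = np.append(g0, 1e-4)
            lt0 = np.append(lt0, rng.uniform(lo, hi))
        starts[0] = (_project_gamma(g0), lt0)

    candidates = []
    for start in starts:
        g, lt, chi_sa = _anneal(r_exp, eval_times, cfg, rng, start, t_ref)
        candidates.append((chi_sa, g, lt))
    # refine each candidate; keep the best refined solution
    best = None
    for chi_sa, g, lt in candidates:
        g2, lt2, chi2, ok = _local_refine(g, lt, r_exp, eval_times, cfg, t_ref)
        if best is None or chi2 < best[0]:
            best = (chi2, g2, lt2, ok)
    chi_opt, g_opt, lt_opt, converged = best
    # warm start must never be degraded: evaluate it as a candidate too
    if warm_start is not None and warm_start.m == cfg.m:
        g_w = warm_start.gammas
        lt_w = np.log(warm_start.taus)
        chi_w = _chi_of(g_w, np.clip(lt_w, lo, hi), r_exp, eval_times, t_ref)
        if chi_w < chi_opt:
            chi_opt, g_opt, lt_opt = chi_w, g_w, np.clip(lt_w, lo, hi)
    order = np.argsort(lt_opt)
    ps = PronySeries(zip(g_opt[order], np.exp(lt_opt[order])))
    return FitResult(ps, chi_opt, cfg.m, cfg.seed, n_restarts, converged, cfg)


def select_model(
    traces: Sequence[StressTrace],
    cfg: FitConfig | None = None,
    m_range: Iterable[int] = (1, 2, 3, 4),
    improvement_threshold: float = 0.05,
    chi_floor: float = 1e-4,
) -> tuple[dict[int, FitResult], int]:
    """Fit every branch count in ``m_range`` and recommend one.

    Each fit warm-starts from the previous optimum plus a tiny extra
    branch, so chi is non-increasing in m.  The recommended m is the
    smallest whose fit is either essentially exact (chi below
    ``chi_floor``) or whose successor improves chi by less than
    ``improvement_threshold`` (relative); otherwise the largest m.
    """
    if cfg is None:
        cfg = FitConfig()
    m_list = sorted(m_range)
    if not m_list:
        raise ValueError("m_range is empty")
    results: dict[int, FitResult] = {}
    prev: FitResult | None = None
    for m in m_list:
        c = replace(cfg, m=m)
        warm = prev.prony if prev is not None else None
        res = fit_prony(traces, c, warm_start=warm)
        if prev is not None and res.chi > prev.chi + 1e-15:
            # warm-started search should not regress; keep best-of-both by
            # padding the previous optimum with a negligible branch
            g = np.append(prev.prony.gammas, 1e-12)[:m]
            t = np.append(prev.prony.taus, cfg.tau_min)[:m]
            ps = PronySeries(zip(g, t))
            chi = chi_error(ps, traces, c.eval_times)
            if chi < res.chi:
                res = FitResult(ps, chi, m, c.seed, res.n_restarts_used, True, c)
        results[m] = res
        prev = res
    recommended = m_list[-1]
    for i, m in enumerate(m_list):
        if results[m].chi <= chi_floor:
            recommended = m
            break
        if i + 1 < len(m_list):
            nxt = m_list[i + 1]
            rel_gain = (results[m].chi - results[nxt].chi) / max(results[m].chi, 1e-300)
            if rel_gain < improvement_threshold:
                recommended = m
                break
    return results, recommended
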