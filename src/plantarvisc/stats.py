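"""Summary tables and strain-level invariance testing for relaxation data.

Under quasi-linear viscoelasticity the normalized relaxation
S(t)/S(0) does not depend on the strain level.  This module computes,
per strain level, the mean and sample SD of the normalized stress at
the reporting instants (0.1, 6, 72 and 240 s by default) and tests the
invariance with a classical one-way ANOVA across strain levels at each
instant, computed from between/within sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .fitting import normalize_trace
from .viscoelastic import REPORTING_INSTANTS, StressTrace

__all__ = ["SummaryTable", "AnovaResult", "summarize", "anova_by_strain"]


@dataclass(frozen=True)
class SummaryTable:
    """Mean and sample SD of normalized stress by strain level and instant."""

    mean: pd.DataFrame  # rows: strain level, columns: instant (s)
    sd: pd.DataFrame
    n: pd.DataFrame

    def formatted(self, decimals: int = 2) -> pd.DataFrame:
        """Cells rendered as 'mean (SD)', one row per strain level."""
        out = self.mean.round(decimals).astype(str)
        sd = self.sd.round(decimals).astype(str)
        for c in out.columns:
            out[c] = out[c] + " (" + sd[c] + ")"
        return out

    def to_csv(self, path) -> None:
        df = self.formatted()
        df.index = [f"{100 * s:g}%" for s in df.index]
        df.index.name = "strain"
        df.columns = [f"t={c:g}s" for c in df.columns]
        df.to_csv(path)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA of normalized stress across strain levels."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    significant: bool

    @property
    def alpha(self) -> float:
        return 0.05


def _normalized_value_at(trace: StressTrace, instant: float) -> float:
    ntr = trace if trace.measure == "normalized" else normalize_trace(trace)
    return float(ntr.stress_at(instant))


def _groups_by_strain(
    traces: Sequence[StressTrace], instant: float, donors: Sequence[str] | None
) -> dict[float, list[float]]:
    groups: dict[float, list[float]] = {}
    for tr in traces:
        if donors is not None and tr.donor_id not in donors:
            continue
        level = tr.strain_level if tr.strain_level is not None else float(tr.strain[0])
        groups.setdefault(round(float(level), 10), []).append(
            _normalized_value_at(tr, instant)
        )
    return groups


def summarize(
    traces: Sequence[StressTrace],
    instants: Sequence[float] = REPORTING_INSTANTS,
    donors: Sequence[str] | None = None,
) -> SummaryTable:
    """Mean and sample SD (n-1 denominator) of normalized stress.

    Traces are grouped by strain level; values at each instant are
    obtained by linear interpolation on the trace's sampling grid.
    Raises if any instant lies outside a trace's support.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty dataset")
    levels = sorted({round(float(tr.strain_level if tr.strain_level is not None
                                  else tr.strain[0]), 10) for tr in traces})
    mean = pd.DataFrame(index=levels, columns=list(instants), dtype=float)
    sd = pd.DataFrame(index=levels, columns=list(instants), dtype=float)
    n = pd.DataFrame(index=levels, columns=list(instants), dtype=float)
    for instant in instants:
        groups = _groups_by_strain(traces, instant, donors)
        for level in levels:
            vals = np.asarray(groups.get(level, []))
            if vals.size == 0:
                raise ValueError(f"no traces at strain level {level}")
            mean.loc[level, instant] = vals.mean()
            sd.loc[level, instant] = vals.std(ddof=1) if vals.size > 1 else 0.0
            n.loc[level, instant] = vals.size
    return SummaryTable(mean=mean, sd=sd, n=n)


def anova_by_strain(
    traces: Sequence[StressTrace],
    instant: float,
    donors: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA of normalized stress across strain levels at ``instant``.

    The F statistic is computed from the between-group and within-group
    sums of squares:

        F = [SS_between / (k - 1)] / [SS_within / (n - k)]

    with p-value from the F(k-1, n-k) distribution.  Requires at least
    two groups with at least two observations each.
    """
    groups = list(_groups_by_strain(traces, instant, donors).values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 strain groups with >= 2 observations each")
    all_vals = np.concatenate([np.asarray(g) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else np.inf
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        significant=bool(p < alpha),
    )
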