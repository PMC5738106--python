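"""Digestion metrics: conversion degree, released D-glucose and %SH.

Three per-timepoint readouts summarize a digestion time series:

* degree of starch conversion, ``100 * (S_i - S(t)) / S_i`` — the fraction of
  the initial starch no longer measurable as starch;
* released D-glucose, ``G(t) - G(0)`` — baseline-subtracted free glucose;
* percentage of starch hydrolysis, ``%SH = 100 * 0.9 * G_R / S_i`` — the
  glucose-side estimate of hydrolyzed starch, using the 0.9 anhydroglucose
  stoichiometric constant.  %SH may exceed 100% when part of the released
  glucose derives from non-starch saccharides (fermented foods).

The initial-starch convention differs by food category: for plain starch
foods S_i is measured before the sterilization treatment (supply it
explicitly or via run metadata); for cream-based foods S_i is the starch
measured after dissolving the food, i.e. the t=0 baseline record.

Group comparisons use a two-sided Student t-test on replicate values, the
procedure used for the triplicate digestions this package emulates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, MidaError
from .simulator import SimTimeSeries

__all__ = [
    "STARCH_GLUCOSE_STOICHIOMETRY",
    "conversion_degree",
    "glucose_released",
    "starch_hydrolysis_pct",
    "metrics_table",
    "MetricsResult",
    "GroupComparison",
    "compare_groups",
]

#: Mass of anhydroglucose (starch) per mass of free D-glucose.
STARCH_GLUCOSE_STOICHIOMETRY = 0.9

_SI_SOURCES = ("pre_treatment", "at_dissolution", "explicit")


def conversion_degree(S_initial_g: float, S_t_g: float) -> float:
    """Degree of starch conversion, percent: ``100 * (S_i - S_t) / S_i``.

    A measured ``S_t`` above ``S_initial`` (assay noise) yields a negative
    conversion, returned with a warning rather than clipped.
    """
    if S_initial_g <= 0:
        raise DomainError("S_initial_g must be > 0")
    if S_t_g < 0:
        raise DomainError("S_t_g must be >= 0")
    if S_t_g > S_initial_g:
        warnings.warn(
            f"starch at t ({S_t_g} g) exceeds initial starch ({S_initial_g} g); "
            "returning negative conversion", stacklevel=2)
    return 100.0 * (S_initial_g - S_t_g) / S_initial_g


def glucose_released(G_t_g: float, G_0_g: float) -> float:
    """Baseline-subtracted released D-glucose, grams: ``G(t) - G(0)``.

    May be negative under measurement noise; preserved, not clipped.
    """
    if G_t_g < 0 or G_0_g < 0:
        raise DomainError("glucose masses must be >= 0")
    released = G_t_g - G_0_g
    if released < 0:
        warnings.warn(
            f"glucose at t ({G_t_g} g) is below baseline ({G_0_g} g); "
            "returning negative release", stacklevel=2)
    return released


def starch_hydrolysis_pct(G_released_g: float, S_initial_g: float) -> float:
    """Percentage of starch hydrolysis: ``100 * 0.9 * G_R / S_i``.

    Explicitly allowed to exceed 100% (glucose from non-starch saccharides).
    """
    if S_initial_g <= 0:
        raise DomainError("S_initial_g must be > 0")
    if G_released_g < 0:
        warnings.warn("negative released glucose; returning negative %SH", stacklevel=2)
    return 100.0 * STARCH_GLUCOSE_STOICHIOMETRY * G_released_g / S_initial_g


@dataclass
class MetricsResult:
    """Per-sample metrics plus replicate means/SDs per timepoint."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    s_i: dict[int, float]  # initial starch used, per replicate
    si_source: str


def _phase_of(purpose: str) -> str:
    return "intestinal" if purpose == "drain" else purpose


def metrics_table(
    ts: SimTimeSeries | pd.DataFrame,
    si_source: str = "at_dissolution",
    s_i: float | None = None,
) -> MetricsResult:
    """Apply the three digestion metrics at every timepoint of a time series.

    ``si_source`` selects the initial-starch convention: ``"at_dissolution"``
    uses each replicate's t=0 baseline starch record, ``"pre_treatment"`` or
    ``"explicit"`` use the supplied ``s_i`` for every replicate.  The glucose
    baseline G(0) is always taken from the t=0 record.
    """
    if si_source not in _SI_SOURCES:
        raise DomainError(f"si_source must be one of {_SI_SOURCES}")
    if si_source in ("pre_treatment", "explicit") and s_i is None:
        raise DomainError(f"si_source={si_source!r} requires an explicit s_i value")
    df = (ts.samples if isinstance(ts, SimTimeSeries) else ts).copy()

    baselines = df[df["purpose"] == "baseline"]
    if baselines.empty:
        raise MidaError("no t=0 record: the time series has no baseline sample")

    rows = []
    s_i_used: dict[int, float] = {}
    for rep, group in df.groupby("replicate"):
        base = group[group["purpose"] == "baseline"]
        if base.empty:
            raise MidaError(f"no t=0 record for replicate {rep}")
        g0 = float(base["glucose_g"].iloc[0])
        si_rep = float(base["starch_g"].iloc[0]) if si_source == "at_dissolution" else float(s_i)
        if si_rep <= 0:
            raise DomainError(f"initial starch for replicate {rep} must be > 0")
        s_i_used[int(rep)] = si_rep
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noise-driven negatives are expected here
            for rec in group.itertuples():
                g_r = glucose_released(rec.glucose_g, g0)
                rows.append({
                    "time_min": rec.time_min,
                    "phase": _phase_of(rec.purpose),
                    "replicate": int(rep),
                    "starch_g": rec.starch_g,
                    "glucose_g": rec.glucose_g,
                    "conversion_pct": conversion_degree(si_rep, rec.starch_g),
                    "glucose_released_g": g_r,
                    "sh_pct": starch_hydrolysis_pct(g_r, si_rep),
                })
    per_sample = (pd.DataFrame(rows)
                  .sort_values(["time_min", "replicate"])
                  .reset_index(drop=True))
    summary = (per_sample
               .groupby(["time_min", "phase"], as_index=False)
               .agg(**{
                   f"{col}_{stat}": (col, stat)
                   for col in ("starch_g", "glucose_g", "conversion_pct",
                               "glucose_released_g", "sh_pct")
                   for stat in ("mean", "std")
               }))
    return MetricsResult(per_sample=per_sample, summary=summary,
                         s_i=s_i_used, si_source=si_source)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Student t-test at one timepoint."""

    time_min: float
    column: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    zero_variance: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01


def compare_groups(
    ts_a: SimTimeSeries | pd.DataFrame,
    ts_b: SimTimeSeries | pd.DataFrame,
    timepoint: float,
    column: str = "starch_g",
    equal_var: bool = True,
) -> GroupComparison:
    """Student t-test on replicate values of ``column`` at one timepoint.

    Equal-variance (classical Student) by default; pass ``equal_var=False``
    for Welch.  Degenerate zero-variance groups are flagged: identical groups
    give t=0, p=1; separated zero-variance groups report p at the machine-eps
    floor.
    """
    def _values(ts) -> np.ndarray:
        df = ts.samples if isinstance(ts, SimTimeSeries) else ts
        sel = df[np.isclose(df["time_min"], timepoint)]
        return sel.groupby("replicate")[column].mean().to_numpy(float)

    a, b = _values(ts_a), _values(ts_b)
    if len(a) < 2 or len(b) < 2:
        raise MidaError(
            f"need >= 2 replicates per group at t={timepoint} (got {len(a)} and {len(b)})"
        )
    zero_var = float(np.var(a)) == 0.0 and float(np.var(b)) == 0.0
    if zero_var:
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, a.mean() - b.mean())
            p = float(np.finfo(float).eps)  # below any attainable level
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        time_min=float(timepoint), column=column,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
        t_statistic=float(t_stat), p_value=float(p), zero_variance=zero_var,
    )
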