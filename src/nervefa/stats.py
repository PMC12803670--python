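"""Longitudinal association between SFI and Gompertz-derived FA parameters.

Two complementary analyses, run on the animal x MRI-timepoint join of the
behavioral (SFI) and imaging (Gompertz parameter) tables:

* pooled Pearson correlations of SFI with each of the five derived
  parameters (FA0, FA_ip, dFA, FA_target, x_ip), with Bonferroni
  correction over the family of five tests;
* a repeated-measures ANOVA per parameter: SFI regressed on the
  parameter with one intercept per animal (the animal as error term),
  so the covariate F-test has df = (1, n_obs - n_animals - 1).

Joining is exact by week: each MRI session is paired with the SFI
measured the same week (week 0 pairs the pre-surgery baselines); the
3-day post-surgery SFI never joins an MRI session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "GOMPERTZ_PARAMETERS",
    "CorrelationResult",
    "AnovaResult",
    "join_timepoints",
    "pearson_bonferroni",
    "rm_anova",
]

GOMPERTZ_PARAMETERS = ("fa0", "fa_ip", "dfa", "fa_target", "x_ip")


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    r: float
    p: float
    p_adjusted: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    F: float
    df1: int
    df2: int
    p: float


def join_timepoints(sfi_table: pd.DataFrame, gompertz_table: pd.DataFrame,
                    include_baseline: bool = True) -> pd.DataFrame:
    """Inner-join SFI onto MRI sessions by (animal_id, week).

    ``sfi_table`` carries timepoint_days (weekly sampling; converted to
    weeks as days/7); ``gompertz_table`` carries timepoint_weeks.  Only
    exact-week matches join; unmatched rows and animals present in one
    table only are logged and dropped.  ``include_baseline=False`` drops
    week 0 (pre-surgery) rows.
    """
    sfi = sfi_table.copy()
    if "timepoint_weeks" not in sfi.columns:
        sfi["timepoint_weeks"] = sfi["timepoint_days"] / 7.0
    # exact-week matching: keep only integral weeks (the day-3 measurement
    # maps to week 3/7 and can never match an MRI week)
    integral = np.isclose(sfi["timepoint_weeks"] % 1.0, 0.0)
    sfi = sfi[integral].copy()
    sfi["timepoint_weeks"] = sfi["timepoint_weeks"].round().astype(int)

    gom = gompertz_table.copy()
    gom["timepoint_weeks"] = gom["timepoint_weeks"].round().astype(int)

    only_sfi = set(sfi.animal_id) - set(gom.animal_id)
    only_gom = set(gom.animal_id) - set(sfi.animal_id)
    for a in sorted(only_sfi | only_gom):
        log.warning("animal %s present in one table only; excluded", a)
    if not (set(sfi.animal_id) & set(gom.animal_id)):
        log.warning("no animals in common between SFI and Gompertz tables")
        return gom.iloc[0:0].merge(sfi.iloc[0:0], on=["animal_id", "timepoint_weeks"])

    joined = gom.merge(sfi[["animal_id", "timepoint_weeks", "sfi"] +
                           (["sfi_se"] if "sfi_se" in sfi.columns else [])],
                       on=["animal_id", "timepoint_weeks"], how="inner")
    n_dropped = len(gom) - len(joined)
    if n_dropped:
        log.info("%d MRI sessions had no same-week SFI and were dropped", n_dropped)
    if joined.duplicated(["animal_id", "timepoint_weeks"]).any():
        raise ValueError("duplicated (animal, timepoint) keys after join")
    # rows missing any derived parameter are dropped with a logged reason
    present = [p for p in GOMPERTZ_PARAMETERS if p in joined.columns]
    bad = joined[present].isna().any(axis=1)
    if bad.any():
        log.info("dropping %d rows with missing Gompertz parameters", int(bad.sum()))
        joined = joined[~bad]
    if not include_baseline:
        joined = joined[joined["timepoint_weeks"] > 0]
    return joined.reset_index(drop=True)


def pearson_bonferroni(table: pd.DataFrame, parameters=GOMPERTZ_PARAMETERS,
                       family_size: int | None = None,
                       outcome: str = "sfi") -> list[CorrelationResult]:
    """Pooled Pearson correlation of the outcome with each parameter.

    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 df (two-sided); the Bonferroni-adjusted p is min(1, m p) with m
    the family size (default: the number of parameters tested).  Zero
    variance in either variable yields r = NaN (undefined, not 0).
    """
    m = family_size if family_size is not None else len(parameters)
    results = []
    for param in parameters:
        sub = table[[outcome, param]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"need >= 3 complete pairs for {param}; got {n}")
        x = sub[param].to_numpy(float)
        y = sub[outcome].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(CorrelationResult(param, float("nan"), float("nan"),
                                             float("nan"), n))
            continue
        r, p = sps.pearsonr(x, y)
        results.append(CorrelationResult(param, float(r), float(p),
                                         float(min(1.0, m * p)), n))
    return results


def rm_anova(table: pd.DataFrame, parameter: str, outcome: str = "sfi") -> AnovaResult:
    """Repeated-measures ANOVA: outcome ~ parameter + animal blocks.

    Equivalent to R's ``aov(sfi ~ param + Error(animal))`` within-subject
    stratum for a continuous covariate: per-animal intercepts absorb
    between-animal variation and the covariate is tested with
    F = SS_covariate / (SS_residual / df2), df2 = n_obs - n_animals - 1.
    """
    sub = table[["animal_id", outcome, parameter]].dropna()
    animals = sub["animal_id"].unique()
    n_animals = animals.size
    n_obs = len(sub)
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    if (sub.groupby("animal_id").size() < 2).any():
        raise ValueError("every animal needs at least 2 timepoints")

    y = sub[outcome].to_numpy(float)
    xcov = sub[parameter].to_numpy(float)
    # block design: one indicator column per animal (saturated intercepts)
    Z = (sub["animal_id"].to_numpy()[:, None] == animals[None, :]).astype(float)

    # within-animal centering projects out the block space
    def center(v):
        out = v.astype(float).copy()
        for j in range(n_animals):
            idx = Z[:, j] > 0
            out[idx] -= out[idx].mean()
        return out

    y_w = center(y)
    x_w = center(xcov)
    sxx = float(x_w @ x_w)
    if sxx <= 1e-12 * max(1.0, float(xcov @ xcov)):
        raise ValueError(f"covariate {parameter!r} is collinear with the animal blocks")

    beta = float(x_w @ y_w) / sxx
    ss_cov = beta * float(x_w @ y_w)
    ss_res = float(y_w @ y_w) - ss_cov
    df1 = 1
    df2 = n_obs - n_animals - 1
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    F = (ss_cov / df1) / (ss_res / df2)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(parameter, float(F), df1, df2, p)
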