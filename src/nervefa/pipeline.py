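"""End-to-end orchestration: profiles -> segmentation -> Gompertz fits ->
SFI -> longitudinal statistics.

These functions are the library-level backbone of the command-line
pipeline and of full-chain simulation studies: they consume in-memory
objects (NerveProfile dicts, footprint DataFrames) and return tidy cohort
tables.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from nervefa import behavior, gompertz, profile as prof, stats
from nervefa.profile import SegmentationParams

log = logging.getLogger(__name__)

__all__ = ["fit_cohort_profiles", "run_cohort", "CohortResults"]


def fit_cohort_profiles(profiles: dict,
                        seg_params: SegmentationParams = SegmentationParams(),
                        weights: str | None = None) -> pd.DataFrame:
    """Classify, extract the distal segment and fit the Gompertz model for
    every (animal, week) profile.

    ``profiles`` maps (animal_id, timepoint_weeks) -> NerveProfile.
    Returns one row per fit with the six derived quantities, their SEs and
    fit flags.  Degenerate (flat-profile) fits report the constant-model
    mean as fa0/fa_target/fa_ip.
    """
    rows = []
    for (animal_id, week), p in profiles.items():
        labeled = prof.classify_regions(p, seg_params)
        distal = prof.extract_distal(labeled)
        w = 1.0 / distal.fa_sd**2 if weights == "inverse_variance" else None
        fit = gompertz.fit_gompertz(distal, weights=w)
        rec = fit.to_record()
        row = {"animal_id": animal_id, "timepoint_weeks": week,
               "no_injury_detected": labeled.no_injury_detected}
        for k in gompertz.QUANTITY_NAMES:
            row[k] = rec[k]
        if fit.degenerate and fit.constant_mean is not None:
            # flat profile: the constant mean is the defensible level summary
            row["fa0"] = fit.constant_mean
            row["fa_target"] = fit.constant_mean
            row["fa_ip"] = fit.constant_mean
            row["dfa"] = 0.0
        for k, v in rec["se"].items():
            row[f"se_{k}"] = v
        row.update(residual_ss=rec["residual_ss"], converged=rec["converged"],
                   degenerate=rec["degenerate"], n_points=rec["n_points"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CohortResults:
    gompertz_table: pd.DataFrame
    sfi_table: pd.DataFrame
    longitudinal: pd.DataFrame
    correlations: list
    anova: list

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.correlations])

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(a) for a in self.anova])


def run_cohort(profiles: dict, footprints: pd.DataFrame,
               seg_params: SegmentationParams = SegmentationParams(),
               include_baseline: bool = True,
               family_size: int | None = None) -> CohortResults:
    """Run the full statistical chain on one cohort."""
    gom = fit_cohort_profiles(profiles, seg_params)
    sfi = behavior.sfi_table(footprints)
    longi = stats.join_timepoints(sfi, gom, include_baseline=include_baseline)
    corr = stats.pearson_bonferroni(longi, stats.GOMPERTZ_PARAMETERS,
                                    family_size=family_size)
    anova = [stats.rm_anova(longi, p) for p in stats.GOMPERTZ_PARAMETERS]
    return CohortResults(gom, sfi, longi, corr, anova)
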