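"""Longitudinal joining, pooled correlations and repeated-measures ANOVA."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nervefa.stats import (
    GOMPERTZ_PARAMETERS,
    join_timepoints,
    pearson_bonferroni,
    rm_anova,
)


def sfi_frame(animals, days):
    rows = [{"animal_id": a, "timepoint_days": d, "sfi": -50.0 + i + d / 7}
            for i, a in enumerate(animals) for d in days]
    return pd.DataFrame(rows)


def gompertz_frame(animals, weeks, rng=None):
    rows = []
    for a in animals:
        for w in weeks:
            row = {"animal_id": a, "timepoint_weeks": w}
            for p in GOMPERTZ_PARAMETERS:
                row[p] = 0.5 if rng is None else rng.uniform(0.3, 0.7)
            rows.append(row)
    return pd.DataFrame(rows)


class TestJoin:
    MRI_WEEKS = (0, 2, 4, 6, 8, 10, 12)
    SFI_DAYS = (0, 3) + tuple(7 * w for w in range(1, 13))

    def test_weekly_sfi_biweekly_mri_gives_seven_rows_per_animal(self):
        animals = ["a1", "a2"]
        joined = join_timepoints(sfi_frame(animals, self.SFI_DAYS),
                                 gompertz_frame(animals, self.MRI_WEEKS))
        assert len(joined) == 7 * len(animals)
        assert set(joined.timepoint_weeks) == set(self.MRI_WEEKS)

    def test_day3_never_joins(self):
        joined = join_timepoints(sfi_frame(["a"], (0, 3)),
                                 gompertz_frame(["a"], self.MRI_WEEKS))
        assert len(joined) == 1
        assert joined.timepoint_weeks.iloc[0] == 0

    def test_missing_week_dropped(self, caplog):
        days = tuple(d for d in self.SFI_DAYS if d != 42)  # no SFI at week 6
        with caplog.at_level(logging.INFO, logger="nervefa.stats"):
            joined = join_timepoints(sfi_frame(["a"], days),
                                     gompertz_frame(["a"], self.MRI_WEEKS))
        assert len(joined) == 6
        assert 6 not in set(joined.timepoint_weeks)

    def test_animal_in_one_table_only_warns_and_excludes(self, caplog):
        with caplog.at_level(logging.WARNING, logger="nervefa.stats"):
            joined = join_timepoints(sfi_frame(["a", "b"], self.SFI_DAYS),
                                     gompertz_frame(["a"], self.MRI_WEEKS))
        assert "b" in caplog.text
        assert set(joined.animal_id) == {"a"}

    def test_empty_intersection_warns_and_returns_empty(self, caplog):
        with caplog.at_level(logging.WARNING, logger="nervefa.stats"):
            joined = join_timepoints(sfi_frame(["a"], self.SFI_DAYS),
                                     gompertz_frame(["b"], self.MRI_WEEKS))
        assert joined.empty
        assert "no animals in common" in caplog.text

    def test_exclude_baseline_flag(self):
        joined = join_timepoints(sfi_frame(["a"], self.SFI_DAYS),
                                 gompertz_frame(["a"], self.MRI_WEEKS),
                                 include_baseline=False)
        assert 0 not in set(joined.timepoint_weeks)


class TestPearson:
    def test_hand_example(self):
        t = pd.DataFrame({"sfi": [6, 4, 5], "fa0": [1, 2, 3]})
        (res,) = pearson_bonferroni(t, ["fa0"], family_size=1)
        assert res.r == pytest.approx(-0.5, abs=1e-12)

    def test_perfect_linearity(self):
        t = pd.DataFrame({"sfi": [2.0, 4.0, 6.0], "fa0": [1.0, 2.0, 3.0]})
        (res,) = pearson_bonferroni(t, ["fa0"])
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-6

    def test_matches_bruteforce_formulas(self, rng):
        """r by the product-moment formula and p from the exact t transform."""
        for _ in range(5):
            x = rng.normal(0, 1, 50)
            y = 0.4 * x + rng.normal(0, 1, 50)
            t = pd.DataFrame({"sfi": y, "fa0": x})
            (res,) = pearson_bonferroni(t, ["fa0"], family_size=1)
            xm, ym = x - x.mean(), y - y.mean()
            r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
            tt = r * np.sqrt((50 - 2) / (1 - r**2))
            p = float(2 * sps.t.sf(abs(tt), 50 - 2))
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        t1 = pd.DataFrame({"sfi": y, "fa0": x})
        t2 = pd.DataFrame({"sfi": 3 * y - 7, "fa0": 0.1 * x + 2})
        r1 = pearson_bonferroni(t1, ["fa0"])[0].r
        r2 = pearson_bonferroni(t2, ["fa0"])[0].r
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_bonferroni_adjustment(self, rng):
        t = pd.DataFrame({
            "sfi": rng.normal(0, 1, 20),
            **{p: rng.normal(0, 1, 20) for p in GOMPERTZ_PARAMETERS},
        })
        results = pearson_bonferroni(t)
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, 5 * res.p), abs=1e-15)
            assert res.p <= res.p_adjusted <= 1.0

    def test_zero_variance_undefined_not_zero(self):
        t = pd.DataFrame({"sfi": [1.0, 2.0, 3.0], "fa0": [0.5, 0.5, 0.5]})
        (res,) = pearson_bonferroni(t, ["fa0"])
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_too_few_pairs_rejected(self):
        t = pd.DataFrame({"sfi": [1.0, 2.0], "fa0": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">= 3"):
            pearson_bonferroni(t, ["fa0"])


def anova_bruteforce(df, param):
    """Independent oracle: explicit least-squares projections.

    Residual SS of sfi ~ animal-blocks, minus residual SS of
    sfi ~ animal-blocks + covariate, gives the covariate SS.
    """
    animals = sorted(df.animal_id.unique())
    Z = np.column_stack([(df.animal_id == a).to_numpy(float) for a in animals])
    X = np.column_stack([Z, df[param].to_numpy(float)])
    y = df["sfi"].to_numpy(float)

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    ss_red, ss_full = rss(Z), rss(X)
    df2 = len(df) - len(animals) - 1
    F = (ss_red - ss_full) / (ss_full / df2)
    return F, df2


class TestRMAnova:
    def test_matches_projection_oracle(self, rng):
        df = pd.DataFrame({
            "animal_id": np.repeat(["a", "b", "c"], 4),
            "sfi": rng.normal(-50, 20, 12),
            "fa0": rng.uniform(0.3, 0.7, 12),
        })
        res = rm_anova(df, "fa0")
        F, df2 = anova_bruteforce(df, "fa0")
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df1, res.df2) == (1, df2)

    def test_df_structure_nine_animals_seven_sessions(self, rng):
        df = pd.DataFrame({
            "animal_id": np.repeat([f"r{i}" for i in range(9)], 7),
            "sfi": rng.normal(-50, 20, 63),
            "fa0": rng.uniform(0.3, 0.7, 63),
        })
        res = rm_anova(df, "fa0")
        assert (res.df1, res.df2) == (1, 53)

    def test_invariant_to_per_animal_shift(self, rng):
        df = pd.DataFrame({
            "animal_id": np.repeat(["a", "b", "c", "d"], 5),
            "sfi": rng.normal(-50, 10, 20),
            "fa0": rng.uniform(0.3, 0.7, 20),
        })
        res0 = rm_anova(df, "fa0")
        shifted = df.copy()
        offsets = {"a": 100.0, "b": -40.0, "c": 7.0, "d": 0.0}
        shifted["sfi"] += shifted.animal_id.map(offsets)
        res1 = rm_anova(shifted, "fa0")
        assert res1.F == pytest.approx(res0.F, rel=1e-10)

    def test_df_bookkeeping(self, rng):
        for n_an, n_tp in ((2, 3), (5, 4), (9, 7)):
            df = pd.DataFrame({
                "animal_id": np.repeat([f"x{i}" for i in range(n_an)], n_tp),
                "sfi": rng.normal(0, 1, n_an * n_tp),
                "fa0": rng.uniform(0, 1, n_an * n_tp),
            })
            res = rm_anova(df, "fa0")
            assert res.df2 + n_an + 1 == n_an * n_tp

    def test_collinear_covariate_named_in_error(self, rng):
        df = pd.DataFrame({
            "animal_id": np.repeat(["a", "b"], 3),
            "sfi": rng.normal(0, 1, 6),
            "fa0": np.repeat([0.4, 0.6], 3),  # constant within animal
        })
        with pytest.raises(ValueError, match="fa0"):
            rm_anova(df, "fa0")

    def test_needs_two_animals_and_two_timepoints(self):
        df = pd.DataFrame({"animal_id": ["a"] * 4, "sfi": [1.0, 2, 3, 4],
                           "fa0": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="2 animals"):
            rm_anova(df, "fa0")
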