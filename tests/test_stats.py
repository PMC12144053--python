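"""Summary blocks, ICC variance decomposition, repeated-measures correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sm_phenotype.stats import (
    duration_checks_correlation,
    icc_between_fraction,
    rm_correlation,
    summarize,
)


def two_level_data(rng, k, n, between_sd, within_sd, mean=0.0):
    person = rng.normal(mean, between_sd, size=k)
    values = person[:, None] + rng.normal(0.0, within_sd, size=(k, n))
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i}" for i in range(k)], n),
            "value": values.ravel(),
        }
    )


class TestSummarize:
    def test_between_person_averages_within_first(self):
        df = pd.DataFrame(
            {"participant_id": ["a", "a", "b", "b"], "value": [5.0, 15.0, 30.0, 30.0]}
        )
        block = summarize(df, "value", "between_person")
        assert block.mean == 20.0 and block.n == 2
        assert block.min == 10.0 and block.max == 30.0

    def test_all_zero(self):
        df = pd.DataFrame({"participant_id": ["a"] * 4, "value": 0.0})
        block = summarize(df, "value", "daily")
        assert block.mean == 0.0 and block.sd == 0.0

    def test_hourly_flagged_as_including_idle_hours(self):
        df = pd.DataFrame({"participant_id": ["a"] * 4, "value": [0, 1, 2, 3.0]})
        assert summarize(df, "value", "hourly").includes_idle_hours
        assert not summarize(df, "value", "daily").includes_idle_hours

    def test_grains_mutually_consistent_without_missingness(self):
        rng = np.random.default_rng(5)
        df = two_level_data(rng, 6, 30, 10.0, 5.0, mean=50.0)
        between = summarize(df, "value", "between_person")
        daily = summarize(df, "value", "daily")
        person_means = df.groupby("participant_id")["value"].mean()
        assert between.mean == pytest.approx(person_means.mean())
        assert daily.mean == pytest.approx(df["value"].mean())
        # balanced design: the two grand means coincide
        assert between.mean == pytest.approx(daily.mean)

    def test_unknown_grain_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame({"participant_id": ["a"], "value": [1.0]}), "value", "weekly")


class TestIcc:
    def test_distinct_constants_give_fraction_one(self):
        df = pd.DataFrame(
            {"participant_id": np.repeat(["a", "b", "c"], 4), "value": np.repeat([1.0, 5.0, 9.0], 4)}
        )
        assert icc_between_fraction(df, "value").between_fraction == 1.0

    def test_iid_null_fraction_near_zero(self):
        rng = np.random.default_rng(6)
        k, n = 50, 40
        df = two_level_data(rng, k, n, between_sd=0.0, within_sd=1.0)
        frac = icc_between_fraction(df, "value").between_fraction
        se = np.sqrt(2.0 / (k - 1)) / n  # null fluctuation scale of the fraction
        assert frac < 3 * se

    def test_matches_pingouin_icc1_balanced(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        df = two_level_data(rng, 8, 12, 3.0, 2.0, mean=20.0)
        df["day"] = np.tile(np.arange(12), 8)
        ours = icc_between_fraction(df, "value").between_fraction
        icc_table = pg.intraclass_corr(
            data=df, targets="participant_id", raters="day", ratings="value"
        )
        icc1 = float(icc_table["ICC"].iloc[0])  # first row: one-way single-rater ICC
        assert ours == pytest.approx(icc1, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        df = two_level_data(rng, 6, 10, 4.0, 3.0)
        base = icc_between_fraction(df, "value").between_fraction
        scaled = df.assign(value=5.0 * df["value"] - 100.0)
        assert icc_between_fraction(scaled, "value").between_fraction == pytest.approx(base)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(9)
        df = two_level_data(rng, 40, 200, between_sd=np.sqrt(1.5), within_sd=1.0)
        frac = icc_between_fraction(df, "value").between_fraction
        assert 0.5 < frac < 0.7  # configured fraction 0.60

    def test_negative_between_truncated(self):
        # within-variance dominates: estimator would go negative
        df = pd.DataFrame(
            {"participant_id": ["a", "a", "b", "b"], "value": [0.0, 10.0, 5.0, 5.0]}
        )
        dec = icc_between_fraction(df, "value")
        assert dec.between_variance == 0.0 and dec.between_fraction == 0.0

    def test_single_participant_rejected(self):
        df = pd.DataFrame({"participant_id": ["a"] * 5, "value": np.arange(5.0)})
        with pytest.raises(ValueError):
            icc_between_fraction(df, "value")


class TestRmCorrelation:
    def test_identity_gives_one(self):
        x = np.arange(20.0)
        g = np.repeat(["a", "b"], 10)
        res = rm_correlation(x, x, g)
        assert res.r == 1.0 and res.p == 0.0

    def test_per_participant_offsets_do_not_mask_negative_coupling(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        offsets = np.repeat([0.0, 100.0, -50.0], 10)
        res = rm_correlation(x + offsets, -x + 2 * offsets, np.repeat(["a", "b", "c"], 10))
        assert res.r == pytest.approx(-1.0)

    @given(st.tuples(st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100)))
    def test_invariant_to_per_participant_constants(self, consts):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        base = rm_correlation(x, y, g)
        shift = np.repeat(np.asarray(consts), 10)
        shifted = rm_correlation(x + shift, y - shift, g)
        assert shifted.r == pytest.approx(base.r, abs=1e-9)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        n, k = 15, 6
        g = np.repeat([f"p{i}" for i in range(k)], n)
        x = rng.normal(size=n * k) + np.repeat(rng.normal(0, 3, k), n)
        y = 0.6 * x + rng.normal(size=n * k)
        ours = rm_correlation(x, y, g)
        theirs = pg.rm_corr(
            data=pd.DataFrame({"x": x, "y": y, "g": g}), x="x", y="y", subject="g"
        )
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert ours.df == int(theirs["dof"].iloc[0])
        assert ours.p == pytest.approx(float(theirs["pval"].iloc[0]), rel=1e-6)

    def test_common_slope_recovery(self):
        rng = np.random.default_rng(13)
        k, n, rho = 50, 30, 0.8
        g = np.repeat([f"p{i}" for i in range(k)], n)
        x = rng.normal(size=k * n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=k * n)
        y += np.repeat(rng.normal(0, 5, k), n)  # person offsets: removed by centering
        res = rm_correlation(x, y, g)
        se = np.sqrt((1 - res.r**2) / res.df)
        assert abs(res.r - rho) < 3 * se

    def test_degenerate_input_rejected(self):
        g = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError, match="within-person"):
            rm_correlation(np.ones(10), np.arange(10.0), g)

    def test_checks_proportional_to_duration(self):
        daily = pd.DataFrame(
            {
                "participant_id": np.repeat(["a", "b"], 6),
                "daily_sum": np.arange(12.0) * 5,
                "daily_checks": np.arange(12.0),
            }
        )
        assert duration_checks_correlation(daily).r == pytest.approx(1.0)

    def test_independent_checks_near_zero(self):
        rng = np.random.default_rng(14)
        k, n = 30, 50
        daily = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(k)], n),
                "daily_sum": rng.normal(size=k * n),
                "daily_checks": rng.normal(size=k * n),
            }
        )
        res = duration_checks_correlation(daily)
        se = np.sqrt(1.0 / res.df)
        assert abs(res.r) < 3 * se
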