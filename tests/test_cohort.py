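"""Exclusion logic, normality testing and Spearman correlation machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laborhrv.cohort import (
    METRIC_COLUMNS,
    OUTCOME_COLUMNS,
    apply_exclusions,
    correlation_table,
    demographics_summary,
    format_correlation_table,
    lilliefors_null,
    lilliefors_test,
    spearman_with_ci,
    time_to_delivery,
)


def _roster(n_spont, n_induced, n_cesarean, n_poor):
    rows = (
        [{"delivery_mode": "spontaneous", "quality_ok": True}] * n_spont
        + [{"delivery_mode": "induced", "quality_ok": True}] * n_induced
        + [{"delivery_mode": "cesarean", "quality_ok": True}] * n_cesarean
    )
    df = pd.DataFrame(rows)
    df.loc[: n_poor - 1, "quality_ok"] = False
    df["subject_id"] = [f"S{i}" for i in range(len(df))]
    return df


class TestExclusions:
    def test_ehg_cohort_counts(self):
        # 45 subjects: 4 induced, 6 cesarean, 10 with poor R peaks -> 25
        kept, log = apply_exclusions(_roster(35, 4, 6, 10))
        assert len(kept) == 25
        assert log == {"induced": 4, "cesarean": 6, "poorly detectable R peaks": 10}

    def test_ecg_cohort_counts(self):
        # 52 subjects, 40 non-physiological deliveries -> 12
        kept, _ = apply_exclusions(_roster(12, 24, 16, 0))
        assert len(kept) == 12

    def test_identity_when_all_usable(self):
        df = _roster(10, 0, 0, 0)
        kept, log = apply_exclusions(df)
        assert len(kept) == 10
        assert sum(log.values()) == 0

    def test_idempotent_and_order_independent(self):
        df = _roster(20, 3, 2, 5)
        kept1, _ = apply_exclusions(df)
        kept2, _ = apply_exclusions(kept1)
        assert kept1.equals(kept2)
        shuffled = df.sample(frac=1.0, random_state=4)
        kept3, _ = apply_exclusions(shuffled)
        assert sorted(kept3["subject_id"]) == sorted(kept1["subject_id"])

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(_roster(0, 3, 2, 0))


class TestTimeToDelivery:
    @pytest.mark.parametrize(
        "gd,gr,expected",
        [(40.0, 35.0, 5.0), (39.0, 39.0, 0.0), (40 + 2 / 7, 38.0, 16 / 7)],
    )
    def test_examples(self, gd, gr, expected):
        assert time_to_delivery(gd, gr) == pytest.approx(expected, abs=1e-9)

    def test_negative_difference_rejected(self):
        with pytest.raises(ValueError):
            time_to_delivery(38.0, 39.0)


class TestLilliefors:
    def test_statistic_bounded(self, rng):
        for _ in range(20):
            d, _ = lilliefors_test(rng.normal(size=rng.integers(5, 100)),
                                   n_mc=200, seed=1)
            assert 0.0 <= d <= 1.0

    def test_gaussian_samples_usually_pass(self):
        null = lilliefors_null(2000, n_mc=2000, seed=7)
        rng = np.random.default_rng(8)
        accepted = sum(
            lilliefors_test(rng.standard_normal(2000), null_stats=null)[1] > 0.05
            for _ in range(100)
        )
        assert accepted >= 90

    def test_uniform_samples_rejected(self):
        # power against uniform(0,1) at n=200 is ~0.94 (measured with the
        # statsmodels implementation as an independent oracle)
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        null = lilliefors_null(200, n_mc=2000, seed=9)
        rng = np.random.default_rng(10)
        ours = oracle = 0
        for _ in range(100):
            x = rng.uniform(0, 1, size=200)
            ours += lilliefors_test(x, null_stats=null)[1] <= 0.05
            oracle += sm_lilliefors(x)[1] <= 0.05
        assert ours >= 90
        assert abs(ours - oracle) <= 3

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        x = rng.normal(size=200)
        d_ours, p_ours = lilliefors_test(x, n_mc=5000, seed=3)
        d_sm, p_sm = sm_lilliefors(x)
        assert d_ours == pytest.approx(d_sm, abs=1e-12)
        assert p_ours == pytest.approx(min(p_sm, 1.0), abs=0.05)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_test(np.full(20, 3.0))


def _oracle_spearman(x, y):
    """Independent mid-rank correlation via scipy ranks + plain Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _oracle_exact_p(x, y):
    """Two-sided permutation p by direct itertools enumeration."""
    r_obs = abs(_oracle_spearman(x, y))
    y = np.asarray(y, dtype=float)
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        r = abs(_oracle_spearman(x, y[list(perm)]))
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4]
        assert spearman_with_ci(x, [10, 20, 30, 40]).r == pytest.approx(1.0)
        assert spearman_with_ci(x, [40, 30, 20, 10]).r == pytest.approx(-1.0)

    def test_worked_example(self):
        res = spearman_with_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        assert res.p == pytest.approx(_oracle_exact_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_all_permutations_of_five_match_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0, 4.0]):  # with ties
            res = spearman_with_ci(x, list(perm))
            assert res.r == pytest.approx(_oracle_spearman(x, perm), abs=1e-12)

    @pytest.mark.parametrize("n", [6, 7])
    def test_exact_p_matches_enumeration(self, n, rng):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        y[1] = y[0]  # introduce a tie
        res = spearman_with_ci(x, y)
        assert res.p == pytest.approx(_oracle_exact_p(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman_with_ci(x, y)
        ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ci_brackets_estimate(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_with_ci(x, y)
        assert res.ci_low <= res.r <= res.ci_high
        assert -1.0 <= res.ci_low and res.ci_high <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


def _metric_cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({m: rng.normal(size=n) for m in METRIC_COLUMNS})
    df["ga_delivery"] = rng.uniform(37, 41, size=n)
    df["ttd"] = rng.uniform(0, 9.3, size=n)
    df["ga_recording"] = df["ga_delivery"] - df["ttd"]
    df["age"] = rng.normal(29, 5, size=n)
    df["bmi"] = rng.normal(26, 4, size=n)
    df["subject_id"] = [f"S{i}" for i in range(n)]
    df["delivery_mode"] = "spontaneous"
    df["quality_ok"] = True
    return df


class TestTables:
    def test_correlation_table_shape(self):
        table = correlation_table(_metric_cohort())
        assert len(table) == 7  # one row per HRV metric
        for o in OUTCOME_COLUMNS:
            assert {f"{o}_r", f"{o}_p", f"{o}_ci_low", f"{o}_ci_high"} <= set(table.columns)
        assert table.attrs["primary_outcome"] == "ttd"

    def test_null_cohort_small_correlations(self):
        rs = []
        for seed in range(20):
            table = correlation_table(_metric_cohort(n=37, seed=seed))
            rs.extend(table["ttd_r"].tolist())
        assert np.mean(np.abs(rs) > 0.5) < 0.05

    def test_missing_metric_column_rejected(self):
        df = _metric_cohort().drop(columns=["sdnn"])
        with pytest.raises(KeyError):
            correlation_table(df)

    def test_bh_option_adds_columns(self):
        table = correlation_table(_metric_cohort(), bh_correct=True)
        assert "ttd_p_bh" in table.columns
        assert (table["ttd_p_bh"] >= table["ttd_p"] - 1e-12).all()

    def test_formatting_mentions_primary_outcome(self):
        text = format_correlation_table(correlation_table(_metric_cohort()))
        assert "Time to delivery" in text and "primary" in text.lower()

    def test_demographics_groups(self):
        df = _metric_cohort(n=30)
        df.loc[:14, "delivery_mode"] = "induced"
        out = demographics_summary(df, group_by="delivery_mode")
        assert set(out["group"]) == {"induced", "spontaneous"}
        assert out["n"].sum() == 30

    def test_single_subject_sd_flagged(self):
        out = demographics_summary(_metric_cohort(n=1))
        assert out.loc[0, "age_sd"] == 0.0
        assert not out.loc[0, "age_sd_defined"]
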