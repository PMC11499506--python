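"""Cohort statistics against independent brute-force oracles.

Oracles here use raw order statistics, explicit normal equations
(np.linalg.solve on X'X) and the F survival function directly — independent
of the statsmodels fitting path used by the implementation.
"""

import math

import numpy as np
import pytest
from scipy import stats

from petglu.cohort import (
    RISK_FACTORS,
    PatientRecord,
    ancova,
    describe,
    multiple_regression,
    paired_delta,
    read_cohort_csv,
    records_to_dataframe,
)
from petglu.errors import (
    EmptyInput,
    GroupEmpty,
    PairingError,
    SchemaError,
    SingularDesign,
)
from petglu.phantom import make_synthetic_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Linear interpolation of order statistics, written out longhand."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])

def skew_oracle(values):
    """Adjusted Fisher-Pearson standardized third moment."""
    v = np.asarray(values, float)
    n = len(v)
    m = v.mean()
    m2 = ((v - m) ** 2).mean()
    m3 = ((v - m) ** 3).mean()
    g1 = m3 / m2**1.5
    return math.sqrt(n * (n - 1)) / (n - 2) * g1

def ols_oracle(x, y):
    """Normal equations + residual sums; returns (beta, ssr, rank)."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    return beta, float(resid @ resid), np.linalg.matrix_rank(x)

def ancova_oracle(pre, post, group_ind):
    x_full = np.column_stack([np.ones_like(pre), pre, group_ind])
    x_red = x_full[:, :2]
    _, ssr_full, _ = ols_oracle(x_full, post)
    _, ssr_red, _ = ols_oracle(x_red, post)
    df_den = len(post) - 3
    f = (ssr_red - ssr_full) / (ssr_full / df_den)
    return f, float(stats.f.sf(f, 1, df_den))


def _records(pre_a, post_a, groups, pre_m=None, post_m=None):
    pre_m = pre_m if pre_m is not None else pre_a
    post_m = post_m if post_m is not None else post_a
    return [
        PatientRecord(id=str(i), group=g, mrglu_aorta_pre=a, mrglu_aorta_post=b,
                      mrglu_myoc_pre=c, mrglu_myoc_post=d)
        for i, (g, a, b, c, d) in enumerate(zip(groups, pre_a, post_a, pre_m, post_m))
    ]


class TestDescribe:
    def test_symmetric_sequence(self):
        d = describe([1, 2, 3, 4, 5])
        assert (d.min, d.q1, d.median, d.q3, d.max) == (1, 2, 3, 4, 5)
        assert d.mean == 3
        assert d.skewness == pytest.approx(0.0, abs=1e-12)

    def test_single_value(self):
        d = describe([7.0])
        assert (d.min, d.q1, d.median, d.q3, d.max) == (7, 7, 7, 7, 7)
        assert d.skewness is None

    def test_empty_raises(self):
        with pytest.raises(EmptyInput):
            describe([])

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.normal(5, 3, 10)
        d = describe(v)
        assert d.q1 == pytest.approx(quantile_oracle(v, 0.25), abs=1e-10)
        assert d.median == pytest.approx(quantile_oracle(v, 0.5), abs=1e-10)
        assert d.q3 == pytest.approx(quantile_oracle(v, 0.75), abs=1e-10)
        assert d.skewness == pytest.approx(skew_oracle(v), abs=1e-10)
        assert d.mean == pytest.approx(v.mean(), abs=1e-12)

    def test_order_invariant(self):
        assert describe([3, 1, 2]).median == describe([1, 2, 3]).median


class TestPairedDelta:
    def test_printed_group_means_reproduce_deltas(self):
        """Post-minus-pre of the published group means gives the published
        delta column (structural identity of the delta table)."""
        cases = [
            (-2.99, 1.09, 4.08),   # empagliflozin aorta
            (11.99, 14.85, 2.86),  # empagliflozin myocardium
            (-3.99, -0.24, 3.75),  # glimepiride aorta
            (11.50, 11.36, -0.14), # glimepiride myocardium
        ]
        for pre_mean, post_mean, delta in cases:
            # any paired sample with those means has delta mean post - pre
            rng = np.random.default_rng(1)
            noise = rng.normal(0, 1, 10)
            noise -= noise.mean()
            dmean, _, _ = paired_delta(pre_mean + noise, post_mean + noise[::-1])
            assert dmean == pytest.approx(delta, abs=1e-12)

    def test_identical_pairs_zero_delta(self):
        v = [1.0, 2.0, 3.0]
        dmean, dsd, deltas = paired_delta(v, v)
        assert dmean == 0.0 and dsd == 0.0
        assert np.all(deltas == 0.0)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            paired_delta([1, 2], [1, 2, 3])


class TestAncova:
    def test_identical_groups_give_null_result(self):
        pre = [1.0, 2.0, 3.0, 4.0] * 2
        post = [2.0, 2.5, 4.0, 5.0] * 2
        groups = ["Group1"] * 4 + ["Group2"] * 4
        res = ancova(_records(pre, post, groups), "aorta")
        assert res.group_f == pytest.approx(0.0, abs=1e-12)
        assert res.group_p == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # fixed printed 8-row toy dataset
        pre = np.array([-4.3, -4.8, -6.4, -0.5, 1.2, -2.1, 0.7, -3.3])
        post = np.array([-0.9, -0.6, 1.4, 0.7, 2.3, 1.0, 3.1, -0.2])
        groups = ["Group1"] * 4 + ["Group2"] * 4
        res = ancova(_records(pre, post, groups), "aorta")
        f, p = ancova_oracle(pre, post, np.array([0.0] * 4 + [1.0] * 4))
        assert res.group_f == pytest.approx(f, abs=1e-8)
        assert res.group_p == pytest.approx(p, abs=1e-8)

    def test_recovers_simulated_group_effect(self):
        effects = {"aorta": {"Group1": 0.0, "Group2": 4.0},
                   "myoc": {"Group1": 0.0, "Group2": 0.0}}
        records = make_synthetic_cohort(200, effects=effects, seed=5)
        res = ancova(records, "aorta")
        assert abs(res.group_effect - 4.0) <= 3.0 * res.group_effect_se
        assert res.group_p < 0.001

    def test_group_empty(self):
        pre = [1.0, 2.0, 3.0]
        groups = ["Group1", "Group1", "Group2"]
        with pytest.raises(GroupEmpty):
            ancova(_records(pre, pre, groups), "aorta")

    def test_delta_identity(self):
        records = make_synthetic_cohort(20, seed=2)
        res = ancova(records, "myoc")
        for gd in res.per_group.values():
            assert gd.delta_mean == pytest.approx(gd.post_mean - gd.pre_mean,
                                                  abs=1e-10)

    def test_negative_filtering_drops_rows(self):
        records = make_synthetic_cohort(50, seed=3)
        res_all = ancova(records, "aorta", filter_negatives=False)
        res_flt = ancova(records, "aorta", filter_negatives=True)
        n_all = sum(g.n for g in res_all.per_group.values())
        n_flt = sum(g.n for g in res_flt.per_group.values())
        assert n_flt < n_all  # default aorta distribution straddles zero
        for gd in res_flt.per_group.values():
            assert gd.pre_mean >= 0.0

    def test_null_p_values_uniform_under_permutation(self):
        """With labels permuted at random the ANCOVA group p-value follows
        U(0,1); checked by a Kolmogorov-Smirnov test on 500 permutations."""
        rng = np.random.default_rng(17)
        n = 40
        pre = rng.normal(0, 3, n)
        post = pre * 0.8 + rng.normal(0, 2, n)
        pvals = []
        for _ in range(500):
            labels = np.array(["Group1"] * (n // 2) + ["Group2"] * (n // 2))
            rng.shuffle(labels)
            res = ancova(_records(pre, post, labels), "aorta")
            pvals.append(res.group_p)
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01


class TestMultipleRegression:
    def test_perfect_linear_fit_gives_r_one(self):
        rng = np.random.default_rng(21)
        n = 40
        records = make_synthetic_cohort(n // 2, seed=21, post_noise_sd=0.0,
                                        regression_link={
                                            "district": "aorta",
                                            "intercept": 3.0,
                                            "coefficients": {"bmi": 2.0,
                                                             "fpg": -1.0},
                                            "noise_sd": 0.0,
                                        })
        res = multiple_regression(records, "mrglu_aorta", ("bmi", "fpg"))
        assert res.multiple_r == pytest.approx(1.0, abs=1e-8)
        assert res.coefficients["bmi"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients["fpg"] == pytest.approx(-1.0, abs=1e-8)

    def test_rank_deficiency_with_small_n(self):
        records = make_synthetic_cohort(5, seed=1)  # n=10 vs 13 predictors
        with pytest.raises(SingularDesign):
            multiple_regression(records, "mrglu_aorta", RISK_FACTORS)

    def test_duplicate_predictor_reported(self):
        records = make_synthetic_cohort(20, seed=1)
        with pytest.raises(SingularDesign, match="bmi"):
            multiple_regression(records, "mrglu_aorta", ("bmi", "bmi", "fpg"))

    def test_matches_least_squares_oracle_and_recovers_coefficients(self):
        link = {"district": "myoc", "intercept": 2.0,
                "coefficients": {"bmi": 0.8, "sbp": -0.3, "pwv": 1.5},
                "noise_sd": 1.0}
        records = make_synthetic_cohort(100, seed=9, regression_link=link)
        preds = ("bmi", "sbp", "pwv")
        res = multiple_regression(records, "mrglu_myoc", preds)
        df = records_to_dataframe(records)
        x = np.column_stack([np.ones(len(df)),
                             df[list(preds)].to_numpy(dtype=float)])
        y = df["mrglu_myoc_pre"].to_numpy(dtype=float)
        beta, ssr, _ = ols_oracle(x, y)
        sst = float(((y - y.mean()) ** 2).sum())
        r_oracle = math.sqrt(1.0 - ssr / sst)
        assert res.multiple_r == pytest.approx(r_oracle, abs=1e-8)
        for name, truth in link["coefficients"].items():
            est = res.coefficients[name]
            se = res.std_errors[name]
            assert abs(est - truth) <= 3 * se
        p = len(preds)
        f_oracle = ((sst - ssr) / p) / (ssr / (len(y) - p - 1))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-8)

    def test_r_invariant_under_predictor_rescaling(self):
        records = make_synthetic_cohort(50, seed=13)
        preds = ("bmi", "fpg", "age_years")
        base = multiple_regression(records, "mrglu_aorta", preds).multiple_r
        for r in records:
            r.bmi = 100.0 * r.bmi + 7.0  # affine rescale of one predictor
        rescaled = multiple_regression(records, "mrglu_aorta", preds).multiple_r
        assert rescaled == pytest.approx(base, abs=1e-10)


class TestTableIO:
    def test_csv_round_trip(self, tmp_path):
        from petglu.cohort import write_cohort_csv

        records = make_synthetic_cohort(3, seed=0)
        write_cohort_csv(records, tmp_path / "c.csv")
        back = read_cohort_csv(tmp_path / "c.csv")
        assert len(back) == 6
        assert back[0].group == "Group1"
        assert back[0].bmi == pytest.approx(records[0].bmi)

    def test_missing_group_column(self, tmp_path):
        (tmp_path / "bad.csv").write_text("id,bmi\n1,30\n")
        with pytest.raises(SchemaError, match="group"):
            read_cohort_csv(tmp_path / "bad.csv")

    def test_non_numeric_value_names_column(self, tmp_path):
        (tmp_path / "bad.csv").write_text("id,group,bmi\n1,Group1,heavy\n")
        with pytest.raises(SchemaError, match="bmi"):
            read_cohort_csv(tmp_path / "bad.csv")

    def test_bad_group_label(self):
        with pytest.raises(SchemaError):
            PatientRecord(id="1", group="GroupX")
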