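import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lineagescore.containers import ClinicalTable, ValidationError
from lineagescore.survival import (
    bh_adjust,
    cox_multivariate,
    cox_univariate,
    cox_univariate_all,
    dichotomize_lss,
    group_tests,
    km_logrank,
)


def bh_closed_form(p):
    """Independent step-up oracle: adj_(i) = min_{j>=i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def make_clinical(times, events, index=None, **covs):
    idx = index or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"time": times, "event": events, **covs}, index=idx)
    )


def simulate_exponential(rng, x, beta, n, baseline=0.1, censor_q=0.7):
    hazard = baseline * np.exp(beta * x)
    t = rng.exponential(1 / hazard)
    c = rng.uniform(0, np.quantile(t, censor_q) * 2, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_matches_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_closed_form(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestCoxUnivariate:
    def test_recovers_planted_coefficient(self):
        """Exponential survival with log-hazard 0.5x: mean estimate within
        +-0.1 of 0.5 across replicates (n=500)."""
        rng = np.random.default_rng(2)
        coefs = []
        for _ in range(20):
            x = rng.normal(size=500)
            t, e = simulate_exponential(rng, x, 0.5, 500)
            clin = make_clinical(t, e)
            res = cox_univariate(pd.Series(x, index=clin.sample_ids), clin)
            coefs.append(res.coef)
        assert np.mean(coefs) == pytest.approx(0.5, abs=0.1)

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        bias = {}
        for n in (100, 500, 2000):
            coefs = []
            for _ in (range(30) if n < 2000 else range(10)):
                x = rng.normal(size=n)
                t, e = simulate_exponential(rng, x, 0.7, n)
                clin = make_clinical(t, e)
                coefs.append(cox_univariate(pd.Series(x, index=clin.sample_ids), clin).coef)
            bias[n] = abs(np.mean(coefs) - 0.7)
        assert bias[2000] < 0.1 and bias[100] < 0.25

    def test_constant_covariate_flagged_not_crashed(self):
        rng = np.random.default_rng(4)
        t, e = simulate_exponential(rng, np.zeros(60), 0.0, 60)
        clin = make_clinical(t, e)
        res = cox_univariate(pd.Series(1.0, index=clin.sample_ids), clin)
        assert not res.converged
        assert np.isnan(res.coef)

    def test_no_events_rejected(self):
        clin = make_clinical([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValidationError, match="events"):
            cox_univariate(pd.Series([1.0, 2.0, 3.0], index=clin.sample_ids), clin)

    def test_screen_adjusts_once_across_all_celltypes(self):
        rng = np.random.default_rng(5)
        n = 120
        t, e = simulate_exponential(rng, rng.normal(size=n), 0.0, n)
        clin = make_clinical(t, e)
        wide = pd.DataFrame(
            rng.normal(size=(n, 6)),
            index=clin.sample_ids,
            columns=[f"CT{i}" for i in range(6)],
        )
        results = cox_univariate_all(wide, clin)
        raw = np.array([r.wald_p for r in results])
        adj = np.array([r.adj_p for r in results])
        np.testing.assert_allclose(adj, bh_closed_form(raw), atol=1e-12)


class TestCoxMultivariate:
    def test_no_covariates_equals_univariate(self):
        rng = np.random.default_rng(6)
        n = 150
        x = rng.normal(size=n)
        t, e = simulate_exponential(rng, x, 0.4, n)
        clin = make_clinical(t, e)
        s = pd.Series(x, index=clin.sample_ids)
        uni = cox_univariate(s, clin)
        multi = cox_multivariate(s, clin, covariates=[])
        assert multi.coef == pytest.approx(uni.coef, rel=1e-6)
        assert multi.wald_p == pytest.approx(uni.wald_p, rel=1e-6)

    def test_adjustment_reduces_confounding_bias(self):
        """Age drives both the score and the hazard; the age-adjusted LSS
        coefficient is closer to the direct effect than the unadjusted."""
        rng = np.random.default_rng(7)
        direct = 0.3
        diffs_unadj, diffs_adj = [], []
        for _ in range(30):
            n = 300
            age = rng.normal(size=n)
            x = 0.8 * age + rng.normal(size=n) * 0.6
            t, e = simulate_exponential(rng, direct * x + 0.8 * age, 1.0, n)
            clin = make_clinical(t, e, age=age)
            s = pd.Series(x, index=clin.sample_ids)
            diffs_unadj.append(cox_univariate(s, clin).coef - direct)
            diffs_adj.append(
                cox_multivariate(s, clin, covariates=["age"]).coef - direct
            )
        assert abs(np.mean(diffs_adj)) < abs(np.mean(diffs_unadj))

    def test_categorical_dummy_coding_against_reference(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.normal(size=n)
        t, e = simulate_exponential(rng, x, 0.5, n)
        flt3 = rng.choice(["wildtype", "mutated"], size=n)
        clin = make_clinical(t, e, flt3=flt3)
        res = cox_multivariate(
            pd.Series(x, index=clin.sample_ids), clin, covariates=["flt3"]
        )
        assert res.n == n and np.isfinite(res.coef)

    def test_missing_covariate_column_rejected(self):
        rng = np.random.default_rng(9)
        t, e = simulate_exponential(rng, np.zeros(50), 0.0, 50)
        clin = make_clinical(t, e)
        with pytest.raises(ValidationError, match="cyto_risk"):
            cox_multivariate(
                pd.Series(np.arange(50.0), index=clin.sample_ids),
                clin,
                covariates=["cyto_risk"],
            )

    def test_singular_design_names_aliased_columns(self):
        rng = np.random.default_rng(10)
        n = 100
        x = rng.normal(size=n)
        t, e = simulate_exponential(rng, x, 0.5, n)
        age = rng.normal(size=n)
        clin = make_clinical(t, e, age=age, age_copy=age)
        with pytest.raises(ValidationError, match="age_copy"):
            cox_multivariate(
                pd.Series(x, index=clin.sample_ids),
                clin,
                covariates=["age", "age_copy"],
            )


class TestDichotomize:
    def test_bimodal_split_at_valley(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(-2, 0.5, 200), rng.normal(2, 0.5, 200)])
        threshold, labels = dichotomize_lss(x)
        assert -1 < threshold < 1
        assert set(labels) == {"high", "low"}
        assert (x[labels == "high"] > threshold).all()

    def test_unimodal_split_near_mode(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 400)
        threshold, labels = dichotomize_lss(x)
        kde = stats.gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), 2000)
        mode = grid[np.argmax(kde(grid))]
        assert threshold == pytest.approx(mode, abs=0.3)
        assert len(np.unique(labels)) == 2

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            dichotomize_lss(np.full(50, 1.23))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="20"):
            dichotomize_lss(np.arange(10.0))


class TestKMLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        clin = make_clinical(np.concatenate([t, t]), np.concatenate([e, e]))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        curves, p = km_logrank(labels, clin)
        assert p == 1.0
        assert set(curves) == {"a", "b"}

    def test_power_against_large_hazard_ratio(self):
        """HR = 3 between two arms of 200: log-rank p < 0.01 in nearly all
        replicates (scaled-down replicate count)."""
        rng = np.random.default_rng(13)
        hits = 0
        reps = 20
        for _ in range(reps):
            t1 = rng.exponential(1 / 0.1, 200)
            t2 = rng.exponential(1 / 0.3, 200)
            c = rng.uniform(0, 30, 400)
            t = np.concatenate([t1, t2])
            e = (t <= c).astype(int)
            clin = make_clinical(np.minimum(t, c), e)
            _, p = km_logrank(np.array(["lo"] * 200 + ["hi"] * 200), clin)
            hits += p < 0.01
        assert hits >= 0.9 * reps

    def test_curve_steps_only_at_event_times(self):
        t = np.array([1.0, 2.0, 2.5, 4.0, 5.0])
        e = np.array([1, 0, 1, 0, 1])
        clin = make_clinical(np.concatenate([t, [9.0] * 3]), np.concatenate([e, [1, 1, 0]]))
        labels = np.array(["x"] * 5 + ["y"] * 3)
        curves, _ = km_logrank(labels, clin)
        cx = curves["x"]
        drops = cx["time"][cx["survival"].diff().fillna(0) < 0]
        assert set(drops) <= {1.0, 2.5, 5.0}

    def test_single_group_rejected(self):
        clin = make_clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError, match="2 groups"):
            km_logrank(np.array(["a", "a"]), clin)


class TestDichotomizedVsContinuousAgreement:
    def test_logrank_and_cox_agree_in_direction(self):
        """On a planted signal, the dichotomized comparison and the
        continuous Cox fit point the same way: positive coefficient and a
        worse high-score arm."""
        rng = np.random.default_rng(18)
        n = 300
        x = np.concatenate([rng.normal(-1.5, 0.5, n // 2), rng.normal(1.5, 0.5, n // 2)])
        t, e = simulate_exponential(rng, x, 0.6, n)
        clin = make_clinical(t, e)
        s = pd.Series(x, index=clin.sample_ids)
        cox = cox_univariate(s, clin)
        threshold, labels = dichotomize_lss(x)
        curves, p = km_logrank(labels, clin)
        assert cox.coef > 0 and cox.wald_p < 0.01
        assert p < 0.01
        # the high-score arm ends with lower survival
        final = {g: c["survival"].iloc[-1] for g, c in curves.items()}
        assert final["high"] < final["low"]


class TestGroupTests:
    def test_kruskal_null_p_uniform(self):
        """Kruskal-Wallis p-values under identical distributions are
        uniform (KS test across replicates)."""
        rng = np.random.default_rng(14)
        ps = []
        groups = np.repeat(["a", "b", "c"], 50)
        for _ in range(500):
            report = group_tests(rng.normal(size=150), groups)
            ps.append(report.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shift_alternative_detected(self):
        rng = np.random.default_rng(15)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        report = group_tests(x, np.repeat(["wildtype", "mutated"], 50))
        assert report.test == "wilcoxon-rank-sum"
        assert report.p_value < 0.001

    def test_group_sizes_reported(self):
        rng = np.random.default_rng(16)
        report = group_tests(
            rng.normal(size=70), np.repeat(["M0", "M1", "M4"], [20, 30, 20])
        )
        assert report.group_sizes == {"M0": 20, "M1": 30, "M4": 20}
        assert report.pairwise is not None and len(report.pairwise) == 3

    def test_one_sided_available(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        g = np.repeat(["CR", "REL"], 40)
        two = group_tests(x, g).p_value
        one = group_tests(x, g, alternative="less").p_value
        assert one < two

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValidationError, match="2 groups"):
            group_tests(np.arange(5.0), np.array(["a", "a", "a", "a", "b"]))
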