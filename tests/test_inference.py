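import itertools
import math

import numpy as np
import pandas as pd
import pytest

from placmatch.errors import SeparationError, ValidationError
from placmatch.inference import (
    clopper_pearson,
    fit_logistic,
    fit_rfm_logistic,
    mann_whitney_u,
    pseudo_r2_from_deviances,
    students_t_test,
)


class TestClopperPearson:
    def test_study_scale_interval(self):
        ci = clopper_pearson(14, 43)
        assert round(ci.point, 3) == 0.326
        assert round(ci.lower, 3) == 0.191
        assert round(ci.upper, 3) == 0.485

    def test_zero_successes_lower_bound(self):
        assert clopper_pearson(0, 10).lower == 0.0

    def test_all_successes_upper_bound(self):
        assert clopper_pearson(10, 10).upper == 1.0

    def test_ordering_invariant(self):
        ci = clopper_pearson(3, 7)
        assert 0 <= ci.lower <= ci.point <= ci.upper <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            clopper_pearson(5, 3)
        with pytest.raises(ValidationError):
            clopper_pearson(1, 10, level=1.5)

    def test_coverage_at_least_nominal(self):
        """Exact interval covers the truth in >= 95% of simulated binomials."""
        rng = np.random.default_rng(5)
        for p in (0.1, 0.33, 0.5):
            n = 43
            xs = rng.binomial(n, p, size=4000)
            covered = 0
            for x in np.unique(xs):
                ci = clopper_pearson(int(x), n)
                if ci.lower <= p <= ci.upper:
                    covered += int((xs == x).sum())
            rate = covered / len(xs)
            se = math.sqrt(0.95 * 0.05 / len(xs))
            assert rate >= 0.95 - 3 * se


class TestLogistic:
    def _univariate(self, n11, n10, n01, n00):
        # exposed: n11 events / n10 non-events; referent: n01 / n00
        y = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00, dtype=float)
        x = np.array([1] * (n11 + n10) + [0] * (n01 + n00), dtype=float)
        X = pd.DataFrame({"Intercept": np.ones_like(x), "exposed": x})
        return fit_logistic(y, X)

    def test_univariate_or_equals_cross_product(self):
        # MFC-exposed 3 RFM / 4 control vs NC-referent 7 RFM / 17 control
        res = self._univariate(3, 4, 7, 17)
        assert res.terms.loc["exposed", "OR"] == pytest.approx((3 * 17) / (7 * 4), rel=1e-6)
        assert round(res.terms.loc["exposed", "OR"], 2) == 1.82

    def test_saturated_design_reproduces_cell_log_odds(self):
        res = self._univariate(5, 10, 4, 16)
        assert res.terms.loc["Intercept", "estimate"] == pytest.approx(
            math.log(4 / 16), abs=1e-6
        )
        assert res.terms.loc["exposed", "estimate"] == pytest.approx(
            math.log(5 / 10) - math.log(4 / 16), abs=1e-6
        )

    def test_information_criteria_identities(self):
        res = self._univariate(5, 10, 4, 16)
        k, n = 2, 35
        assert res.aic - res.deviance_model == pytest.approx(2 * k)
        assert res.bic - res.deviance_model == pytest.approx(k * math.log(n))
        assert res.lr_chi2 == pytest.approx(res.deviance_null - res.deviance_model)
        assert res.lr_chi2 >= 0

    def test_null_deviance_matches_analytic_binomial(self):
        res = self._univariate(5, 10, 9, 19)
        n, events = 43, 14
        analytic = -2 * (
            events * math.log(events / n) + (n - events) * math.log(1 - events / n)
        )
        assert res.deviance_null == pytest.approx(analytic, abs=1e-8)

    def test_degenerate_outcome_raises(self):
        y = np.zeros(10)
        X = pd.DataFrame({"Intercept": np.ones(10)})
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_complete_separation_raises(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = y.copy()
        X = pd.DataFrame({"Intercept": np.ones(20), "x": x})
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_collinear_design_raises(self):
        y = np.array([0.0, 1.0] * 10)
        X = pd.DataFrame({"Intercept": np.ones(20), "a": np.ones(20)})
        with pytest.raises(ValidationError, match="collinear"):
            fit_logistic(y, X)

    def test_parameter_recovery_on_simulated_study(self):
        """Betas recovered within 3 SE when fitting the generating model at n=5,000."""
        from placmatch.compatibility import classify_pairs
        from placmatch.synthetic_data import SimulationConfig, simulate_study

        true = {
            "beta0": -1.04,
            "beta_mcfc_i": 0.34,
            "beta_mfc_i": 0.97,
            "beta_mcfc_ii": 0.16,
            "beta_mfc_ii": -1.01,
        }
        study = simulate_study(
            SimulationConfig(
                seed=21, n_pairs=5000, null_allele_freq={}, rfm_model=dict(true)
            )
        )
        calls = classify_pairs(study.genotypes, study.pairs)
        res = fit_rfm_logistic(calls)
        expected = {
            "Intercept": true["beta0"],
            "MHC I MC+FC": true["beta_mcfc_i"],
            "MHC I MFC": true["beta_mfc_i"],
            "MHC II MC+FC": true["beta_mcfc_ii"],
            "MHC II MFC": true["beta_mfc_ii"],
        }
        for term, beta in expected.items():
            est = res.terms.loc[term, "estimate"]
            se = res.terms.loc[term, "se"]
            assert abs(est - beta) < 3 * se, term


class TestPseudoR2:
    def test_reference_deviance_arithmetic(self):
        """Deviances 52.70 -> 50.84 at n=43 give Cox-Snell and McFadden 0.04."""
        r2 = pseudo_r2_from_deviances(52.70, 50.84, 43)
        assert round(r2["cox_snell"], 2) == 0.04
        assert round(r2["mcfadden"], 2) == 0.04
        assert round(r2["nagelkerke"], 2) == 0.06
        assert r2["lr_chi2"] == pytest.approx(1.86)

    def test_model_worse_than_null_rejected(self):
        with pytest.raises(ValidationError):
            pseudo_r2_from_deviances(50.0, 51.0, 43)


class TestTTest:
    def test_identical_samples(self):
        res = students_t_test([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_equal_means(self):
        res = students_t_test([2, 2], [2, 2])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        res = students_t_test([2, 2], [3, 3])
        assert math.isinf(res.t)
        assert res.p == 0.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(23)
        reps, rejections = 1000, 0
        for _ in range(reps):
            a = rng.normal(size=12)
            b = rng.normal(size=15)
            if students_t_test(a, b).p < 0.05:
                rejections += 1
        rate = rejections / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se


class TestMannWhitney:
    def test_balanced_symmetry(self):
        # rank-symmetric samples: both groups hold the same rank pattern
        res = mann_whitney_u([1, 4, 5, 8], [2, 3, 6, 7])
        assert res.u == 4 * 4 / 2

    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0

    def test_exact_matches_permutation_oracle(self):
        """Full-enumeration oracle over all 5+5 group assignments."""
        a = [1.2, 3.4, 5.1, 7.8, 9.9]
        b = [2.2, 4.1, 6.3, 8.0, 10.5]
        res = mann_whitney_u(a, b, mode="exact")
        pooled = np.array(a + b)
        ranks = pooled.argsort().argsort() + 1

        def u_min(idx_a):
            ra = ranks[list(idx_a)].sum()
            ua = ra - 5 * 6 / 2
            return min(ua, 25 - ua)

        observed = u_min(range(5))
        count = sum(
            u_min(combo) <= observed
            for combo in itertools.combinations(range(10), 5)
        )
        oracle_p = count / math.comb(10, 5)
        assert res.method == "exact"
        assert res.u == observed
        assert res.p == pytest.approx(oracle_p, abs=1e-12)

    def test_ties_fall_back_to_normal_approx(self):
        res = mann_whitney_u([1, 1, 2], [1, 2, 3], mode="auto")
        assert res.method == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])
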