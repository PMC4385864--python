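"""Kaplan-Meier, log-rank, hazard ratios and Cox regression."""

import numpy as np
import pandas as pd
import pytest

from hmtscore.survival import (
    cna_groups,
    cox_multivariate,
    kaplan_meier,
    logrank,
    median_split,
    survival_association,
    univariate_hr,
)

from _oracles import cox_univariate_nr, km_product_limit_bf, logrank_two_group_bf
from conftest import make_cohort


def _survival_cohort(times, events, calls=None, z=None, gene="G"):
    samples = [f"S{i}" for i in range(len(times))]
    kw = {}
    if calls is not None:
        kw["cn"] = pd.DataFrame([calls], index=pd.Index([gene], name="gene"), columns=samples)
    if z is not None:
        kw["expr"] = pd.DataFrame([z], index=pd.Index([gene], name="gene"), columns=samples)
    clinical = pd.DataFrame(
        {
            "subtype": "unknown",
            "os_months": [float(t) for t in times],
            "os_event": [float(e) for e in events],
            "age_years": np.nan, "er": "unknown", "pr": "unknown", "her2": "unknown",
            "tumor_size": np.nan, "node_status": np.nan, "metastasis_status": np.nan,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return make_cohort(clinical=clinical, samples=samples, **kw)


class TestGrouping:
    def test_cna_group_assignment(self):
        cohort = _survival_cohort([10] * 5, [1] * 5, calls=[-2, -1, 0, 1, 2])
        labels = cna_groups(cohort, "G")
        assert labels.tolist() == ["deletion", "deletion", "diploid", "amp_gain", "amp_gain"]

    def test_assignment_equals_set_membership(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-2, 3, size=50).tolist()
        cohort = _survival_cohort(rng.exponential(10, 50), [1] * 50, calls=calls)
        labels = cna_groups(cohort, "G")
        for s, c in zip(cohort.samples, calls):
            expect = "amp_gain" if c >= 1 else "diploid" if c == 0 else "deletion"
            assert labels[s] == expect

    def test_single_group_not_computable(self):
        cohort = _survival_cohort([5, 6, 7], [1, 1, 0], calls=[0, 0, 0])
        with pytest.raises(ValueError, match="two non-empty groups"):
            survival_association(cohort, "G", "cna")

    def test_median_split_770_distinct_values_gives_385_each(self):
        rng = np.random.default_rng(1)
        z = rng.permutation(np.linspace(-3, 3, 770)).tolist()
        cohort = _survival_cohort(rng.exponential(50, 770), [1] * 770, z=z)
        labels = median_split(cohort, "G")
        assert (labels == "low").sum() == 385
        assert (labels == "high").sum() == 385

    def test_median_split_four_values(self):
        cohort = _survival_cohort([1, 2, 3, 4], [1] * 4, z=[1.0, 2.0, 3.0, 4.0])
        labels = median_split(cohort, "G")
        assert labels.tolist() == ["low", "low", "high", "high"]

    @pytest.mark.parametrize("z", [
        [1.0, 2.0, 2.0, 4.0],        # ties exactly at the median
        [2.0, 2.0, 2.0, 4.0, 5.0],   # median equals the tied value
        [1.0, 1.0, 1.0, 1.0, 9.0],
    ])
    def test_ties_at_median_go_low(self, z):
        cohort = _survival_cohort([1] * len(z), [1] * len(z), z=z)
        labels = median_split(cohort, "G")
        med = float(np.median(z))
        for s, v in zip(cohort.samples, z):
            assert labels[s] == ("low" if v <= med else "high")

    def test_constant_expression_raises(self):
        cohort = _survival_cohort([1, 2, 3], [1, 1, 1], z=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="constant"):
            median_split(cohort, "G")


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        """times (5+, 10, 10, 15): S(10) = 1/3, S(15) = 0."""
        km = kaplan_meier([5, 10, 10, 15], [0, 1, 1, 1]).set_index("time")["survival"]
        assert km.loc[10] == pytest.approx(1 / 3)
        assert km.loc[15] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0]
        km = kaplan_meier(times, [1] * 4).set_index("time")["survival"]
        for i, t in enumerate(times):
            assert km.loc[t] == pytest.approx(1 - (i + 1) / 4)

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([3, 6, 9], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_monotone_right_continuous_from_one(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 100)
        events = rng.integers(0, 2, 100)
        km = kaplan_meier(times, events)
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
        assert km.loc[km["time"] == 0, "survival"].eq(1.0).all()

    def test_matches_textbook_product_formula(self):
        rng = np.random.default_rng(3)
        times = np.round(rng.exponential(10, 60), 1)
        events = rng.integers(0, 2, 60)
        km = kaplan_meier(times, events).set_index("time")["survival"]
        for t, s in km_product_limit_bf(times, events).items():
            assert km.loc[t] == pytest.approx(s)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [5, 10, 15, 20] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank(times, events, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_small_instance_matches_hypergeometric_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 8
            times = rng.exponential(10, n).round(1)
            events = rng.integers(0, 2, n)
            groups = np.array(["a"] * 4 + ["b"] * 4)
            if events.sum() == 0:
                continue
            res = logrank(times, events, groups)
            assert res.chi2 == pytest.approx(
                logrank_two_group_bf(times, events, groups), abs=1e-9
            )

    def test_invariant_to_monotone_time_rescaling(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 80)
        events = rng.integers(0, 2, 80)
        groups = np.repeat(["a", "b"], 40)
        a = logrank(times, events, groups)
        b = logrank(np.exp(times / 10), events, groups)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_type_i_error_within_band(self):
        """Null rejection rate at 0.05 over 2000 replicates in [0.04, 0.06]."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            times = rng.exponential(10, 60)
            events = (rng.uniform(size=60) < 0.8).astype(int)
            groups = np.repeat(["a", "b"], 30)
            res = logrank(times, events, groups)
            rejections += res.p < 0.05
        assert 0.04 <= rejections / n_rep <= 0.06

    def test_power_at_hazard_ratio_three(self):
        """HR 3 with n=200 per arm, no censoring: p<0.001 nearly always."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            t1 = rng.exponential(10, 200)
            t2 = rng.exponential(10 / 3, 200)
            res = logrank(
                np.concatenate([t1, t2]), np.ones(400), np.repeat(["a", "b"], 200)
            )
            hits += res.p < 0.001
        assert hits / n_rep >= 0.99

    def test_pairwise_tests_against_reference(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 90)
        events = np.ones(90)
        groups = np.repeat(["amp_gain", "diploid", "deletion"], 30)
        res = logrank(times, events, groups)
        assert set(res.pairwise) == {"amp_gain", "deletion"}
        assert res.df == 2


class TestUnivariateHR:
    def test_group_swap_inverts_hr(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, 200)
        x = rng.integers(0, 2, 200)
        a = univariate_hr(times, np.ones(200), x)
        b = univariate_hr(times, np.ones(200), 1 - x)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-6)

    def test_recovers_hr_two_within_ten_percent(self):
        """Simulated HR=2, n=2000, ~20% censoring."""
        rng = np.random.default_rng(10)
        x = rng.integers(0, 2, 2000)
        lam = 0.01 * np.exp(np.log(2) * x)
        event_t = rng.exponential(1 / lam)
        censor_t = rng.uniform(0, 350, 2000)
        times = np.minimum(event_t, censor_t)
        events = (event_t <= censor_t).astype(int)
        assert 0.1 < 1 - events.mean() < 0.35
        res = univariate_hr(times, events, x)
        assert abs(res.hr - 2.0) / 2.0 < 0.10
        assert res.ci_low <= res.hr <= res.ci_high

    def test_agrees_with_newton_raphson_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.integers(0, 2, 150)
            times = rng.exponential(10 * np.exp(-0.4 * x))
            res = univariate_hr(times, np.ones(150), x)
            beta, se = cox_univariate_nr(times, np.ones(150), x)
            assert np.log(res.hr) == pytest.approx(beta, abs=1e-5)
            assert (np.log(res.ci_high) - np.log(res.hr)) / 1.959963984540054 == (
                pytest.approx(se, abs=1e-5)
            )

    def test_ci_coverage_under_null(self):
        """95% CI covers HR=1 in 95% +/- 2% of 1000 null replicates.

        Uses the Newton-Raphson partial-likelihood fit (validated above
        against the package estimator) for speed.
        """
        rng = np.random.default_rng(12)
        covered = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.integers(0, 2, 150)
            times = rng.exponential(10, 150)
            beta, se = cox_univariate_nr(times, np.ones(150), x)
            covered += abs(beta) <= 1.959963984540054 * se
        assert abs(covered / n_rep - 0.95) <= 0.02


class TestCoxMultivariate:
    @staticmethod
    def _cohort(n=400, seed=0, basal_loghazard=0.0):
        from hmtscore.simulate import (
            CNASpec, ExprSpec, SimulationSpec, SurvSpec, simulate_cohort,
        )
        spec = SimulationSpec(
            n_samples=n,
            subtype_weights={"Basal": 0.3, "LuminalA": 0.7},
            cna={"G": CNASpec(probs={-2: 0.05, -1: 0.2, 0: 0.4, 1: 0.25, 2: 0.1})},
            expr={"G": ExprSpec(beta=1.0, sigma=1.0)},
            surv=SurvSpec(baseline_hazard=0.01, max_follow_up=600, coverage=1.0,
                          basal_loghazard=basal_loghazard),
            seed=seed,
        )
        return simulate_cohort(spec)

    def test_single_binary_covariate_reduces_to_univariate(self):
        cohort = self._cohort(seed=1)
        labels = median_split(cohort, "G")
        surv = cohort.clinical.loc[labels.index]
        uni = univariate_hr(
            surv["os_months"], surv["os_event"], (labels == "high").astype(int)
        )
        fit = cox_multivariate(cohort, "G", covariates=[], exposure="expr")
        assert fit.converged
        assert fit.coefficients.loc["G_high", "coef"] == pytest.approx(
            np.log(uni.hr), abs=1e-8
        )

    def test_null_covariates_rarely_exceed_three_se(self):
        total = within = 0
        for seed in range(25):
            fit = cox_multivariate(self._cohort(seed=seed), "G", exposure="cna")
            assert fit.converged
            z = (fit.coefficients["coef"].abs() / fit.coefficients["se"])
            within += int((z < 3).sum())
            total += len(z)
        assert within / total >= 0.95

    def test_recovers_basal_effect_within_fifteen_percent(self):
        # average over replicate cohorts: the basal indicator is correlated
        # with the ER/PR covariates, which inflates single-fit variance
        coefs = []
        for seed in (3, 103, 203):
            fit = cox_multivariate(self._cohort(n=2000, seed=seed, basal_loghazard=0.7),
                                   "G", exposure="cna")
            assert fit.converged
            coefs.append(fit.coefficients.loc["basal", "coef"])
        assert abs(np.mean(coefs) - 0.7) / 0.7 < 0.15

    def test_singular_design_names_collinear_columns(self):
        cohort = self._cohort(seed=4)
        cohort.clinical["tumor_size"] = cohort.clinical["node_status"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(cohort, "G", exposure="cna")

    def test_efron_agrees_with_breslow_oracle_on_tie_free_data(self):
        """With no tied event times the two tie conventions coincide."""
        rng = np.random.default_rng(13)
        x = rng.integers(0, 2, 300)
        times = rng.exponential(10 * np.exp(-0.5 * x))
        res = univariate_hr(times, np.ones(300), x)  # lifelines: Efron
        beta, _ = cox_univariate_nr(times, np.ones(300), x)  # oracle: Breslow
        # agreement limited by lifelines' own convergence tolerance
        assert np.log(res.hr) == pytest.approx(beta, abs=1e-6)


class TestAssociation:
    def test_expression_split_reports_hazard_ratio(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=300).tolist()
        lam = 0.01 * np.exp(0.8 * (np.array(z) > np.median(z)))
        times = rng.exponential(1 / lam)
        cohort = _survival_cohort(times, [1] * 300, z=z)
        assoc = survival_association(cohort, "G", "expr")
        assert assoc.analysis == "expr_split"
        assert assoc.hr is not None and assoc.hr.hr > 1
        assert set(assoc.logrank.pairwise) == {"high"}

    def test_cna_association_uses_diploid_reference(self, paper_sim):
        assoc = survival_association(paper_sim, "SMYD3", "cna")
        assert assoc.analysis == "cna_groups"
        assert "diploid" not in assoc.logrank.pairwise
        assert 0 <= assoc.logrank.min_pairwise_p <= 1
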