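"""Expression transform, DE statistics, ROC, Cox fits and risk scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from iodoscreen.recurrence_risk import (
    COVARIATE_COLUMNS,
    benjamini_hochberg,
    build_risk_model,
    cox_univariate,
    differential_expression,
    fisher_exact_2x2,
    log2p1,
    multivariate_adjusted,
    optimal_cutpoint,
    roc_curve_auc,
    stratify_by_risk,
)
from iodoscreen.synthetic_data import CohortSimSpec, simulate_cohort

from _naive import (
    naive_breslow_loglik,
    naive_concordance,
    naive_fisher_two_sided,
    naive_youden_best_j,
)


class TestLog2p1:
    @pytest.mark.parametrize("x,expected", [(0, 0.0), (1, 1.0), (3, 2.0)])
    def test_values(self, x, expected):
        assert log2p1(x) == pytest.approx(expected)

    def test_negative_rejected_and_frames_preserved(self):
        with pytest.raises(ValueError):
            log2p1(np.array([-1.0]))
        df = pd.DataFrame({"g": [0.0, 3.0]})
        out = log2p1(df)
        assert list(out.columns) == ["g"] and out["g"].tolist() == [0.0, 2.0]


class TestBenjaminiHochberg:
    def test_worked_step_up_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30))
    def test_permutation_invariant_per_test(self, pvals):
        p = np.array(pvals)
        q = benjamini_hochberg(p)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = benjamini_hochberg(p[perm])
        assert q_perm == pytest.approx(q[perm])
        assert np.all((0 <= q) & (q <= 1))


class TestDifferentialExpression:
    def _frame(self, arr, genes):
        return pd.DataFrame(arr, columns=genes)

    def test_identical_groups_have_zero_log2fc(self):
        rng = np.random.default_rng(0)
        a = self._frame(rng.lognormal(1, 1, (10, 4)), list("abcd"))
        res = differential_expression(a, a.copy())
        assert res["log2fc"].abs().max() == 0.0

    def test_constant_gene_p_is_one(self):
        a = self._frame(np.ones((5, 1)), ["g"])
        res = differential_expression(a, a.copy())
        assert res.loc[0, "p"] == 1.0

    def test_detects_shifted_genes_controls_false_positives(self):
        """10/100 genes shifted by +1 on the transformed scale, n=50/arm:
        most shifted genes reach q<0.05 and few nulls do (median, 10 seeds)."""
        hits_true, hits_false = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(100)]
            xa = rng.normal(3.0, 1.0, (50, 100))
            xb = rng.normal(3.0, 1.0, (50, 100))
            xa[:, :10] += 1.0
            a = self._frame(xa, genes)
            b = self._frame(xb, genes)
            res = differential_expression(a, b,
                                          already_transformed=True).set_index("gene")
            sig = set(res[res["q"] < 0.05].index)
            hits_true.append(len(sig & set(genes[:10])))
            hits_false.append(len(sig - set(genes[:10])))
        assert np.median(hits_true) >= 8
        assert np.median(hits_false) <= 2


class TestFisherExact:
    def test_diagonal_table_enumeration_value(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(1 / 126, rel=1e-9)

    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[3, 3], [3, 3]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        _, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            t = rng.integers(0, 10, (2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(naive_fisher_two_sided(t), abs=1e-12)


class TestRocAndCutpoint:
    def test_perfect_separation_auc_one(self):
        *_, auc = roc_curve_auc([1, 2, 3, 10, 11, 12],
                                [False, False, False, True, True, True])
        assert auc == 1.0

    def test_auc_equals_all_pairs_concordance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            score = rng.integers(0, 20, n).astype(float)  # force ties
            label = rng.random(n) < 0.4
            if label.all() or not label.any():
                continue
            *_, auc = roc_curve_auc(score, label)
            assert auc == pytest.approx(naive_concordance(score, label), abs=1e-12)

    def test_independent_score_auc_near_half(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=5000)
        label = rng.random(5000) < 0.5
        *_, auc = roc_curve_auc(score, label)
        assert abs(auc - 0.5) < 0.05

    def test_cutpoint_perfect_separation_lies_between_groups(self):
        score = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        label = [False, False, False, True, True, True]
        t = optimal_cutpoint(score, label)
        assert 3.0 < t < 10.0

    def test_cutpoint_attains_exhaustive_scan_maximum(self):
        score = [0.1, 0.4, 0.35, 0.8, 0.7, 0.7, 0.2, 0.9]
        label = [False, False, True, True, False, True, False, True]
        t = optimal_cutpoint(score, label)
        s, y = np.array(score), np.array(label)
        pred = s > t
        j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
        assert j == pytest.approx(naive_youden_best_j(score, label))

    def test_shuffled_labels_give_small_j(self):
        rng = np.random.default_rng(42)
        js = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            score = r.normal(size=200)
            label = r.permutation([True] * 100 + [False] * 100)
            t = optimal_cutpoint(score, label)
            pred = score > t
            j = (pred & label).sum() / 100 + (~pred & ~label).sum() / 100 - 1
            js.append(j)
        assert np.median(js) < 0.25

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 2], [True, True])
        with pytest.raises(ValueError):
            optimal_cutpoint([1, 2], [False, False])


class TestCoxUnivariate:
    def test_symmetric_groups_give_unit_hazard_ratio(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [True] * 8
        group = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = cox_univariate(group, time, event)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_breslow_maximization(self):
        """Six-subject dataset: PHReg equals direct maximization of the
        naive Breslow partial likelihood."""
        time = [2.0, 3.0, 3.0, 5.0, 7.0, 9.0]
        event = [True, True, False, True, True, False]
        x = [0.0, 1.0, 1.0, 0.0, 1.0, 0.0]
        fit = cox_univariate(x, time, event, ties="breslow")
        res = minimize_scalar(lambda b: -naive_breslow_loglik(b, x, time, event),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(0)
        n = 1000
        group = rng.random(n) < 0.5
        t = rng.exponential(1.0 / np.where(group, 0.2, 0.1))
        c = rng.exponential(10.0, n)
        time, event = np.minimum(t, c), t <= c
        fit = cox_univariate(group.astype(float), time, event)
        assert abs(fit.beta[0] - np.log(2)) < 0.15
        assert fit.ci_low[0] < 2.0 < fit.ci_high[0]

    def test_complete_separation_flagged(self):
        # all events in one group, orders of magnitude apart
        time = [0.1, 0.2, 0.3, 10.0, 11.0, 12.0]
        event = [True, True, True, True, True, True]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        fit = cox_univariate(x, time, event)
        assert (not fit.converged) or abs(fit.beta[0]) > 3


class TestRiskModel:
    def test_forced_beta_score_is_linear_form(self):
        cohort, _ = simulate_cohort(CohortSimSpec(n_patients=50, seed=0))
        genes = CohortSimSpec().genes
        model = build_risk_model(cohort, genes,
                                 forced_beta={"GENE_01": 1.0})
        expected = log2p1(cohort["GENE_01"])
        assert model.scores(cohort).to_numpy() == pytest.approx(
            expected.to_numpy())

    def test_score_invariant_to_gene_ordering(self):
        spec = CohortSimSpec(n_patients=300, seed=1)
        cohort, _ = simulate_cohort(spec)
        m1 = build_risk_model(cohort, spec.genes)
        m2 = build_risk_model(cohort, spec.genes[::-1])
        assert m1.scores(cohort).to_numpy() == pytest.approx(
            m2.scores(cohort).to_numpy(), rel=1e-6)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-12)

    def test_permuted_events_give_null_auc(self):
        aucs = []
        for seed in range(5):
            spec = CohortSimSpec(n_patients=400, seed=seed)
            cohort, _ = simulate_cohort(spec)
            rng = np.random.default_rng(seed)
            cohort["event"] = rng.permutation(cohort["event"].to_numpy())
            model = build_risk_model(cohort, spec.genes)
            aucs.append(model.auc)
        assert abs(np.median(aucs) - 0.5) < 0.07


class TestStratifyByRisk:
    def _fitted(self, seed=0, n=600):
        spec = CohortSimSpec(n_patients=n, seed=seed)
        cohort, _ = simulate_cohort(spec)
        return cohort, build_risk_model(cohort, spec.genes)

    def test_km_curves_start_at_one(self):
        cohort, model = self._fitted()
        strat = stratify_by_risk(model, cohort)
        for curve in strat.km_curves.values():
            assert curve.iloc[0, 0] == pytest.approx(1.0)

    def test_identical_groups_null_logrank(self):
        """Duplicating the cohort into both groups: HR 1, log-rank p ~ 1."""
        cohort, _ = self._fitted(seed=3, n=200)
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        forced = pd.Series(np.r_[np.ones(len(cohort)), np.zeros(len(cohort))])
        fit = cox_univariate(forced, doubled["time"], doubled["event"])
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)

    def test_tripled_hazard_recovered(self):
        """A group carrying 3x the hazard is recovered by the stratified HR
        with a decisive log-rank test at n=600."""
        hrs, ps = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 600
            high = rng.random(n) < 0.5
            t = rng.exponential(1.0 / np.where(high, 0.3, 0.1))
            c = rng.exponential(10.0, n)
            cohort = pd.DataFrame({
                "MARKER": np.where(high, 10.0, 0.0),
                "time": np.minimum(t, c),
                "event": t <= c,
            })
            model = build_risk_model(cohort, ["MARKER"],
                                     forced_beta={"MARKER": 1.0})
            model.group_cutoff = float(log2p1(5.0))  # between the two levels
            strat = stratify_by_risk(model, cohort)
            hrs.append(strat.hazard_ratio)
            ps.append(strat.logrank_p)
        assert 2.0 < np.median(hrs) < 4.5
        assert np.median(ps) < 0.01

    def test_percentile_mode_drops_middle_tertile(self):
        cohort, model = self._fitted(seed=5)
        strat = stratify_by_risk(model, cohort, mode="percentile")
        assert len(strat.groups) < len(cohort)


class TestMultivariateAdjusted:
    def _cohort(self, seed=0, n=600):
        spec = CohortSimSpec(n_patients=n, seed=seed)
        cohort, _ = simulate_cohort(spec)
        model = build_risk_model(cohort, spec.genes)
        group = (model.scores(cohort) > model.group_cutoff).astype(float)
        return cohort, group

    def test_causal_score_stays_significant_null_covariates_do_not(self):
        sig_score, sig_cov = [], []
        for seed in range(5):
            cohort, group = self._cohort(seed)
            fit = multivariate_adjusted(group, cohort[COVARIATE_COLUMNS],
                                        cohort["time"], cohort["event"])
            sig_score.append(fit["risk_high"]["p"] < 0.05)
            others = [t for t in fit.terms if t != "risk_high"]
            sig_cov.append(np.mean([fit[t]["p"] < 0.05 for t in others]))
        assert np.median(sig_score) == 1.0
        assert np.median(sig_cov) < 0.5

    def test_permuted_score_ci_covers_one(self):
        covered = []
        for seed in range(10):
            cohort, group = self._cohort(seed, n=400)
            rng = np.random.default_rng(seed)
            permuted = pd.Series(rng.permutation(group.to_numpy()),
                                 index=group.index)
            fit = multivariate_adjusted(permuted, cohort[COVARIATE_COLUMNS],
                                        cohort["time"], cohort["event"])
            t = fit["risk_high"]
            covered.append(t["ci_low"] <= 1.0 <= t["ci_high"])
        assert np.mean(covered) >= 0.9

    def test_duplicated_covariate_dropped_fit_unchanged(self):
        cohort, group = self._cohort(seed=2)
        cov = cohort[COVARIATE_COLUMNS]
        fit1 = multivariate_adjusted(group, cov, cohort["time"], cohort["event"])
        cov2 = cov.copy()
        cov2["age_copy"] = cov2["age"]
        fit2 = multivariate_adjusted(group, cov2, cohort["time"], cohort["event"])
        assert "age_copy" not in fit2.terms
        assert fit2.beta == pytest.approx(fit1.beta, rel=1e-8)
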