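import numpy as np
import pandas as pd
import pytest

from lncpairsig import (
    ValidationError,
    compare_roc_features,
    encode_clinical,
    kaplan_meier,
    logrank_test,
    multivariate_cox,
    optimal_cutoff,
    stratify,
    survival_roc,
    univariate_cox_screen,
)
from lncpairsig.evaluate import ROCCurve
from lncpairsig.pairs import PairMatrix


def pairwise_concordance_auc(scores, labels):
    """Brute-force binary AUC: P(score_case > score_control) + 0.5 P(equal)."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    num = 0.0
    for c in cases:
        for d in controls:
            num += 1.0 if c > d else (0.5 if c == d else 0.0)
    return num / (len(cases) * len(controls))


class TestSurvivalROC:
    def test_perfect_separation_auc_one(self, surv_from_arrays):
        times = [10.0, 20.0, 400.0, 500.0]
        surv = surv_from_arrays(times, [1, 1, 0, 0])
        scores = pd.Series([5.0, 4.0, 1.0, 2.0], index=surv.sample_ids)
        roc = survival_roc(scores, surv, horizon=365)
        assert roc.auc == pytest.approx(1.0)
        assert roc.sens[0] == 0.0 and roc.spec[0] == 1.0  # (0, 1) endpoint
        assert roc.sens[-1] == 1.0 and roc.spec[-1] == 0.0  # (1, 0) endpoint

    def test_reduces_to_binary_roc_without_censoring(self, surv_from_arrays):
        rng = np.random.default_rng(7)
        n = 30
        times = rng.exponential(300, n)
        surv = surv_from_arrays(times, np.ones(n, dtype=int))
        scores = pd.Series(np.round(rng.normal(size=n), 1), index=surv.sample_ids)
        roc = survival_roc(scores, surv, horizon=250.0)
        labels = times <= 250.0
        assert roc.auc == pytest.approx(pairwise_concordance_auc(scores.to_numpy(), labels), abs=1e-12)

    def test_sensitivity_monotone_as_threshold_decreases(self, cohort):
        scores = pd.Series(
            np.random.default_rng(1).normal(size=len(cohort.clinical.sample_ids)),
            index=cohort.clinical.sample_ids,
        )
        roc = survival_roc(scores, cohort.clinical, horizon=365)
        assert (np.diff(roc.sens) >= -1e-12).all()
        assert 0.0 <= roc.auc <= 1.0

    def test_auc_invariant_under_increasing_score_transform(self, cohort):
        scores = pd.Series(
            np.random.default_rng(2).lognormal(size=len(cohort.clinical.sample_ids)),
            index=cohort.clinical.sample_ids,
        )
        a = survival_roc(scores, cohort.clinical, horizon=365)
        b = survival_roc(np.exp(scores / 3.0), cohort.clinical, horizon=365)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.sens, b.sens)
        np.testing.assert_array_equal(a.spec, b.spec)

    def test_reversed_scores_flip_auc(self, surv_from_arrays):
        rng = np.random.default_rng(9)
        n = 40
        times = rng.exponential(300, n)
        surv = surv_from_arrays(times, np.ones(n, dtype=int))
        scores = pd.Series(rng.normal(size=n), index=surv.sample_ids)
        a = survival_roc(scores, surv, horizon=200.0)
        b = survival_roc(-scores, surv, horizon=200.0)
        assert a.auc + b.auc == pytest.approx(1.0, abs=1e-12)

    def test_no_events_by_horizon_rejected(self, surv_from_arrays):
        surv = surv_from_arrays([400.0, 500.0], [1, 1])
        scores = pd.Series([1.0, 2.0], index=surv.sample_ids)
        with pytest.raises(ValidationError, match="no events by horizon"):
            survival_roc(scores, surv, horizon=100.0)


class TestOptimalCutoff:
    def test_matches_exhaustive_enumeration(self, surv_from_arrays):
        times = [50.0, 60.0, 400.0, 70.0, 500.0, 600.0]
        events = [1, 1, 0, 1, 0, 0]
        surv = surv_from_arrays(times, events)
        scores = pd.Series([3.0, 1.0, 2.0, 4.0, 0.5, 1.5], index=surv.sample_ids)
        roc = survival_roc(scores, surv, horizon=365)
        best = optimal_cutoff(roc)
        finite = np.isfinite(roc.thresholds)
        j = roc.sens + roc.spec - 1.0
        enumerated = {t: jj for t, jj in zip(roc.thresholds[finite], j[finite])}
        assert enumerated[best] == pytest.approx(max(enumerated.values()))

    def test_perfect_separation_ties_resolve_to_larger_threshold(self):
        roc = ROCCurve(
            horizon=365.0,
            thresholds=np.array([np.inf, 3.0, 2.0, 1.0, -np.inf]),
            sens=np.array([0.0, 1.0, 1.0, 1.0, 1.0]),
            spec=np.array([1.0, 1.0, 1.0, 0.0, 0.0]),
            auc=1.0,
        )
        assert optimal_cutoff(roc) == 3.0

    def test_uninformative_scores_warn(self, surv_from_arrays, caplog):
        times = [100.0, 400.0, 150.0, 500.0]
        surv = surv_from_arrays(times, [1, 0, 1, 0])
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=surv.sample_ids)
        roc = survival_roc(scores, surv, horizon=365)
        import logging

        with caplog.at_level(logging.WARNING, logger="lncpairsig"):
            optimal_cutoff(roc)
        assert any("uninformative" in rec.message for rec in caplog.records)


class TestStratify:
    def test_published_cutoff_example(self):
        scores = pd.Series([0.8, 1.0, 2.0], index=["S1", "S2", "S3"])
        strat = stratify(scores, 1.395)
        assert strat.labels.tolist() == ["low", "low", "high"]

    def test_score_equal_to_cutoff_is_low(self):
        scores = pd.Series([1.395, 2.0], index=["S1", "S2"])
        strat = stratify(scores, 1.395)
        assert strat.labels["S1"] == "low"

    def test_empty_group_rejected(self):
        scores = pd.Series([2.0, 3.0], index=["S1", "S2"])
        with pytest.raises(ValidationError, match="empty group"):
            stratify(scores, 1.0)


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self, surv_from_arrays):
        km = kaplan_meier(surv_from_arrays([10.0, 20.0, 30.0], [0, 0, 0]))
        assert km.times.size == 0  # no steps anywhere: S(t) = 1

    def test_no_censoring_reduces_to_ecdf(self, surv_from_arrays):
        km = kaplan_meier(surv_from_arrays([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_classic_censored_fixture_matches_product_limit(self, surv_from_arrays):
        """times (6,6,6,7,10+,13,16+): hand product of (1 - d/n) terms."""
        surv = surv_from_arrays([6, 6, 6, 7, 10, 13, 16], [1, 1, 1, 1, 0, 1, 0])
        km = kaplan_meier(surv)
        np.testing.assert_array_equal(km.times, [6.0, 7.0, 13.0])
        np.testing.assert_allclose(km.survival, [4 / 7, 3 / 7, 3 / 14])
        np.testing.assert_array_equal(km.at_risk, [7, 4, 2])
        np.testing.assert_array_equal(km.events, [3, 1, 1])


class TestLogrank:
    def _strat(self, surv, labels):
        scores = pd.Series(
            [2.0 if lab == "high" else 0.5 for lab in labels], index=surv.sample_ids
        )
        return stratify(scores, 1.0)

    def test_identical_groups_give_zero_statistic(self, surv_from_arrays):
        times = [5.0, 8.0, 13.0, 21.0] * 2
        events = [1, 0, 1, 1] * 2
        surv = surv_from_arrays(times, events)
        labels = ["high"] * 4 + ["low"] * 4
        chi2, p = logrank_test(self._strat(surv, labels), surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_leaves_chi2_unchanged(self, surv_from_arrays):
        rng = np.random.default_rng(3)
        times = rng.exponential(100, 12)
        events = rng.integers(0, 2, 12)
        events[:2] = 1
        surv = surv_from_arrays(times, events)
        labels = ["high"] * 5 + ["low"] * 7
        swapped = ["low" if l == "high" else "high" for l in labels]
        a, _ = logrank_test(self._strat(surv, labels), surv)
        b, _ = logrank_test(self._strat(surv, swapped), surv)
        assert a == pytest.approx(b, abs=1e-12)

    def test_terms_match_hypergeometric_enumeration(self, surv_from_arrays):
        """10-sample toy with ties and censoring: chi2 = (sum O-E)^2 / sum V."""
        times = [3.0, 3.0, 5.0, 5.0, 7.0, 9.0, 9.0, 11.0, 13.0, 15.0]
        events = [1, 1, 1, 0, 1, 1, 1, 0, 1, 0]
        grp1 = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 0])  # high-risk membership
        o_minus_e = 0.0
        var = 0.0
        t_arr, e_arr = np.array(times), np.array(events)
        for t in sorted(set(t_arr[e_arr == 1])):
            at_risk = t_arr >= t
            n = at_risk.sum()
            n1 = grp1[at_risk].sum()
            d = ((t_arr == t) & (e_arr == 1)).sum()
            d1 = ((t_arr == t) & (e_arr == 1) & (grp1 == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2_oracle = o_minus_e**2 / var
        surv = surv_from_arrays(times, events)
        labels = ["high" if g else "low" for g in grp1]
        chi2, p = logrank_test(self._strat(surv, labels), surv)
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-10)
        assert 0.0 <= p <= 1.0

    def test_time_rescaling_invariance(self, surv_from_arrays):
        rng = np.random.default_rng(4)
        times = rng.exponential(100, 16)
        events = np.ones(16, dtype=int)
        labels = ["high"] * 8 + ["low"] * 8
        a, _ = logrank_test(
            self._strat(surv_from_arrays(times, events), labels),
            surv_from_arrays(times, events),
        )
        b, _ = logrank_test(
            self._strat(surv_from_arrays(times * 3.7, events), labels),
            surv_from_arrays(times * 3.7, events),
        )
        assert a == pytest.approx(b, abs=1e-10)


class TestMultivariateCox:
    def test_single_term_reproduces_univariate_screen(self, cohort):
        clin = cohort.clinical
        vals = cohort.expr.values[clin.sample_ids]
        x = (vals.loc["LNC0001"] > vals.loc["LNC0002"]).astype(int)
        pm = PairMatrix(pd.DataFrame({"LNC0001|LNC0002": x}).T)
        uni = univariate_cox_screen(pm, clin)[0]
        multi = multivariate_cox(clin, pd.DataFrame({"LNC0001|LNC0002": x.astype(float)}))[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-8)
        assert multi.p == pytest.approx(uni.p, abs=1e-8)

    def test_duplicated_covariate_raises_collinearity(self, cohort):
        clin = cohort.clinical
        enc = encode_clinical(clin)
        enc["age_copy"] = enc["age"]
        with pytest.raises(ValidationError, match="collinear.*age_copy"):
            multivariate_cox(clin, enc)

    def test_joint_fit_reports_each_term(self, cohort):
        clin = cohort.clinical
        enc = encode_clinical(clin)
        fits = multivariate_cox(clin, enc)
        assert [f.term for f in fits] == list(enc.columns)
        for f in fits:
            assert f.ci_low <= f.hr <= f.ci_high
            assert np.isclose(f.hr, np.exp(f.beta))


class TestCompareROCFeatures:
    def test_identity_feature_ties_risk_score(self, cohort):
        clin = cohort.clinical
        scores = pd.Series(
            np.random.default_rng(5).lognormal(size=len(clin.sample_ids)),
            index=clin.sample_ids,
        )
        feats = pd.DataFrame({"risk_score": scores, "copy": scores})
        table = compare_roc_features(clin, feats, horizon=365)
        assert table.loc["risk_score", "auc"] == table.loc["copy", "auc"]

    def test_sign_reversal_flips_auc(self, surv_from_arrays):
        rng = np.random.default_rng(6)
        times = rng.exponential(300, 50)
        surv = surv_from_arrays(times, np.ones(50, dtype=int))
        f = pd.Series(rng.normal(size=50), index=surv.sample_ids)
        table = compare_roc_features(surv, pd.DataFrame({"f": f, "neg_f": -f}), horizon=200)
        assert table.loc["f", "auc"] + table.loc["neg_f", "auc"] == pytest.approx(1.0, abs=1e-12)

    def test_sorted_descending(self, cohort):
        clin = cohort.clinical
        scores = pd.Series(
            np.random.default_rng(8).normal(size=len(clin.sample_ids)), index=clin.sample_ids
        )
        feats = encode_clinical(clin)
        feats.insert(0, "risk_score", scores)
        table = compare_roc_features(clin, feats, horizon=365)
        assert (table["auc"].diff().dropna() <= 1e-12).all()


def test_encode_clinical_codes(cohort):
    enc = encode_clinical(cohort.clinical)
    raw = cohort.clinical.data
    assert set(enc.columns) == {"age", "sex", "grade", "stage"}
    assert (enc.loc[raw["sex"] == "male", "sex"] == 1).all()
    assert (enc.loc[raw["grade"] == "G3", "grade"] == 3).all()
    assert (enc.loc[raw["stage"] == "IV", "stage"] == 4).all()
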