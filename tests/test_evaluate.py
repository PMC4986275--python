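"""Unit and oracle tests for model evaluation: KM, log-rank, stratification,
IPCW concordance, explained variation, permutation control."""

import numpy as np
import pandas as pd
import pytest

from musico.coxph import SurvivalOutcome
from musico.evaluate import (
    added_value_p,
    compare_models,
    concordance_ipw,
    evaluate_model,
    explained_variation,
    global_p,
    km_estimate,
    logrank_test,
    permute_gene_block,
    stratify_risk,
)

from conftest import make_outcome


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        out = make_outcome([1, 2, 3], [1, 1, 1])
        km = km_estimate(out)
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_product_limit_by_hand(self):
        # times 1 (event), 2 (censored), 3 (event): S(1) = 2/3, then the
        # risk set at t=3 is the single remaining subject, so S(3) = 0,
        # with S constant on [1, 3)
        out = make_outcome([1, 2, 3], [1, 0, 1])
        km = km_estimate(out)
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2.9) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        out = make_outcome([5, 8, 13], [0, 0, 0])
        km = km_estimate(out)
        assert km.at(100.0) == 1.0

    def test_monotone_non_increasing(self, rng):
        out = make_outcome(
            rng.exponential(10, 50) + 0.1, (rng.uniform(size=50) < 0.6).astype(int)
        )
        km = km_estimate(out)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.at(0.0) == 1.0


def logrank_reference(time, event, groups):
    """Hand risk-set tabulation of the two-group log-rank statistic."""
    time, event, groups = map(np.asarray, (time, event, groups))
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        out = make_outcome([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        chi2, df, p = logrank_test(out, ["a", "a", "a", "b", "b", "b"])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        out = make_outcome([1, 3, 5, 2, 4, 6], [1, 1, 1, 1, 1, 1])
        groups = ["A", "A", "A", "B", "B", "B"]
        chi2, _, _ = logrank_test(out, groups)
        expected = logrank_reference(out.time, out.event, groups)
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_matches_hand_tabulation_censored(self, rng):
        out = make_outcome(
            rng.exponential(10, 40) + 0.1, (rng.uniform(size=40) < 0.7).astype(int)
        )
        groups = np.where(rng.uniform(size=40) < 0.5, "A", "B")
        chi2, _, _ = logrank_test(out, groups)
        assert chi2 == pytest.approx(
            logrank_reference(out.time, out.event, groups), abs=1e-10
        )

    def test_single_group_rejected(self):
        out = make_outcome([1, 2], [1, 1])
        with pytest.raises(ValueError, match="two"):
            logrank_test(out, ["a", "a"])


class TestStratifyRisk:
    def test_cohort_quartile_sizes_186(self, rng):
        groups = stratify_risk(pd.Series(rng.normal(size=186)))
        counts = groups.value_counts()
        assert counts["low"] == 46 and counts["high"] == 46
        assert counts["intermediate"] == 94

    def test_small_n_floor(self, rng):
        groups = stratify_risk(pd.Series(rng.normal(size=8)))
        counts = groups.value_counts()
        assert counts["low"] == 2 and counts["high"] == 2 and counts["intermediate"] == 4

    def test_monotone_relabelling_invariance(self, rng):
        eta = pd.Series(rng.normal(size=50))
        g1 = stratify_risk(eta)
        g2 = stratify_risk(np.exp(3 * eta) + 7)
        assert (g1 == g2).all()

    def test_low_group_has_lowest_predictors(self, rng):
        eta = pd.Series(rng.normal(size=40))
        groups = stratify_risk(eta)
        assert eta[groups == "low"].max() <= eta[groups == "intermediate"].min()
        assert eta[groups == "intermediate"].max() <= eta[groups == "high"].min()

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="discrimination"):
            stratify_risk(pd.Series(np.ones(10)))

    def test_ties_warn(self):
        with pytest.warns(UserWarning, match="ties"):
            stratify_risk(pd.Series([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]))


def harrell_reference(eta, time, event):
    """All-pairs Harrell concordance (uncensored oracle)."""
    num = den = 0.0
    n = len(eta)
    for i in range(n):
        for j in range(n):
            if event[i] == 1 and time[i] < time[j]:
                den += 1
                if eta[i] > eta[j]:
                    num += 1
                elif eta[i] == eta[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_predictor(self):
        out = make_outcome([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_ipw(-out.time, out) == pytest.approx(1.0)

    def test_all_pairs_oracle_uncensored(self, rng):
        out = make_outcome(rng.exponential(5, 25) + 0.1, np.ones(25, int))
        eta = rng.normal(size=25)
        assert concordance_ipw(eta, out) == pytest.approx(
            harrell_reference(eta, out.time, out.event), abs=1e-12
        )

    def test_agrees_with_sksurv_ipcw(self, rng):
        from sksurv.metrics import concordance_index_ipcw
        from sksurv.util import Surv

        n = 80
        time = rng.exponential(10, n) + 0.1
        event = (rng.uniform(size=n) < 0.7).astype(int)
        out = make_outcome(time, event)
        eta = rng.normal(size=n)
        y = Surv.from_arrays(event.astype(bool), time)
        # default truncation (all events usable) matches sksurv without tau
        expected = concordance_index_ipcw(y, y, eta)[0]
        assert concordance_ipw(eta, out) == pytest.approx(expected, abs=1e-10)
        # explicit (strict) truncation matches sksurv with the same tau
        tau = float(np.median(time))
        expected_tau = concordance_index_ipcw(y, y, eta, tau=tau)[0]
        assert concordance_ipw(eta, out, tau=tau) == pytest.approx(
            expected_tau, abs=1e-10
        )

    def test_independent_predictor_near_half(self):
        rng = np.random.default_rng(0)
        cs = []
        for _ in range(10):
            n = 400
            time = rng.exponential(10, n) + 0.1
            event = (rng.uniform(size=n) < 0.7).astype(int)
            cs.append(concordance_ipw(rng.normal(size=n), make_outcome(time, event)))
        assert np.mean(cs) == pytest.approx(0.5, abs=0.02)


def pev_reference(eta, time, event):
    """Independent straight-line transcription of the explained-variation
    estimator (uncensored case): KM vs Cox-model status prediction errors
    averaged at event times, weighted by event counts."""
    from scipy.optimize import brentq

    time, event = np.asarray(time, float), np.asarray(event, int)
    eta = np.asarray(eta, float)
    etac = eta - eta.mean()

    def score(b):
        s = 0.0
        for t in np.unique(time[event == 1]):
            rs = time >= t
            eh = (time == t) & (event == 1)
            w = np.exp(b * etac[rs])
            s += etac[eh].sum() - eh.sum() * (w * etac[rs]).sum() / w.sum()
        return s

    beta = brentq(score, -20, 20, xtol=1e-14)
    risk = np.exp(beta * etac)
    uniq = np.unique(time[event == 1])
    # Breslow baseline hazard and subject curves
    H0 = []
    h = 0.0
    for t in uniq:
        h += ((time == t) & (event == 1)).sum() / risk[time >= t].sum()
        H0.append(h)
    H0 = np.array(H0)
    S_cox = np.exp(-np.outer(risk, H0))
    # marginal KM
    S_km = []
    s = 1.0
    for t in uniq:
        n_at = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n_at
        S_km.append(s)
    S_km = np.array(S_km)

    def mae(S_mat):
        out = []
        for k, t in enumerate(uniq):
            contrib = np.where(time > t, 1 - S_mat[:, k], S_mat[:, k])
            out.append(contrib.mean())
        return np.array(out)

    w = np.array([((time == t) & (event == 1)).sum() for t in uniq], float)
    d0 = (w * mae(np.tile(S_km, (len(time), 1)))).sum() / w.sum()
    de = (w * mae(S_cox)).sum() / w.sum()
    return 100.0 * (d0 - de) / d0


class TestExplainedVariation:
    def test_constant_predictor_zero(self):
        out = make_outcome([1, 2, 3, 4, 5], [1, 1, 1, 0, 1])
        assert explained_variation(np.ones(5), out) == 0.0

    def test_five_subject_uncensored_oracle(self):
        time = np.array([2.0, 4.0, 5.0, 7.0, 11.0])
        event = np.ones(5, int)
        eta = np.array([0.9, 0.1, 0.5, -0.6, -1.1])
        out = make_outcome(time, event)
        assert explained_variation(eta, out) == pytest.approx(
            pev_reference(eta, time, event), abs=1e-8
        )

    def test_larger_uncensored_oracle(self, rng):
        n = 30
        time = rng.exponential(10, n) + 0.1
        eta = -0.8 * np.log(time) + rng.normal(size=n)
        out = make_outcome(time, np.ones(n, int))
        assert explained_variation(eta, out) == pytest.approx(
            pev_reference(eta, time, np.ones(n, int)), abs=1e-8
        )

    def test_affine_transform_invariance(self, rng):
        n = 40
        time = rng.exponential(10, n) + 0.1
        event = (rng.uniform(size=n) < 0.75).astype(int)
        eta = rng.normal(size=n)
        out = make_outcome(time, event)
        p0 = explained_variation(eta, out)
        p1 = explained_variation(3.0 * eta - 5.0, out)
        assert p0 == pytest.approx(p1, abs=1e-6)

    def test_informative_predictor_beats_noise(self, rng):
        n = 200
        lp = rng.normal(size=n)
        time = np.maximum(rng.exponential(np.exp(-lp) * 10), 1e-3)
        out = make_outcome(time, np.ones(n, int))
        assert explained_variation(lp, out) > explained_variation(
            rng.normal(size=n), out
        ) + 1.0


class TestGlobalAndAddedValue:
    def test_global_p_is_univariate_wald(self, rng):
        n = 100
        eta = rng.normal(size=n)
        out = make_outcome(rng.exponential(10, n) + 0.1, np.ones(n, int))
        from musico.coxph import fit_univariate_cox

        assert global_p(eta, out) == fit_univariate_cox(eta, out).p

    def test_added_value_detects_independent_signal(self, rng):
        n = 300
        clin = rng.normal(size=n)
        gene = rng.normal(size=n)
        lp = 0.5 * clin + 0.8 * gene
        time = np.maximum(rng.exponential(np.exp(-lp) * 10), 1e-3)
        out = make_outcome(time, np.ones(n, int))
        assert added_value_p(clin, gene, out) < 0.01

    def test_collinear_rejected(self, rng):
        eta = rng.normal(size=50)
        out = make_outcome(rng.exponential(10, 50) + 0.1, np.ones(50, int))
        with pytest.raises(ValueError, match="collinear"):
            added_value_p(eta, eta * 2 + 1, out)

    def test_constant_gene_predictor_rejected(self, rng):
        eta = rng.normal(size=50)
        out = make_outcome(rng.exponential(10, 50) + 0.1, np.ones(50, int))
        with pytest.raises(ValueError, match="constant"):
            added_value_p(eta, np.ones(50), out)


class TestPermutationInvariants:
    def test_block_shuffle_preserves_marginals_and_correlation(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        perm = permute_gene_block(X, np.random.default_rng(1))
        for c in X.columns:
            np.testing.assert_array_equal(
                np.sort(X[c].to_numpy()), np.sort(perm[c].to_numpy())
            )
        np.testing.assert_allclose(X.corr(), perm.corr(), atol=1e-12)
        assert not np.allclose(X.to_numpy(), perm.to_numpy())


class TestCompareModels:
    def _report(self, label, available=True, pev=5.0):
        from musico.evaluate import ModelReport

        return ModelReport(
            label=label,
            endpoint="OS",
            penalty="ridge",
            available=available,
            pev=pev,
            c_index=0.6,
            global_p=0.01,
            risk_groups=pd.Series(["low"] * 2 + ["intermediate"] * 4 + ["high"] * 2)
            if available
            else None,
        )

    def test_identical_reports_identical_rows(self):
        table = compare_models([self._report("A"), self._report("B")])
        assert table.loc[0, "PEV_pct"] == table.loc[1, "PEV_pct"]

    def test_unavailable_renders_na(self):
        table = compare_models(
            [self._report("Clinics"), self._report("AID/APOBEC", available=False)]
        )
        row = table.set_index("model").loc["AID/APOBEC"]
        assert (row[["PEV_pct", "c_index", "p"]] == "n.a.").all()

    def test_needs_two_reports(self):
        with pytest.raises(ValueError, match="two"):
            compare_models([self._report("A")])
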