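"""Cox fitting, LRT, concordance: oracle checks and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from conftest import random_survival
from coxradius.errors import DataError, UsageError
from coxradius.survival import (
    CoxFit,
    clinical_design,
    concordance_index,
    fit_cox,
    likelihood_ratio_test,
    null_loglik,
    standard_dose_metric_screen,
)


def breslow_loglik(beta, x, time, event):
    """Independent partial-likelihood oracle (no ties)."""
    eta = x * beta
    ll = 0.0
    for i in np.nonzero(event)[0]:
        risk = time >= time[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


def brute_force_concordance(risk, time, event):
    """Pair-enumeration oracle for Harrell's C."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (event[i] and time[i] < time[j]) or (
                event[i] and not event[j] and time[i] == time[j]
            )
            if not comparable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


class TestFitCox:
    def test_label_swap_symmetry_forces_zero(self):
        # two groups with mirrored outcome patterns: HR must be 1
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_cox(x[:, None], time, event)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)

    def test_six_subject_grid_search_oracle(self):
        time = np.array([1.0, 2.5, 3.0, 4.5, 6.0, 7.5])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        fit = fit_cox(x[:, None], time, event)
        res = minimize_scalar(
            lambda b: -breslow_loglik(b, x, time, event), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-8},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_null_loglik_closed_form(self, rng):
        _, time, event = random_survival(rng, 30)
        expected = 0.0
        for i in np.nonzero(event)[0]:
            expected -= np.log(np.sum(time >= time[i]))
        assert null_loglik(time, event) == pytest.approx(expected, abs=1e-10)

    def test_constant_column_reported(self, rng):
        X, time, event = random_survival(rng, 20)
        X[:, 1] = 3.0
        with pytest.raises(DataError, match="constant"):
            fit_cox(X, time, event, terms=("a", "b"))

    def test_separation_flagged_not_raised(self):
        # covariate perfectly orders event times -> monotone likelihood
        n = 20
        time = np.arange(1.0, n + 1)
        event = np.ones(n, dtype=int)
        x = -time
        fit = fit_cox(x[:, None], time, event)
        assert not fit.converged
        assert "separation" in fit.message or "convergence" in fit.message

    def test_aic_and_hr_definitions(self, rng):
        X, time, event = random_survival(rng, 50)
        fit = fit_cox(X, time, event)
        assert fit.aic == pytest.approx(2 * len(fit.terms) - 2 * fit.loglik)
        assert np.allclose(fit.hazard_ratios, np.exp(fit.coef))

    def test_nesting_never_decreases_loglik(self, rng):
        for _ in range(5):
            X, time, event = random_survival(rng, 40, p=3)
            sub = fit_cox(X[:, :2], time, event)
            full = fit_cox(X, time, event)
            assert full.loglik >= sub.loglik - 1e-8

    def test_scale_equivariance(self, rng):
        X, time, event = random_survival(rng, 60, p=2)
        fit = fit_cox(X, time, event)
        Xs = X.copy()
        Xs[:, 0] *= 10.0
        fit_s = fit_cox(Xs, time, event)
        assert fit_s.coef[0] == pytest.approx(fit.coef[0] / 10.0, rel=1e-6)
        assert fit_s.loglik == pytest.approx(fit.loglik, abs=1e-8)
        assert fit_s.cindex == pytest.approx(fit.cindex, abs=1e-12)

    @pytest.mark.parametrize("tie_frac", [0.0, 1.0])
    def test_agreement_with_lifelines(self, rng, tie_frac):
        from lifelines import CoxPHFitter

        for _ in range(10):
            X, time, event = random_survival(rng, int(rng.integers(30, 60)), p=2,
                                             tie_frac=tie_frac)
            if event.sum() < 5:
                continue
            df = pd.DataFrame(X, columns=["x0", "x1"])
            df["T"], df["E"] = time, event
            ref = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-9})
            fit = fit_cox(X, time, event)
            assert np.max(np.abs(fit.coef - ref.params_.values)) < 1e-4
            assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)


class TestLikelihoodRatioTest:
    def _fake(self, loglik, terms):
        p = len(terms)
        return CoxFit(
            terms=terms, coef=np.zeros(p), se=np.zeros(p), cov=np.zeros((p, p)),
            loglik=loglik, loglik_null=-50.0, aic=0.0, cindex=0.5, converged=True,
            n_iter=1, n=20, n_events=10,
        )

    def test_identical_models_give_p_one(self, rng):
        X, time, event = random_survival(rng, 30)
        fit = fit_cox(X, time, event)
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_tail_value(self):
        full = self._fake(-45.0, ("a", "b"))
        red = self._fake(-47.0, ("a",))
        res = likelihood_ratio_test(full, red)
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(chi2.sf(4.0, 1), abs=1e-12)
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_negative_statistic_clamped_with_warning(self):
        full = self._fake(-47.001, ("a", "b"))
        red = self._fake(-47.0, ("a",))
        with pytest.warns(UserWarning, match="clamped"):
            res = likelihood_ratio_test(full, red)
        assert res.statistic == 0.0

    def test_non_nested_rejected(self):
        full = self._fake(-45.0, ("a", "b"))
        red = self._fake(-46.0, ("c",))
        with pytest.raises(UsageError):
            likelihood_ratio_test(full, red)


class TestConcordance:
    def test_perfect_ordering(self):
        time = np.array([1.0, 2, 3, 4])
        event = np.ones(4, dtype=int)
        assert concordance_index(-time, time, event) == 1.0

    def test_constant_risk_is_half(self):
        time = np.array([1.0, 2, 3, 4])
        event = np.array([1, 1, 0, 1])
        assert concordance_index(np.zeros(4), time, event) == 0.5

    def test_matches_pair_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 12))
            time = rng.integers(1, 6, n).astype(float)
            event = rng.integers(0, 2, n)
            risk = rng.integers(-2, 3, n).astype(float)
            if not event.any() or np.all(time == time[0]):
                continue
            try:
                got = concordance_index(risk, time, event)
            except DataError:
                continue
            assert got == pytest.approx(brute_force_concordance(risk, time, event), abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DataError):
            concordance_index(np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.array([0, 0]))


def _clinical_frame(rng, n):
    return pd.DataFrame(
        {
            "tumor_volume_cc": rng.uniform(1, 20, n),
            "motion_cm": rng.uniform(0, 1.5, n),
            "lobe": rng.choice(["upper", "lower"], n),
            "age": rng.uniform(50, 90, n),
            "sex": rng.choice(["male", "female"], n),
        }
    )


class TestClinicalDesign:
    def test_reference_coding_and_log_volume(self, rng):
        clin = _clinical_frame(rng, 30)
        d = clinical_design(clin)
        assert set(d.columns) == {"ln_volume", "motion_cm", "lobe_upper", "age", "sex_male"}
        assert set(np.unique(d["sex_male"])) <= {0.0, 1.0}
        assert d["ln_volume"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_missing_column_named(self, rng):
        clin = _clinical_frame(rng, 10).drop(columns=["lobe"])
        with pytest.raises(Exception, match="lobe"):
            clinical_design(clin)


class TestDoseMetricScreen:
    def _outcome(self, rng, clin, effect_col=None, beta=0.0):
        lp = np.zeros(len(clin))
        if effect_col is not None:
            v = effect_col - effect_col.mean()
            lp = beta * v
        t = rng.exponential(np.exp(-lp) * 20.0)
        cens = np.full(len(clin), 60.0)
        clin["time_lr"] = np.minimum(t, cens)
        clin["event_lr"] = (t <= cens).astype(int)
        return clin

    def test_constant_and_collinear_flagged(self, rng):
        clin = self._outcome(rng, _clinical_frame(rng, 60))
        stats = pd.DataFrame(
            {
                "GTV_mean": np.full(60, 110.0),
                "PTV_mean": clin["age"].to_numpy() * 2.0,  # collinear with age
                "PTV_sd": rng.normal(10, 2, 60),
            }
        )
        res = standard_dose_metric_screen(clin, stats).set_index("metric")
        assert res.loc["GTV_mean", "note"] == "constant"
        assert res.loc["PTV_mean", "note"] == "collinear"
        assert np.isfinite(res.loc["PTV_sd", "p_lrt"])

    def test_planted_dose_effect_detected(self, rng):
        hits = 0
        for _ in range(5):
            clin = _clinical_frame(rng, 300)
            sd = rng.normal(10, 2, 300)
            clin = self._outcome(rng, clin, effect_col=sd, beta=0.4)
            stats = pd.DataFrame({"PTV_sd": sd, "GTV_mean": rng.normal(110, 5, 300)})
            res = standard_dose_metric_screen(clin, stats).set_index("metric")
            hits += res.loc["PTV_sd", "p_lrt"] < 0.05
        assert hits >= 4
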