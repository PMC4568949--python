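"""Regression families and stepwise-AIC selection.

Three families cover the endpoint kinds: Cox proportional hazards
(survival, Efron tie handling, partial likelihood), binary logistic
regression, and the proportional-odds cumulative-logit model (ordered
multi-class).  Signature proteins are chosen by bidirectional stepwise
search that adds or drops one protein at a time, keeping clinical
covariates forced, until the Akaike information criterion (AIC = -2l + 2k)
can no longer be strictly improved.

The Cox partial likelihood is maximized by a damped Newton solver written
against the Efron-approximated likelihood; logistic and proportional-odds
fits are delegated to statsmodels.  Monotone-likelihood / separation cases
are capped (|beta| <= 15) and flagged rather than raised, so that
cross-validation folds always complete.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import CohortError

COEF_CAP = 15.0

FAMILIES = ("cox", "logistic", "propodds")


class FitError(RuntimeError):
    """A model fit that cannot proceed (invalid inputs, empty class...)."""


@dataclasses.dataclass
class FittedModel:
    """A fitted regression model.

    ``coef`` is aligned with ``predictors`` (clinical covariates first,
    then proteins); ``intercept`` is the logistic intercept, ``thresholds``
    the strictly increasing proportional-odds cutpoints (cumulative logit
    P(Y <= j) = expit(thresholds[j] - x.beta)).  ``loglik`` is the
    maximized (partial, for Cox) log-likelihood and ``k`` the number of
    estimated parameters entering the AIC.
    """

    family: str
    predictors: list[str]
    coef: np.ndarray
    loglik: float
    k: int
    n: int
    intercept: float | None = None
    thresholds: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.predictors):
            raise FitError("coefficient count does not match predictor count")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if np.any(np.diff(self.thresholds) <= 0):
                raise FitError("proportional-odds thresholds must increase")

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def protein_predictors(self) -> list[str]:
        from .cohort import FORCED_COVARIATES

        return [p for p in self.predictors if p not in FORCED_COVARIATES]

    # -- prediction --------------------------------------------------------

    def linear_predictor(self, newdata: pd.DataFrame) -> pd.Series:
        """beta' x for each row of ``newdata`` (no intercept/threshold)."""
        missing = [p for p in self.predictors if p not in newdata.columns]
        if missing:
            raise FitError(f"newdata lacks predictors: {missing}")
        if not self.predictors:
            return pd.Series(0.0, index=newdata.index)
        X = newdata[self.predictors].to_numpy(dtype=float)
        return pd.Series(X @ self.coef, index=newdata.index)

    def predict_proba(self, newdata: pd.DataFrame) -> pd.Series:
        """Logistic: P(Y = 1)."""
        if self.family != "logistic":
            raise FitError("predict_proba requires a logistic model")
        return pd.Series(
            special.expit(self.intercept + self.linear_predictor(newdata)),
            index=newdata.index,
        )

    def class_probabilities(self, newdata: pd.DataFrame) -> pd.DataFrame:
        """Proportional odds: per-class probabilities (columns 0..J-1)."""
        if self.family != "propodds":
            raise FitError("class_probabilities requires a proportional-odds model")
        eta = self.linear_predictor(newdata).to_numpy()
        cum = special.expit(self.thresholds[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        probs = np.diff(cum, axis=1)
        return pd.DataFrame(probs, index=newdata.index)

    def predict_class(self, newdata: pd.DataFrame) -> pd.Series:
        """Argmax-probability class (propodds) or 0/1 at p=0.5 (logistic)."""
        if self.family == "propodds":
            return self.class_probabilities(newdata).idxmax(axis=1)
        if self.family == "logistic":
            return (self.predict_proba(newdata) >= 0.5).astype(int)
        raise FitError("predict_class undefined for Cox models")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "predictors": self.predictors,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "thresholds": None if self.thresholds is None else self.thresholds.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aic": self.aic,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            family=d["family"], predictors=list(d["predictors"]),
            coef=np.asarray(d["coef"], dtype=float), loglik=d["loglik"],
            k=d["k"], n=d["n"], intercept=d.get("intercept"),
            thresholds=None if d.get("thresholds") is None
            else np.asarray(d["thresholds"], dtype=float),
            converged=d.get("converged", True),
        )


def aic(model: FittedModel) -> float:
    """Akaike information criterion, -2 loglik + 2 k."""
    return model.aic


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

def cox_partial_loglik(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray,
    derivatives: bool = True,
):
    """Efron-approximated Cox partial log-likelihood (and derivatives).

    Subjects censored at an event time remain in that time's risk set.
    Returns ``ll`` or ``(ll, gradient, information)``; the information is
    the negative Hessian.
    """
    n, p = X.shape if X.ndim == 2 else (len(X), 0)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    Xs = X[order] if p else np.zeros((n, 0))
    eta = Xs @ beta if p else np.zeros(n)
    w = np.exp(eta)
    wx = Xs * w[:, None]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # accumulate risk-set sums from the largest time downwards
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        t = time[i]
        j = i
        while j >= 0 and time[j] == t:
            j -= 1
        block = slice(j + 1, i + 1)
        S0 += w[block].sum()
        S1 += wx[block].sum(axis=0)
        S2 += Xs[block].T @ wx[block]
        ev = np.where(event[block] == 1)[0] + (j + 1)
        d = len(ev)
        if d:
            ll += eta[ev].sum()
            grad += Xs[ev].sum(axis=0)
            S0D = w[ev].sum()
            S1D = wx[ev].sum(axis=0)
            S2D = Xs[ev].T @ wx[ev]
            for l in range(d):
                phi = l / d
                d0 = S0 - phi * S0D
                ll -= np.log(d0)
                if derivatives and p:
                    d1 = S1 - phi * S1D
                    d2 = S2 - phi * S2D
                    grad -= d1 / d0
                    info += d2 / d0 - np.outer(d1, d1) / d0**2
        i = j
    if not derivatives:
        return ll
    return ll, grad, info


def fit_cox(
    data: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    predictors: Sequence[str] = (),
    max_iter: int = 50,
    tol: float = 1e-9,
) -> FittedModel:
    """Maximize the Efron partial likelihood by damped Newton iteration.

    Monotone likelihood (e.g. a perfectly separating covariate) is handled
    by capping coefficients at +/-15 and flagging non-convergence; the fit
    never raises for it.
    """
    predictors = list(predictors)
    t = time.to_numpy(dtype=float)
    e = event.to_numpy(dtype=int)
    if e.sum() == 0:
        raise FitError("no events in the data")
    if np.any(t < 0):
        raise FitError("negative survival time")
    X = data[predictors].to_numpy(dtype=float) if predictors else np.zeros((len(t), 0))
    if predictors:
        if np.any(X.std(axis=0) == 0):
            const = [predictors[j] for j in np.where(X.std(axis=0) == 0)[0]]
            raise FitError(f"constant covariate: {const}")
    p = len(predictors)
    beta = np.zeros(p)
    ll = cox_partial_loglik(X, t, e, beta, derivatives=False)
    converged = p == 0
    for _ in range(max_iter if p else 0):
        ll, grad, info = cox_partial_loglik(X, t, e, beta)
        if np.max(np.abs(grad)) < 1e-7:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # damped update with step halving
        for _ in range(30):
            cand = np.clip(beta + step, -COEF_CAP, COEF_CAP)
            ll_new = cox_partial_loglik(X, t, e, cand, derivatives=False)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        if np.allclose(cand, beta, atol=1e-12):
            break
        improved = ll_new - ll
        beta, ll = cand, ll_new
        if np.any(np.abs(beta) >= COEF_CAP):
            converged = False
            break
        if improved < tol and np.max(np.abs(grad)) < 1e-5:
            converged = True
            break
    else:
        converged = p == 0
    return FittedModel(
        family="cox", predictors=predictors, coef=beta,
        loglik=float(ll), k=p, n=len(t), converged=converged,
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _logistic_negloglik(params, X, y):
    eta = params[0] + X @ params[1:]
    return -(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    data: pd.DataFrame, labels: pd.Series, predictors: Sequence[str] = ()
) -> FittedModel:
    """Maximum-likelihood logistic regression (intercept always included).

    Complete separation is capped at |beta| <= 15 via a bounded refit and
    flagged rather than raised.
    """
    predictors = list(predictors)
    y = labels.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("both classes must be present")
    X = data[predictors].to_numpy(dtype=float) if predictors else np.zeros((len(y), 0))
    design = np.hstack([np.ones((len(y), 1)), X])
    converged = True
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", True) and np.all(
                np.abs(res.params) <= COEF_CAP
            ):
                params = np.asarray(res.params)
        except Exception:
            params = None
    if params is None:
        converged = False
        x0 = np.zeros(design.shape[1])
        bounds = [(-COEF_CAP, COEF_CAP)] * design.shape[1]
        opt = optimize.minimize(
            _logistic_negloglik, x0, args=(X, y), method="L-BFGS-B", bounds=bounds
        )
        params = opt.x
    ll = -_logistic_negloglik(params, X, y)
    return FittedModel(
        family="logistic", predictors=predictors, coef=params[1:],
        intercept=float(params[0]), loglik=float(ll),
        k=len(params), n=len(y), converged=converged,
    )


# ---------------------------------------------------------------------------
# proportional odds (cumulative logit)
# ---------------------------------------------------------------------------

def fit_propodds(
    data: pd.DataFrame, labels: pd.Series, predictors: Sequence[str] = ()
) -> FittedModel:
    """Cumulative-logit proportional-odds fit: logit P(Y <= j) = theta_j - x.beta.

    Classes must be coded 0..J-1; every class must be non-empty.  With no
    predictors the thresholds are the closed-form logits of the cumulative
    class proportions.
    """
    predictors = list(predictors)
    y = labels.to_numpy(dtype=int)
    classes = np.unique(y)
    J = len(classes)
    if J < 2:
        raise FitError("at least 2 classes required")
    if not np.array_equal(classes, np.arange(J)):
        raise FitError("ordinal labels must be coded 0..J-1 with all classes present")
    n = len(y)
    if not predictors:
        counts = np.bincount(y, minlength=J)
        cum = np.cumsum(counts)[:-1] / n
        thresholds = special.logit(cum)
        ll = float(np.sum(counts * np.log(counts / n)))
        return FittedModel(
            family="propodds", predictors=[], coef=np.zeros(0),
            thresholds=thresholds, loglik=ll, k=J - 1, n=n,
        )
    X = data[predictors].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = OrderedModel(y, X, distr="logit")
        res = mod.fit(method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = mod.fit(method="lbfgs", maxiter=1000, disp=0, start_params=res.params)
    p = len(predictors)
    beta = np.asarray(res.params[:p], dtype=float)
    thresholds = np.asarray(
        mod.transform_threshold_params(np.asarray(res.params))[1:-1], dtype=float
    )
    converged = bool(res.mle_retvals.get("converged", True)) and np.all(
        np.abs(beta) <= COEF_CAP
    )
    return FittedModel(
        family="propodds", predictors=predictors, coef=beta,
        thresholds=thresholds, loglik=float(res.llf), k=p + J - 1, n=n,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# dispatch, stepwise selection, likelihood-ratio test
# ---------------------------------------------------------------------------

def fit_family(
    family: str, data: pd.DataFrame, response, predictors: Sequence[str] = ()
) -> FittedModel:
    """Fit ``family`` with ``response`` = labels Series (logistic/propodds)
    or a (time, event) pair of Series (cox)."""
    if family == "cox":
        time, event = response
        return fit_cox(data, time, event, predictors)
    if family == "logistic":
        return fit_logistic(data, response, predictors)
    if family == "propodds":
        return fit_propodds(data, response, predictors)
    raise FitError(f"unknown family {family!r}")


def stepwise_select(
    family: str,
    data: pd.DataFrame,
    response,
    forced: Sequence[str] = (),
    candidates: Sequence[str] = (),
    min_improvement: float = 1e-9,
    max_steps: int = 200,
    trace: list | None = None,
) -> FittedModel:
    """Bidirectional stepwise-AIC protein selection.

    Starts from the forced-covariates-only model; each iteration evaluates
    every single-protein addition and deletion (forced covariates are
    never dropped), applies the move with the lowest AIC if it strictly
    improves on the current AIC, and stops otherwise.  Ties break towards
    addition, then lexicographically by protein id.  Candidate fits that
    fail are skipped with a warning.
    """
    forced = list(forced)
    candidates = sorted(set(candidates) - set(forced))
    current = fit_family(family, data, response, forced)
    if trace is not None:
        trace.append(current.aic)
    selected: list[str] = []
    for _ in range(max_steps):
        moves: list[tuple[float, int, str, FittedModel]] = []
        for pid in candidates:
            if pid in selected:
                continue
            try:
                m = fit_family(family, data, response, forced + sorted(selected + [pid]))
                moves.append((m.aic, 0, pid, m))
            except (FitError, CohortError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"stepwise: skipping addition of {pid}: {exc}")
        for pid in sorted(selected):
            rest = [q for q in selected if q != pid]
            try:
                m = fit_family(family, data, response, forced + sorted(rest))
                moves.append((m.aic, 1, pid, m))
            except (FitError, CohortError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"stepwise: skipping deletion of {pid}: {exc}")
        if not moves:
            break
        best_aic, action, pid, model = min(moves, key=lambda m: (m[0], m[1], m[2]))
        if best_aic < current.aic - min_improvement:
            current = model
            if trace is not None:
                trace.append(current.aic)
            if action == 0:
                selected.append(pid)
            else:
                selected.remove(pid)
        else:
            break
    return current


def lr_test(reduced: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models: (statistic, df, p).

    statistic = 2 (l_full - l_reduced), df = k_full - k_reduced,
    p from the upper tail of chi-square(df).
    """
    if reduced.family != full.family:
        raise FitError("models must share a family")
    if reduced.n != full.n:
        raise FitError("models must be fit on the same patients")
    if not set(reduced.predictors) <= set(full.predictors):
        raise FitError("reduced model predictors must nest in the full model")
    df = full.k - reduced.k
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if set(reduced.predictors) == set(full.predictors):
        return 0.0, 0, 1.0
    if df <= 0:
        raise FitError("full model must have more parameters than the reduced model")
    return stat, df, float(stats.chi2.sf(stat, df))
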