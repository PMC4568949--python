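"""Risk stratification and fixed-signature transfer.

A fitted outcome signature assigns each patient a protein risk score (the
linear combination of signature-protein abundances).  Patients are split
into HIGH/LOW risk groups at the median score of a designated subgroup
(the study convention: stages I-III), survival is visualized with
Kaplan-Meier curves per group and with Cox-model predicted survival at
fixed covariate settings (Breslow baseline hazard).

Transfer applies a *fixed* signature to a second dataset: coefficients
are always re-estimated on the new data (no screening, no stepwise, no
coefficient transport), and performance is summarized with the same
stratified K-fold held-out machinery as discovery.  Subtype prediction
retrains a proportional-odds model on the signature features and reports
the median per-class recall over the folds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .cohort import AbundanceMatrix, CohortError, EndpointLabels
from .evaluation import (
    PerformanceSummary, pairwise_rocs, pseudomedian_fold, roc_binary,
    roc_survival_cd,
)
from .models import FitError, FittedModel, fit_family
from .discovery import stratified_folds


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KMCurve:
    """Product-limit survival estimate: step function dropping at event
    times, with at-risk and event counts per distinct time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t) -> np.ndarray:
        """S(t) evaluated as a right-continuous step function."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.times) - 1)])
        return out if out.size > 1 else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after
    their time (subjects censored at an event time count as at risk)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise CohortError("empty survival data")
    if np.any(times < 0):
        raise CohortError("negative survival time")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, idx = np.unique(t, return_index=True)
    at_risk = len(t) - idx
    deaths = np.add.reduceat(e, idx)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(times=uniq, survival=surv, at_risk=at_risk, events=deaths)


# ---------------------------------------------------------------------------
# risk groups
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RiskStratification:
    scores: pd.Series
    cutoff: float
    groups: pd.Series  # "HIGH" / "LOW"

    def km_by_group(self, time: pd.Series, event: pd.Series) -> dict[str, KMCurve]:
        out = {}
        for g in ["LOW", "HIGH"]:
            ids = self.groups.index[self.groups == g]
            if len(ids):
                out[g] = km_estimate(time[ids], event[ids])
        return out


def risk_groups(scores: pd.Series, cutoff_subgroup_mask: pd.Series | None = None
                ) -> RiskStratification:
    """HIGH/LOW risk split at the median score of a designated subgroup.

    The cutoff is the exact median (even count: mean of the two central
    order statistics) of the subgroup's scores; every patient — inside or
    outside the subgroup — is HIGH iff score >= cutoff.
    """
    if cutoff_subgroup_mask is None:
        cutoff_subgroup_mask = pd.Series(True, index=scores.index)
    sub = scores[cutoff_subgroup_mask.reindex(scores.index, fill_value=False)]
    if len(sub) == 0:
        raise CohortError("empty cutoff subgroup")
    cutoff = float(np.median(sub))
    groups = pd.Series(np.where(scores >= cutoff, "HIGH", "LOW"), index=scores.index)
    return RiskStratification(scores=scores, cutoff=cutoff, groups=groups)


# ---------------------------------------------------------------------------
# predicted survival (Breslow baseline)
# ---------------------------------------------------------------------------

def breslow_baseline(time: pd.Series, event: pd.Series,
                     linear_predictor: pd.Series) -> KMCurve:
    """Breslow cumulative baseline hazard, returned as the baseline
    survival step function S0(t) = exp(-H0(t))."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    w = np.exp(np.asarray(linear_predictor, dtype=float))
    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    uniq, idx = np.unique(t, return_index=True)
    # risk-set sums of exp(lp), largest time downwards
    w_rev_cum = np.cumsum(w[::-1])[::-1]
    risk_w = w_rev_cum[idx]
    deaths = np.add.reduceat(e, idx)
    h0 = np.cumsum(deaths / risk_w)
    at_risk = len(t) - idx
    return KMCurve(times=uniq, survival=np.exp(-h0), at_risk=at_risk, events=deaths)


def predicted_survival_cox(
    model: FittedModel,
    data: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    settings: list[dict],
) -> list[tuple[dict, KMCurve]]:
    """Predicted survival curves S(t|x) = S0(t)^exp(beta'x) for each
    requested covariate setting, with S0 the Breslow baseline estimated
    from the model's data."""
    if model.family != "cox":
        raise FitError("predicted survival requires a Cox model")
    lp = model.linear_predictor(data)
    base = breslow_baseline(time, event, lp)
    out = []
    for setting in settings:
        missing = [p for p in model.predictors if p not in setting]
        if missing:
            raise FitError(f"covariate setting lacks fields: {missing}")
        x = np.array([float(setting[p]) for p in model.predictors])
        risk = float(np.exp(x @ model.coef)) if model.predictors else 1.0
        curve = KMCurve(
            times=base.times, survival=base.survival**risk,
            at_risk=base.at_risk, events=base.events,
        )
        out.append((setting, curve))
    return out


# ---------------------------------------------------------------------------
# fixed-signature transfer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TransferResult:
    signature: list[str]
    family: str
    model: FittedModel                      # full-data refit on the new data
    performance: PerformanceSummary | None
    per_class_recall: dict[int, list[float]] | None = None
    median_recall: dict[int, float] | None = None
    km_by_predicted_class: dict[int, KMCurve] | None = None


def _check_signature(matrix: AbundanceMatrix, signature: list[str]) -> None:
    missing = [p for p in signature if p not in matrix.values.index]
    if missing:
        raise CohortError(f"signature features missing from the matrix: {missing}")


def transfer_signature(
    matrix: AbundanceMatrix,
    labels: EndpointLabels,
    signature: list[str],
    family: str,
    K: int = 10,
    seed: int = 0,
    design_extra: pd.DataFrame | None = None,
    forced: list[str] | None = None,
    horizon: float = 5.0,
) -> TransferResult:
    """Re-estimate a fixed signature on a new dataset and cross-validate it.

    The predictor set is exactly ``signature`` (plus ``forced`` clinical
    covariates if given); no screening or stepwise selection is performed,
    and no coefficients are transported from the discovery data.
    """
    _check_signature(matrix, signature)
    if matrix.n_missing():
        matrix = matrix.impute_lod()
    design = matrix.samples()
    if design_extra is not None:
        design = design_extra.join(design)
    forced = list(forced or [])
    predictors = forced + list(signature)
    ids = labels.included_ids()
    folds = stratified_folds(labels, K, seed)

    fold_aucs = []
    for k in range(K):
        test_ids = folds.index[folds == k]
        train_ids = folds.index[folds != k]
        try:
            if labels.kind == "survival":
                resp = (labels.time[train_ids], labels.event[train_ids])
            else:
                resp = labels.y[train_ids].astype(int)
            m = fit_family(family, design.loc[train_ids], resp, predictors)
            scores = m.linear_predictor(design.loc[test_ids])
            if labels.kind == "survival":
                auc = roc_survival_cd(
                    scores, labels.time[test_ids].to_numpy(),
                    labels.event[test_ids].to_numpy(), horizon).auc
            elif labels.kind == "binary":
                auc = roc_binary(scores, labels.y[test_ids].astype(int)).auc
            else:
                rocs = pairwise_rocs(scores.to_numpy(),
                                     labels.y[test_ids].astype(int).to_numpy())
                auc = float(np.mean([c.auc for c in rocs.values()]))
            fold_aucs.append(auc)
        except (FitError, CohortError) as exc:
            warnings.warn(f"transfer fold {k} failed: {exc}")
            fold_aucs.append(np.nan)

    if labels.kind == "survival":
        full_resp = (labels.time[ids], labels.event[ids])
    else:
        full_resp = labels.y[ids].astype(int)
    model = fit_family(family, design.loc[ids], full_resp, predictors)
    scores = model.linear_predictor(design.loc[ids])
    if labels.kind == "survival":
        auc_full = roc_survival_cd(
            scores, labels.time[ids].to_numpy(), labels.event[ids].to_numpy(),
            horizon).auc
    elif labels.kind == "binary":
        auc_full = roc_binary(scores, labels.y[ids].astype(int)).auc
    else:
        rocs = pairwise_rocs(scores.to_numpy(), labels.y[ids].astype(int).to_numpy())
        auc_full = float(np.mean([c.auc for c in rocs.values()]))

    perf = PerformanceSummary(
        auc_full=auc_full, fold_aucs=fold_aucs,
        auc_median=pseudomedian_fold(fold_aucs),
    )
    return TransferResult(signature=list(signature), family=family,
                          model=model, performance=perf)


def predict_subtypes(
    matrix: AbundanceMatrix,
    labels: EndpointLabels,
    signature: list[str],
    K: int = 10,
    seed: int = 0,
    survival: tuple[pd.Series, pd.Series] | None = None,
) -> TransferResult:
    """Subtype prediction with a fixed signature.

    Fits a proportional-odds model (logistic for two classes) on the
    signature features within stratified K-fold CV, predicts the held-out
    class by argmax probability, and reports the per-class recall of each
    fold plus the median per-class recall over folds.  When survival data
    are supplied, Kaplan-Meier curves grouped by *predicted* class are
    also returned.
    """
    _check_signature(matrix, signature)
    if matrix.n_missing():
        matrix = matrix.impute_lod()
    design = matrix.samples()
    ids = labels.included_ids()
    y = labels.y[ids].astype(int)
    classes = sorted(y.unique())
    family = "propodds" if len(classes) > 2 else "logistic"
    folds = stratified_folds(labels, K, seed)

    recalls: dict[int, list[float]] = {c: [] for c in classes}
    predicted = pd.Series(index=ids, dtype=float)
    for k in range(K):
        test_ids = folds.index[folds == k]
        train_ids = folds.index[folds != k]
        try:
            m = fit_family(family, design.loc[train_ids],
                           y[train_ids], signature)
        except (FitError, CohortError) as exc:
            warnings.warn(f"subtype fold {k} flagged: {exc}")
            continue
        pred = m.predict_class(design.loc[test_ids])
        predicted[test_ids] = pred
        for c in classes:
            in_c = y[test_ids] == c
            if in_c.sum():
                recalls[c].append(float((pred[in_c.index[in_c]] == c).mean()))

    median_recall = {c: float(np.median(v)) for c, v in recalls.items() if v}
    model = fit_family(family, design.loc[ids], y, signature)

    km_by_class = None
    if survival is not None:
        time, event = survival
        km_by_class = {}
        for c in classes:
            pids = predicted.index[predicted == c]
            if len(pids):
                km_by_class[int(c)] = km_estimate(time[pids], event[pids])

    return TransferResult(
        signature=list(signature), family=family, model=model,
        performance=None, per_class_recall=recalls,
        median_recall=median_recall, km_by_predicted_class=km_by_class,
    )
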