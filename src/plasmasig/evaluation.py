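"""Performance evaluation: ROC curves, AUCs, fold summaries, bootstrap.

Binary ROC/AUC wraps scikit-learn; the time-dependent (cumulative/dynamic)
survival ROC at a horizon is computed with the Kaplan-Meier-conditional
estimator: with marker M, cutoff c and S the KM survival estimate,

    sensitivity(c) = (1 - S(t | M > c)) P(M > c) / (1 - S(t))
    specificity(c) = 1 - S(t | M > c) P(M > c) / S(t)

which reduces exactly to the binary ROC on event-by-horizon labels when
no subject is censored before the horizon.  Cross-validated performance
is summarized by the pseudomedian fold (the ceil(K/2)-th largest held-out
fold AUC: 5th largest of ten, 4th largest of eight) and by 25th/75th
percentile sensitivity bands over a 1-specificity grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortError
from .models import FitError, FittedModel, fit_family

BAND_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclasses.dataclass
class ROCCurve:
    """An ROC curve: (1-specificity, sensitivity) points from (0,0) to
    (1,1), trapezoidal AUC, and group sizes."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    clipped: bool = False

    def sensitivity_at(self, grid: np.ndarray) -> np.ndarray:
        """Right-continuous step-function evaluation on a 1-spec grid."""
        idx = np.searchsorted(self.fpr, grid, side="right") - 1
        return self.tpr[np.clip(idx, 0, len(self.tpr) - 1)]


@dataclasses.dataclass
class PerformanceSummary:
    """Full-data and cross-validated performance of a signature."""

    auc_full: float
    fold_aucs: list[float]
    auc_median: float
    band_q25: np.ndarray | None = None
    band_q75: np.ndarray | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    se: dict[str, float] | None = None
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "auc_full": self.auc_full,
            "fold_aucs": list(self.fold_aucs),
            "auc_median": self.auc_median,
            "band_q25": None if self.band_q25 is None else self.band_q25.tolist(),
            "band_q75": None if self.band_q75 is None else self.band_q75.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "se": self.se,
            "n_bootstrap": self.n_bootstrap,
        }


# ---------------------------------------------------------------------------
# ROC curves
# ---------------------------------------------------------------------------

def roc_binary(scores, labels) -> ROCCurve:
    """Binary ROC over all score thresholds; trapezoidal AUC (equals the
    Mann-Whitney concordance with ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise CohortError("both classes must be present for an ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, n_cases=n_cases,
                    n_controls=n_controls)


def pairwise_rocs(scores, labels, class_names=None) -> dict[tuple, ROCCurve]:
    """One binary ROC per unordered class pair of an ordinal endpoint
    (the higher class of the pair is the case group).  Pairs with an
    empty class are skipped."""
    scores = pd.Series(np.asarray(scores, dtype=float))
    labels = pd.Series(np.asarray(labels, dtype=int))
    classes = sorted(labels.unique())
    out: dict[tuple, ROCCurve] = {}
    for i, ca in enumerate(classes):
        for cb in classes[i + 1:]:
            mask = labels.isin([ca, cb])
            if (labels[mask] == ca).sum() == 0 or (labels[mask] == cb).sum() == 0:
                continue
            key = (
                (class_names[ca], class_names[cb]) if class_names else (ca, cb)
            )
            out[key] = roc_binary(scores[mask], (labels[mask] == cb).astype(int))
    return out


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Kaplan-Meier survival estimate S(t) (product-limit, vectorized)."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq, idx = np.unique(time, return_index=True)
    n = len(time)
    at_risk = n - idx
    deaths = np.add.reduceat(event, idx)
    keep = (uniq <= t) & (deaths > 0)
    if not keep.any():
        return 1.0
    return float(np.prod(1.0 - deaths[keep] / at_risk[keep]))


def roc_survival_cd(scores, times, events, horizon: float) -> ROCCurve:
    """Cumulative/dynamic time-dependent ROC at ``horizon``.

    Cases are subjects with events by the horizon, controls those
    event-free at the horizon; censoring is handled by Kaplan-Meier
    conditioning (see module docstring).  Out-of-range estimates are
    clipped to [0, 1] and flagged.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s_t = _km_survival_at(times, events, horizon)
    if s_t >= 1.0:
        raise CohortError("no events by the horizon")
    if s_t <= 0.0:
        raise CohortError("no survivors past the horizon")
    n = len(scores)
    cutoffs = np.unique(scores)[::-1]
    sens = [0.0]
    fpr = [0.0]
    clipped = False
    for c in cutoffs:
        pos = scores > c
        p_pos = pos.mean()
        if p_pos == 0:
            continue
        s_c = _km_survival_at(times[pos], events[pos], horizon)
        se = (1.0 - s_c) * p_pos / (1.0 - s_t)
        fp = s_c * p_pos / s_t
        if se < 0 or se > 1 or fp < 0 or fp > 1:
            clipped = True
        sens.append(min(max(se, 0.0), 1.0))
        fpr.append(min(max(fp, 0.0), 1.0))
    sens.append(1.0)
    fpr.append(1.0)
    # round away product-limit float noise so tied rates sort as vertical
    # segments rather than spurious slivers of width ~1e-16
    pts = sorted(zip(np.round(fpr, 12), np.round(sens, 12)))
    fpr_a = np.array([p[0] for p in pts])
    sens_a = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(sens_a, fpr_a))
    n_cases = int(((times <= horizon) & (events == 1)).sum())
    return ROCCurve(fpr=fpr_a, tpr=sens_a, auc=auc, n_cases=n_cases,
                    n_controls=n - n_cases, clipped=clipped)


# ---------------------------------------------------------------------------
# fold summaries
# ---------------------------------------------------------------------------

def pseudomedian_fold(fold_aucs) -> float:
    """The ceil(K/2)-th largest fold AUC — the 5th largest of ten folds,
    the 4th largest of eight; an exact order statistic, no averaging."""
    vals = np.asarray([v for v in fold_aucs if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise CohortError("no fold AUCs")
    k = int(np.ceil(vals.size / 2))
    return float(np.sort(vals)[::-1][k - 1])


def percentile_bands(
    fold_curves: list[ROCCurve], quantiles: tuple[float, float] = (0.25, 0.75)
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise fold-sensitivity quantile bands on the 1-spec grid.

    Each fold ROC is evaluated as a right-continuous step function on a
    0.01-step grid; at each grid point the quantiles of the K fold
    sensitivities are taken with linear interpolation between order
    statistics.
    """
    if len(fold_curves) < 2:
        raise CohortError("percentile bands need at least 2 fold curves")
    sens = np.vstack([c.sensitivity_at(BAND_GRID) for c in fold_curves])
    lo = np.quantile(sens, quantiles[0], axis=0)
    hi = np.quantile(sens, quantiles[1], axis=0)
    return lo, hi


def classification_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) predicting positive iff
    score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise CohortError("both classes must be present")
    sens = float((pred & pos).sum() / pos.sum())
    spec = float((~pred & neg).sum() / neg.sum())
    acc = float((pred == pos).mean())
    return sens, spec, acc


# ---------------------------------------------------------------------------
# bootstrap standard errors
# ---------------------------------------------------------------------------

def bootstrap_se(
    data: pd.DataFrame,
    response,
    family: str,
    predictors: list[str],
    B: int = 2000,
    seed: int = 0,
    horizon: float = 5.0,
    max_redraws: int = 10,
) -> dict[str, float]:
    """Bootstrap SEs of AUC/sensitivity/specificity/accuracy.

    Resamples patients with replacement; each replicate refits the model
    coefficients on the fixed predictor set and recomputes the metrics on
    the replicate.  Replicates missing a class are redrawn (logged via the
    ``n_redrawn`` entry).  Returns sample SDs across replicates.
    """
    if B < 2:
        raise CohortError("B must be >= 2")
    if family == "propodds":
        raise CohortError("bootstrap_se supports the cox and logistic families")
    rng = np.random.default_rng(seed)
    n = len(data)
    stats_out = {"auc": [], "sensitivity": [], "specificity": [], "accuracy": []}
    n_redrawn = 0
    for _ in range(B):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            rows = data.index[idx]
            d = data.loc[rows]
            d.index = range(n)
            try:
                if family == "cox":
                    t = response[0].loc[rows].reset_index(drop=True)
                    e = response[1].loc[rows].reset_index(drop=True)
                    m = fit_family(family, d, (t, e), predictors)
                    lp = m.linear_predictor(d)
                    curve = roc_survival_cd(lp, t.to_numpy(), e.to_numpy(), horizon)
                    by_h = ((t <= horizon) & (e == 1)).astype(int)
                    ok = (t > horizon) | (e == 1)
                    sens, spec, acc = classification_metrics(
                        lp[ok], by_h[ok], float(np.median(lp))
                    )
                else:
                    y = response.loc[rows].reset_index(drop=True)
                    m = fit_family(family, d, y, predictors)
                    if family == "logistic":
                        scores = m.predict_proba(d)
                        thresh = 0.5
                    else:
                        scores = m.linear_predictor(d)
                        thresh = float(np.median(scores))
                    curve = roc_binary(scores, y)
                    sens, spec, acc = classification_metrics(scores, y, thresh)
                break
            except (CohortError, FitError):
                n_redrawn += 1
                continue
        else:
            continue
        stats_out["auc"].append(curve.auc)
        stats_out["sensitivity"].append(sens)
        stats_out["specificity"].append(spec)
        stats_out["accuracy"].append(acc)
    out = {k: float(np.std(v, ddof=1)) for k, v in stats_out.items() if len(v) > 1}
    out["n_redrawn"] = float(n_redrawn)
    return out
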