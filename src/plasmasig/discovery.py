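"""Cross-validated consensus signature discovery.

For one clinical endpoint: patients are split into K endpoint-stratified
folds; within each fold the training 9/10 is screened for differentially
abundant proteins, stepwise-AIC selection builds the fold's predictive
model, and the held-out 1/10 is scored.  Proteins present in at least
``consensus_min_folds`` fold models form the consensus signature, which is
refit once on the full dataset.  Held-out fold AUCs give the unbiased
(pseudomedian) performance estimate; the full-data refit gives the
optimistic upper bound.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    FORCED_COVARIATES, AbundanceMatrix, CohortError, EndpointLabels,
    EndpointSpec, clinical_design, derive_endpoint,
)
from .evaluation import (
    PerformanceSummary, ROCCurve, bootstrap_se, classification_metrics,
    pairwise_rocs, percentile_bands, pseudomedian_fold, roc_binary,
    roc_survival_cd,
)
from .models import FitError, FittedModel, fit_family, stepwise_select
from .screening import (
    ScreenConfig, multigroup_candidates, select_candidates, two_group_test,
)


@dataclasses.dataclass
class DiscoveryConfig:
    """Knobs of the discovery pipeline.

    ``consensus_min_folds`` defaults to 5 both for K=10 ("at least five of
    ten") and for the K=8 stability variant ("more than four of eight").
    Clinical covariates are forced into survival models only, unless
    ``force_clinical_all`` is set.  ``impute_per_fold`` re-derives LOD
    minima from training patients only (leakage-sensitivity studies);
    the default imputes once, globally, before cross-validation.
    """

    K: int = 10
    consensus_min_folds: int = 5
    screen: ScreenConfig = dataclasses.field(default_factory=ScreenConfig)
    force_clinical_all: bool = False
    impute_per_fold: bool = False
    bootstrap_B: int = 0
    horizon: float = 5.0


@dataclasses.dataclass
class FoldResult:
    fold: int
    candidates: list[str]
    model: FittedModel
    heldout_scores: pd.Series
    auc: float
    curve: ROCCurve | None


@dataclasses.dataclass
class SignatureResult:
    """Outcome of one discovery run for one endpoint."""

    endpoint: str
    folds: list[FoldResult]
    selection_counts: dict[str, int]
    consensus_proteins: list[str]
    consensus_model: FittedModel
    performance: PerformanceSummary
    seed: int
    config: DiscoveryConfig

    def heldout_score_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            for pid, s in fr.heldout_scores.items():
                rows.append({"patient_id": pid, "fold": fr.fold, "score": s})
        return pd.DataFrame(rows)

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.selection_counts.items()),
            columns=["protein_id", "n_folds_selected"],
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "endpoint": self.endpoint,
            "seed": self.seed,
            "K": self.config.K,
            "consensus_min_folds": self.config.consensus_min_folds,
            "selection_counts": self.selection_counts,
            "consensus_proteins": self.consensus_proteins,
            "consensus_model": self.consensus_model.to_dict(),
            "fold_models": [fr.model.to_dict() for fr in self.folds],
            "fold_aucs": [fr.auc for fr in self.folds],
            "performance": self.performance.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(labels: EndpointLabels, K: int, seed: int) -> pd.Series:
    """Assign included patients to K folds with class proportions
    preserved (round-robin within shuffled classes).

    The survival endpoint stratifies on the death-within-horizon screening
    class; patients censored before the horizon form their own stratum so
    they too are spread evenly across folds.
    """
    if K < 2:
        raise CohortError("K must be >= 2")
    ids = labels.included_ids()
    if len(ids) < K:
        raise CohortError("fewer included patients than folds")
    if labels.kind == "survival":
        strata = labels.screen_y[ids].fillna(-1.0)
    else:
        strata = labels.y[ids].astype(float)
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=ids, dtype=int)
    offset = 0
    for value in sorted(strata.unique()):
        members = strata.index[strata == value].to_numpy()
        if len(members) < K:
            warnings.warn(
                f"stratum {value} has fewer patients ({len(members)}) than folds"
            )
        members = members[rng.permutation(len(members))]
        fold[members] = (np.arange(len(members)) + offset) % K
        offset += len(members)
    return fold


# ---------------------------------------------------------------------------
# single fold
# ---------------------------------------------------------------------------

def _forced_for(labels: EndpointLabels, config: DiscoveryConfig) -> list[str]:
    if labels.kind == "survival" or config.force_clinical_all:
        return list(FORCED_COVARIATES)
    return []


def _response_for(labels: EndpointLabels, ids) -> object:
    if labels.kind == "survival":
        return (labels.time[ids], labels.event[ids])
    return labels.y[ids].astype(int)


def _screen(matrix: AbundanceMatrix, labels: EndpointLabels, train_ids,
            config: DiscoveryConfig) -> list[str]:
    screen_labels = labels.screen_labels()
    train_screen = screen_labels[screen_labels.index.isin(train_ids)]
    sub = AbundanceMatrix(matrix.values[list(train_screen.index)])
    if labels.kind == "ordinal":
        cands, _ = multigroup_candidates(sub, train_screen, config.screen)
        return cands
    results = two_group_test(sub, train_screen)
    return select_candidates(results, config.screen)


def _fold_auc(labels: EndpointLabels, scores: pd.Series, horizon: float):
    """(auc, curve) of held-out scores; curve is None for ordinal folds."""
    ids = scores.index
    try:
        if labels.kind == "survival":
            curve = roc_survival_cd(
                scores, labels.time[ids].to_numpy(),
                labels.event[ids].to_numpy(), horizon,
            )
            return curve.auc, curve
        if labels.kind == "binary":
            curve = roc_binary(scores, labels.y[ids].astype(int))
            return curve.auc, curve
        rocs = pairwise_rocs(scores.to_numpy(), labels.y[ids].astype(int).to_numpy())
        if not rocs:
            return np.nan, None
        return float(np.mean([c.auc for c in rocs.values()])), None
    except CohortError as exc:
        warnings.warn(f"fold AUC unavailable: {exc}")
        return np.nan, None


def run_fold(
    matrix: AbundanceMatrix,
    design: pd.DataFrame,
    labels: EndpointLabels,
    train_ids,
    test_ids,
    config: DiscoveryConfig,
) -> tuple[list[str], FittedModel, pd.Series]:
    """Screen + stepwise select on the training patients only, then score
    the held-out patients with the fold model's linear predictor."""
    forced = _forced_for(labels, config)
    candidates = _screen(matrix, labels, train_ids, config)
    response = _response_for(labels, train_ids)
    try:
        model = stepwise_select(
            _family_for(labels), design.loc[train_ids], response,
            forced=forced, candidates=candidates,
        )
    except (FitError, CohortError) as exc:
        warnings.warn(f"fold model failed ({exc}); using forced-only model")
        model = fit_family(_family_for(labels), design.loc[train_ids],
                           response, forced)
    scores = model.linear_predictor(design.loc[test_ids])
    return candidates, model, scores


def _family_for(labels: EndpointLabels) -> str:
    return {"survival": "cox", "binary": "logistic", "ordinal": "propodds"}[labels.kind]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def consensus_model(
    fold_models: list[FittedModel],
    min_folds: int,
    data: pd.DataFrame,
    response,
    family: str,
    forced: list[str],
) -> tuple[dict[str, int], list[str], FittedModel]:
    """Count per-fold protein selections, form the consensus set
    (count >= ``min_folds``) and refit it once on the full data."""
    if not fold_models:
        raise CohortError("no fold models")
    counts = Counter()
    for m in fold_models:
        counts.update(m.protein_predictors)
    consensus = sorted(p for p, c in counts.items() if c >= min_folds)
    model = fit_family(family, data, response, forced + consensus)
    return dict(counts), consensus, model


def discover_signature(
    cohort: pd.DataFrame,
    matrix: AbundanceMatrix,
    endpoint: str | EndpointSpec,
    config: DiscoveryConfig | None = None,
    seed: int = 0,
) -> SignatureResult:
    """Run the full K-fold discovery for one endpoint.

    Returns the per-fold models and held-out scores, the selection counts,
    the consensus signature refit on the full data, and a performance
    summary combining the optimistic full-data AUC with the cross-validated
    pseudomedian and 25th/75th percentile sensitivity bands.
    """
    config = config or DiscoveryConfig()
    spec = endpoint if isinstance(endpoint, EndpointSpec) else EndpointSpec(endpoint, horizon=config.horizon)
    labels = derive_endpoint(cohort, spec)
    if matrix.n_missing() and not config.impute_per_fold:
        matrix = matrix.impute_lod()
    design = clinical_design(cohort).join(matrix.samples())
    ids = labels.included_ids()
    folds = stratified_folds(labels, config.K, seed)

    fold_results: list[FoldResult] = []
    for k in range(config.K):
        test_ids = folds.index[folds == k]
        train_ids = folds.index[folds != k]
        fm, fdesign = matrix, design
        if config.impute_per_fold and matrix.n_missing():
            fm = _impute_from_train(matrix, train_ids)
            fdesign = clinical_design(cohort).join(fm.samples())
        candidates, model, scores = run_fold(
            fm, fdesign, labels, train_ids, test_ids, config
        )
        auc_k, curve = _fold_auc(labels, scores, config.horizon)
        fold_results.append(FoldResult(k, candidates, model, scores, auc_k, curve))

    family = _family_for(labels)
    forced = _forced_for(labels, config)
    response = _response_for(labels, ids)
    counts, consensus, cmodel = consensus_model(
        [fr.model for fr in fold_results], config.consensus_min_folds,
        design.loc[ids], response, family, forced,
    )
    if not consensus:
        warnings.warn(f"empty consensus for endpoint {spec.name}; "
                      "performance reflects forced covariates only")

    performance = _summarize(labels, design.loc[ids], cmodel, fold_results,
                             config, seed)
    return SignatureResult(
        endpoint=spec.name, folds=fold_results, selection_counts=counts,
        consensus_proteins=consensus, consensus_model=cmodel,
        performance=performance, seed=seed, config=config,
    )


def _impute_from_train(matrix: AbundanceMatrix, train_ids) -> AbundanceMatrix:
    """Impute LOD minima estimated from the training patients only."""
    vals = matrix.values.to_numpy(copy=True)
    train_vals = matrix.values[list(train_ids)].to_numpy()
    if np.isnan(train_vals).all(axis=1).any():
        raise CohortError("per-fold imputation: a protein has no observed training value")
    row_min = np.nanmin(train_vals, axis=1)
    idx = np.where(np.isnan(vals))
    vals[idx] = row_min[idx[0]]
    return AbundanceMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    )


def _summarize(
    labels: EndpointLabels,
    design: pd.DataFrame,
    cmodel: FittedModel,
    fold_results: list[FoldResult],
    config: DiscoveryConfig,
    seed: int = 0,
) -> PerformanceSummary:
    ids = design.index
    scores = cmodel.linear_predictor(design)
    fold_aucs = [fr.auc for fr in fold_results]
    auc_median = pseudomedian_fold(fold_aucs)

    sens = spec_ = acc = None
    se = None
    if labels.kind == "survival":
        curve = roc_survival_cd(
            scores, labels.time[ids].to_numpy(), labels.event[ids].to_numpy(),
            config.horizon,
        )
        auc_full = curve.auc
        by_h = labels.screen_y[ids]
        ok = by_h.notna()
        sens, spec_, acc = classification_metrics(
            scores[ok], by_h[ok].astype(int), float(np.median(scores))
        )
    elif labels.kind == "binary":
        y = labels.y[ids].astype(int)
        auc_full = roc_binary(scores, y).auc
        probs = cmodel.predict_proba(design)
        sens, spec_, acc = classification_metrics(probs, y, 0.5)
    else:
        rocs = pairwise_rocs(scores.to_numpy(), labels.y[ids].astype(int).to_numpy())
        auc_full = float(np.mean([c.auc for c in rocs.values()]))

    band_lo = band_hi = None
    curves = [fr.curve for fr in fold_results if fr.curve is not None]
    if len(curves) >= 2:
        band_lo, band_hi = percentile_bands(curves)

    if config.bootstrap_B and labels.kind != "ordinal":
        response = _response_for(labels, ids)
        se = bootstrap_se(
            design, response, _family_for(labels), cmodel.predictors,
            B=config.bootstrap_B, seed=seed, horizon=config.horizon,
        )

    return PerformanceSummary(
        auc_full=auc_full, fold_aucs=fold_aucs, auc_median=auc_median,
        band_q25=band_lo, band_q75=band_hi, sensitivity=sens,
        specificity=spec_, accuracy=acc, se=se,
        n_bootstrap=config.bootstrap_B,
    )
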