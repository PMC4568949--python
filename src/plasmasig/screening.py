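"""Per-fold differential-abundance screen.

Each protein is compared between the endpoint's clinical groups with a
two-sided equal-variance two-sample t-test on log2 abundances; p-values
are Benjamini-Hochberg adjusted across proteins within the contrast, and
candidates must pass both the FDR threshold and a linear fold-change
cutoff.  Multi-class (ordinal) endpoints are screened by running every
unordered pairwise contrast and taking the union of passing proteins.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import AbundanceMatrix, CohortError


@dataclasses.dataclass(frozen=True)
class ScreenConfig:
    """Candidate-selection thresholds: BH-adjusted p < ``fdr_threshold``
    and |log2 fold change| >= log2(``fc_threshold``)."""

    fdr_threshold: float = 0.05
    fc_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise CohortError("fdr_threshold must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise CohortError("fc_threshold must exceed 1")

    @property
    def log2fc_cutoff(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclasses.dataclass
class DifferentialResult:
    protein_id: str
    contrast: tuple[str, str]
    log2fc: float          # mean(group_b) - mean(group_a)
    p_value: float
    p_adjusted: float = np.nan
    passed: bool = False
    degenerate: bool = False  # zero pooled variance with unequal means


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise CohortError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_test(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    contrast: tuple[str, str] = ("0", "1"),
) -> list[DifferentialResult]:
    """Per-protein two-group comparison on log2 abundances.

    ``labels`` maps patient id to 0 (group a) / 1 (group b) for the
    patients in the contrast.  Returns one result per protein with
    log2fc = mean(b) - mean(a), a two-sided pooled-variance t-test
    p-value, and BH adjustment across proteins.
    """
    labels = labels.astype(int)
    ids_a = labels.index[labels == 0]
    ids_b = labels.index[labels == 1]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise CohortError("each group needs at least 2 patients")
    a = matrix.values[ids_a].to_numpy()
    b = matrix.values[ids_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a
    tt = stats.ttest_ind(b, a, axis=1, equal_var=True)
    p = np.asarray(tt.pvalue, dtype=float)
    # degenerate rows: zero pooled variance
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    degen = var0 & (log2fc != 0)
    p[var0 & (log2fc == 0)] = 1.0
    p[degen] = 0.0
    p_adj = bh_adjust(p)
    return [
        DifferentialResult(
            protein_id=pid, contrast=contrast, log2fc=float(log2fc[i]),
            p_value=float(p[i]), p_adjusted=float(p_adj[i]),
            degenerate=bool(degen[i]),
        )
        for i, pid in enumerate(matrix.protein_ids)
    ]


def select_candidates(results: list[DifferentialResult],
                      config: ScreenConfig = ScreenConfig()) -> list[str]:
    """Proteins passing the FDR and fold-change thresholds, sorted by id.

    Strict inequality at the FDR threshold; the fold-change criterion is
    |log2fc| >= log2(fc_threshold).  Sets ``passed`` on each result.
    """
    if not results:
        raise CohortError("no differential results to select from")
    cutoff = config.log2fc_cutoff
    out = set()
    for r in results:
        r.passed = (r.p_adjusted < config.fdr_threshold) and (abs(r.log2fc) >= cutoff)
        if r.passed:
            out.add(r.protein_id)
    return sorted(out)


def multigroup_candidates(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    config: ScreenConfig = ScreenConfig(),
    class_names: list[str] | None = None,
) -> tuple[list[str], list[DifferentialResult]]:
    """Union-of-pairwise screen for ordinal endpoints.

    Runs :func:`two_group_test` for every unordered class pair (BH within
    each contrast); a protein is a candidate if it passes in any pair.
    For two classes this reduces exactly to the single binary screen.
    """
    labels = labels.astype(int)
    classes = sorted(labels.unique())
    names = class_names or [str(c) for c in classes]
    candidates: set[str] = set()
    all_results: list[DifferentialResult] = []
    for ca, cb in itertools.combinations(classes, 2):
        sub = labels[labels.isin([ca, cb])]
        sub = (sub == cb).astype(int)
        res = two_group_test(matrix, sub, contrast=(names[classes.index(ca)],
                                                    names[classes.index(cb)]))
        candidates.update(select_candidates(res, config))
        all_results.extend(res)
    return sorted(candidates), all_results


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Screen results as a tidy table (exportable as TSV)."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "contrast": [f"{r.contrast[0]}_vs_{r.contrast[1]}" for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "passed": [r.passed for r in results],
        }
    )
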