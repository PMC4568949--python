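"""Synthetic plasma-proteomic cohort generator.

Emulates the statistical structure the discovery pipeline assumes: a
~202-patient colorectal-cancer cohort with fixed clinical marginals, a
proteins x patients log2 abundance matrix with optional planted
endpoint-associated effects, stage-dependent Weibull proportional-hazards
survival with administrative and dropout censoring, and left-censored
(limit-of-detection) missingness.  Categorical marginals are assigned
exactly, not sampled, so configured counts are reproduced verbatim; the
only joint constraint enforced is the logical one, stage IV <=> M1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    GRADES, REGIONS, STAGES, AbundanceMatrix, CohortError, validate_cohort,
    write_clinical,
)

#: stage-conditional distribution of the T category (primary tumour
#: invasion), loosely following the cohort's cross-tabulation
_T_BY_STAGE = {
    "I": ([1, 2], [13 / 41, 28 / 41]),
    "II": ([3], [1.0]),
    "III": ([2, 3, 4], [5 / 51, 41 / 51, 5 / 51]),
    "IV": ([2, 3, 4], [6 / 29, 19 / 29, 4 / 29]),
}

#: baseline probability of surviving 5 years, by stage, with all planted
#: protein effects at zero
_S5_BY_STAGE = {"I": 0.85, "II": 0.75, "III": 0.60, "IV": 0.30}


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A protein effect planted for one endpoint.

    For group endpoints ``effect`` is an additive log2 abundance shift of
    the case (or, for ordinal endpoints, a shift scaled linearly with the
    class index).  For the survival endpoint it is the log hazard ratio per
    log2 abundance unit.
    """

    protein_id: str
    endpoint: str
    effect: float


@dataclasses.dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Count defaults reproduce the study cohort's clinical marginals; the
    survival baseline is a per-stage Weibull proportional-hazards model,
    censored administratively at ``horizon`` years with an exponential
    dropout process.
    """

    n_patients: int = 202
    n_proteins: int = 80
    stage_counts: tuple[int, int, int, int] = (43, 58, 49, 52)
    gender_counts: tuple[int, int] = (89, 113)   # female, male
    age_center: float = 67.0
    age_sd: float = 11.5
    region_counts: tuple[int, int] = (131, 71)   # colon (C18+C19), rectal (C20)
    m_counts: tuple[int, int] = (150, 52)        # M0, M1
    grade_counts: tuple[int, int, int] = (32, 132, 30)  # G1, G2, G3; rest missing
    protein_mean: float = 0.0
    protein_sd: float = 1.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    weibull_shape: float = 1.2
    horizon: float = 8.0
    dropout_rate: float = 0.015
    lod_quantile: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_patients
        for name, counts in [
            ("stage_counts", self.stage_counts),
            ("gender_counts", self.gender_counts),
            ("region_counts", self.region_counts),
            ("m_counts", self.m_counts),
        ]:
            if sum(counts) != n:
                raise CohortError(f"{name} {counts} does not sum to n_patients={n}")
        if sum(self.grade_counts) > n:
            raise CohortError("grade_counts exceed n_patients")
        if self.m_counts[1] != self.stage_counts[3]:
            raise CohortError("M1 count must equal the stage IV count (stage IV <=> M1)")
        if not 0 <= self.lod_quantile < 1:
            raise CohortError("lod_quantile must lie in [0, 1)")
        if self.protein_sd <= 0 or self.age_sd <= 0 or self.weibull_shape <= 0:
            raise CohortError("SDs and Weibull shape must be positive")
        protein_ids = set(default_protein_ids(self.n_proteins))
        for pe in self.planted_effects:
            if pe.protein_id not in protein_ids:
                raise CohortError(f"planted effect references unknown protein {pe.protein_id!r}")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: which proteins carry which
    planted effects, the seed, and the realized group means per planted
    group-endpoint protein."""

    effects: dict[str, list[tuple[str, float]]]
    seed: int
    realized_group_means: dict[str, dict[str, list[float]]]

    def proteins_for(self, endpoint: str) -> list[str]:
        return [p for p, _ in self.effects.get(endpoint, [])]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def default_protein_ids(n_proteins: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n_proteins + 1)]


def _assign_exact(rng: np.random.Generator, values: Sequence, counts: Sequence[int],
                  n: int) -> np.ndarray:
    """Assign categorical values with exact marginal counts, in random order."""
    arr = np.repeat(np.asarray(values, dtype=object), np.asarray(counts))
    if len(arr) < n:  # pad with missing
        arr = np.concatenate([arr, np.full(n - len(arr), None, dtype=object)])
    return arr[rng.permutation(n)]


def generate_survival_times(
    linear_predictor: np.ndarray,
    shape: float,
    scale: float | np.ndarray,
    horizon: float,
    dropout_rate: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from a Weibull proportional-hazards model.

    The event hazard is the Weibull(shape, scale) baseline multiplied by
    ``exp(linear_predictor)``; the observed time is the minimum of the
    event time, an exponential dropout time (rate per year; 0 disables
    dropout) and the administrative ``horizon``; ``event`` is 1 iff the
    event time is smallest.
    """
    if shape <= 0 or np.any(np.asarray(scale) <= 0):
        raise CohortError("Weibull shape and scale must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)) or np.any(np.abs(lp) > 20):
        raise CohortError("non-finite or extreme linear predictor (|lp| > 20)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = lp.shape[0]
    # S(t) = exp(-(t/scale)^shape * e^lp)  =>  T = scale * (E / e^lp)^(1/shape)
    e = rng.exponential(size=n)
    t_event = np.asarray(scale) * (e / np.exp(lp)) ** (1.0 / shape)
    if dropout_rate > 0:
        t_drop = rng.exponential(1.0 / dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def apply_lod_missingness(matrix: AbundanceMatrix, lod_quantile: float,
                          seed: int = 0) -> AbundanceMatrix:
    """Left-censor each protein below its empirical ``lod_quantile``.

    Every value strictly below the protein's empirical quantile is set
    missing, emulating a per-protein limit of detection.  Deterministic
    given the matrix (``seed`` is accepted for interface uniformity).
    """
    if not 0 <= lod_quantile < 1:
        raise CohortError("lod_quantile must lie in [0, 1)")
    vals = matrix.values.to_numpy(copy=True)
    if lod_quantile > 0:
        thresh = np.quantile(vals, lod_quantile, axis=1, keepdims=True)
        vals[vals < thresh] = np.nan
    return AbundanceMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, AbundanceMatrix, SyntheticTruth]:
    """Generate (clinical table, abundance matrix, ground truth).

    Clinical marginals are assigned exactly per the configuration; protein
    log2 abundances are baseline + planted group shifts + Gaussian noise;
    survival times follow a stage-specific Weibull baseline with the
    planted survival effects entering the log hazard linearly in protein
    abundance; missingness is then applied per ``lod_quantile``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"PT{i:04d}" for i in range(1, n + 1)]

    # -- clinical fields with exact marginals ------------------------------
    stage = np.repeat(STAGES, config.stage_counts)  # kept ordered; see m below
    order = rng.permutation(n)
    stage = stage[order]
    m = (stage == "IV").astype(int)  # logical constraint stage IV <=> M1
    gender = _assign_exact(rng, ["female", "male"], config.gender_counts, n)
    grade = _assign_exact(rng, GRADES, config.grade_counts, n)
    # region: split colon exactly into C18/C19 (4:1), rectal is C20
    n_colon, n_rect = config.region_counts
    n_c19 = n_colon // 5
    region = _assign_exact(rng, REGIONS, [n_colon - n_c19, n_c19, n_rect], n)
    age = np.clip(rng.normal(config.age_center, config.age_sd, size=n), 30, 95)
    t_cat = np.empty(n, dtype=int)
    for s, (vals, probs) in _T_BY_STAGE.items():
        idx = np.where(stage == s)[0]
        t_cat[idx] = rng.choice(vals, size=len(idx), p=probs)
    n_cat = np.where(np.isin(stage, ["I", "II"]), 0, 1)

    # -- abundance matrix --------------------------------------------------
    protein_ids = default_protein_ids(config.n_proteins)
    vals = rng.normal(config.protein_mean, config.protein_sd,
                      size=(config.n_proteins, n))
    group_membership = {
        "localization": (region == "C20").astype(float),
        "dissemination": m.astype(float),
        "stage": pd.Series(stage).map({s: i for i, s in enumerate(STAGES)}).to_numpy() / 3.0,
        "grade": pd.Series(grade).map({g: i for i, g in enumerate(GRADES)}).fillna(0).to_numpy() / 2.0,
    }
    effects: dict[str, list[tuple[str, float]]] = {}
    realized: dict[str, dict[str, list[float]]] = {}
    prot_index = {p: i for i, p in enumerate(protein_ids)}
    for pe in config.planted_effects:
        effects.setdefault(pe.endpoint, []).append((pe.protein_id, pe.effect))
        if pe.endpoint in group_membership:
            vals[prot_index[pe.protein_id]] += pe.effect * group_membership[pe.endpoint]

    # -- survival ----------------------------------------------------------
    lp = np.zeros(n)
    for pid, eff in effects.get("survival5y", []):
        lp += eff * vals[prot_index[pid]]
    lp = np.clip(lp, -19.9, 19.9)
    shape = config.weibull_shape
    scale = np.empty(n)
    for s in STAGES:
        # scale such that S(5y) = _S5_BY_STAGE[s] at zero linear predictor
        scale[stage == s] = 5.0 / (-np.log(_S5_BY_STAGE[s])) ** (1.0 / shape)
    os_time, os_event = generate_survival_times(
        lp, shape, scale, config.horizon, config.dropout_rate, rng
    )

    for endpoint, lst in effects.items():
        if endpoint in group_membership:
            memb = group_membership[endpoint]
            realized[endpoint] = {
                pid: [float(vals[prot_index[pid]][memb == 0].mean()),
                      float(vals[prot_index[pid]][memb > 0].mean())]
                for pid, _ in lst
            }

    cohort = validate_cohort(pd.DataFrame({
        "patient_id": ids,
        "age": np.round(age, 1),
        "gender": gender,
        "stage": stage,
        "t": t_cat,
        "n": n_cat,
        "m": m,
        "grade": grade,
        "region": region,
        "os_time": np.round(os_time, 4),
        "os_event": os_event,
    }))
    matrix = AbundanceMatrix(pd.DataFrame(vals, index=protein_ids, columns=ids))
    if config.lod_quantile > 0:
        matrix = apply_lod_missingness(matrix, config.lod_quantile)
    truth = SyntheticTruth(effects=effects, seed=config.seed,
                           realized_group_means=realized)
    return cohort, matrix, truth


# ---------------------------------------------------------------------------
# scenario helpers
# ---------------------------------------------------------------------------

def survival_signature_config(n_signal: int = 6, magnitude: float = 0.8,
                              seed: int = 0, **kwargs) -> SimConfig:
    """Default signal scenario: ``n_signal`` prognostic proteins with
    alternating-sign log hazard ratios of ``magnitude`` per log2 unit."""
    ids = default_protein_ids(kwargs.get("n_proteins", 80))
    eff = tuple(
        PlantedEffect(ids[i], "survival5y", magnitude * (1 if i % 2 == 0 else -1))
        for i in range(n_signal)
    )
    return SimConfig(planted_effects=eff, seed=seed, **kwargs)


def binary_signature_config(endpoint: str = "localization", n_signal: int = 5,
                            shift: float = 0.8, seed: int = 0, **kwargs) -> SimConfig:
    """Binary-endpoint signal scenario: ``n_signal`` proteins shifted by
    ``shift`` log2 units (alternating sign) in the case group."""
    ids = default_protein_ids(kwargs.get("n_proteins", 80))
    eff = tuple(
        PlantedEffect(ids[i], endpoint, shift * (1 if i % 2 == 0 else -1))
        for i in range(n_signal)
    )
    return SimConfig(planted_effects=eff, seed=seed, **kwargs)


def write_cohort(outdir: str | Path, cohort: pd.DataFrame,
                 matrix: AbundanceMatrix, truth: SyntheticTruth) -> None:
    """Write cohort CSV, abundance TSV and truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_clinical(cohort, outdir / "clinical.csv")
    matrix.to_tsv(outdir / "abundance.tsv")
    truth.to_json(outdir / "truth.json")
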