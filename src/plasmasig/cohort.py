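"""Clinical cohort and protein-abundance containers.

The analysis operates on two aligned tables: a clinical annotation table
(one row per patient: demographics, TNM staging, tumour grade and region,
overall survival) and a proteins x patients matrix of log2 relative
abundances with left-censored missing values.  This module reads and
validates both, performs limit-of-detection (LOD) imputation, and derives
the typed endpoint labels the downstream screening and modelling stages
consume.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "patient_id", "age", "gender", "stage", "t", "n", "m",
    "grade", "region", "os_time", "os_event",
]

STAGES = ["I", "II", "III", "IV"]
GRADES = ["G1", "G2", "G3"]
REGIONS = ["C18", "C19", "C20"]

#: clinical covariates forced into survival models, in model order
FORCED_COVARIATES = ["age", "gender", "stage"]


class CohortError(ValueError):
    """Raised for invalid clinical tables or abundance matrices."""


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table and return it with canonical dtypes.

    Checks patient-id uniqueness, non-negative survival times, categorical
    domains, and stage/metastasis consistency (stage IV <=> M1 whenever both
    fields are present).
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"clinical table missing columns: {missing}")
    table = table.copy()
    if table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortError(f"duplicate patient id: {dup!r}")
    if (table["os_time"] < 0).any():
        raise CohortError("negative os_time")
    if not table["os_event"].isin([0, 1]).all():
        raise CohortError("os_event must be 0/1")
    if not table["gender"].isin(["female", "male"]).all():
        raise CohortError("gender must be 'female' or 'male'")
    if not table["stage"].isin(STAGES).all():
        raise CohortError(f"stage must be one of {STAGES}")
    if not table["region"].isin(REGIONS).all():
        raise CohortError(f"region must be one of {REGIONS}")
    bad_grade = ~(table["grade"].isin(GRADES) | table["grade"].isna())
    if bad_grade.any():
        raise CohortError(f"grade must be one of {GRADES} or missing")
    both = table["m"].notna()
    m1 = table.loc[both, "m"].astype(float) == 1
    iv = table.loc[both, "stage"] == "IV"
    if (m1 != iv).any():
        raise CohortError("stage IV must coincide with m=1")
    table = table.set_index("patient_id", drop=False)
    table.index.name = None
    return table


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical CSV (comma-separated, UTF-8)."""
    table = pd.read_csv(path, na_values=["", "NA"])
    return validate_cohort(table)


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    table[CLINICAL_COLUMNS].to_csv(path, index=False)


def stage_numeric(table: pd.DataFrame) -> pd.Series:
    """Stage encoded 1-4 as a single linear term."""
    return table["stage"].map({s: i + 1 for i, s in enumerate(STAGES)}).astype(float)


def gender_numeric(table: pd.DataFrame) -> pd.Series:
    """Gender encoded 1 = male, 0 = female."""
    return (table["gender"] == "male").astype(float)


def clinical_design(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the forced clinical covariates (age, gender, stage)."""
    return pd.DataFrame(
        {
            "age": table["age"].astype(float),
            "gender": gender_numeric(table),
            "stage": stage_numeric(table),
        },
        index=table.index,
    )


# ---------------------------------------------------------------------------
# abundance matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AbundanceMatrix:
    """Proteins x patients matrix of log2 relative abundances.

    Missing values are NaN in :attr:`values`; the missingness mask is
    therefore implicit.  Rows are proteins, columns are patients.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CohortError(f"duplicate protein id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise CohortError(f"duplicate patient id: {dup!r}")
        self.values = self.values.astype(float)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask, True where the value is missing."""
        return self.values.isna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def impute_lod(self) -> "AbundanceMatrix":
        """Replace missing values by the protein's minimum observed value.

        The minimum observed abundance of a protein across all samples is
        taken as its limit of detection; every missing value of that protein
        is imputed with it.  Observed values are unchanged and the operation
        is idempotent.
        """
        vals = self.values.to_numpy(copy=True)
        all_missing = np.isnan(vals).all(axis=1)
        if all_missing.any():
            pid = self.values.index[np.where(all_missing)[0][0]]
            raise CohortError(f"protein {pid!r} has no observed values")
        row_min = np.nanmin(vals, axis=1)
        idx = np.where(np.isnan(vals))
        vals[idx] = row_min[idx[0]]
        return AbundanceMatrix(
            pd.DataFrame(vals, index=self.values.index, columns=self.values.columns)
        )

    def samples(self) -> pd.DataFrame:
        """Patients x proteins view (design-matrix orientation)."""
        return self.values.T

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="")


def read_abundance_matrix(path: str | Path) -> AbundanceMatrix:
    """Read a TSV/CSV abundance matrix (first column protein ids, header
    row patient ids, empty or NA cells = missing)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["", "NA"])
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CohortError("empty abundance matrix")
    for col in df.columns:
        if df[col].dtype == object:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise CohortError(f"non-numeric cell in column {col!r}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return AbundanceMatrix(df)


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

ENDPOINT_KINDS = {
    "survival5y": "survival",
    "localization": "binary",
    "dissemination": "binary",
    "stage": "ordinal",
    "grade": "ordinal",
}


@dataclasses.dataclass(frozen=True)
class EndpointSpec:
    """A clinical endpoint and how it is derived from the cohort table.

    ``survival5y`` is overall survival with a 5-year screening horizon;
    ``localization`` contrasts colon (C18+C19) against rectal (C20) tumours;
    ``dissemination`` contrasts localized (M0) against metastatic (M1)
    disease; ``stage`` and ``grade`` are ordered multi-class endpoints.
    """

    name: str
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.name not in ENDPOINT_KINDS:
            raise CohortError(f"unknown endpoint {self.name!r}")

    @property
    def kind(self) -> str:
        return ENDPOINT_KINDS[self.name]


@dataclasses.dataclass
class EndpointLabels:
    """Per-patient labels for one endpoint.

    For group endpoints ``y`` holds integer class codes (indexed by
    patient id) and ``classes`` names them.  For the survival endpoint
    ``time``/``event`` hold the (possibly censored) survival data for
    modelling, while ``screen_y`` holds the binary death-within-horizon
    class used by the differential screen; patients censored before the
    horizon carry ``screen_y`` NaN and are excluded from screening only.
    ``included`` marks patients participating in the endpoint at all.
    """

    spec: EndpointSpec
    included: pd.Series
    y: pd.Series | None = None
    classes: list[str] | None = None
    time: pd.Series | None = None
    event: pd.Series | None = None
    screen_y: pd.Series | None = None

    @property
    def kind(self) -> str:
        return self.spec.kind

    def included_ids(self) -> pd.Index:
        return self.included.index[self.included]

    def screen_labels(self) -> pd.Series:
        """Binary labels for the differential screen (survival: the
        death-by-horizon class restricted to uncensored-by-horizon
        patients; group endpoints: the class codes)."""
        if self.kind == "survival":
            s = self.screen_y[self.included]
            return s.dropna().astype(int)
        return self.y[self.included].astype(int)


def derive_endpoint(cohort: pd.DataFrame, spec: EndpointSpec) -> EndpointLabels:
    """Derive typed labels for ``spec`` from a validated clinical table.

    Survival: patients of stages I-III are included (stage is itself a
    forced model covariate and stage IV is the dissemination endpoint's
    case group); the screen compares death within the horizon to survival
    beyond it, ignoring patients censored before the horizon.  Grade:
    patients with missing grade are excluded.
    """
    ids = cohort.index
    if spec.name == "survival5y":
        included = cohort["stage"].isin(["I", "II", "III"])
        time = cohort["os_time"].astype(float)
        event = cohort["os_event"].astype(int)
        h = spec.horizon
        screen = pd.Series(np.nan, index=ids)
        screen[time > h] = 0.0                       # alive at horizon
        screen[(time <= h) & (event == 1)] = 1.0     # death within horizon
        labels = EndpointLabels(
            spec=spec, included=included, time=time, event=event,
            screen_y=screen, classes=["alive5y", "death5y"],
        )
    elif spec.name == "localization":
        y = cohort["region"].map({"C18": 0, "C19": 0, "C20": 1})
        labels = EndpointLabels(
            spec=spec, included=pd.Series(True, index=ids), y=y,
            classes=["colon", "rectal"],
        )
    elif spec.name == "dissemination":
        y = cohort["m"].astype(int)
        labels = EndpointLabels(
            spec=spec, included=pd.Series(True, index=ids), y=y,
            classes=["M0", "M1"],
        )
    elif spec.name == "stage":
        y = cohort["stage"].map({s: i for i, s in enumerate(STAGES)})
        labels = EndpointLabels(
            spec=spec, included=pd.Series(True, index=ids), y=y, classes=STAGES,
        )
    elif spec.name == "grade":
        y = cohort["grade"].map({g: i for i, g in enumerate(GRADES)})
        labels = EndpointLabels(
            spec=spec, included=y.notna(), y=y, classes=GRADES,
        )
    else:  # pragma: no cover - guarded by EndpointSpec
        raise CohortError(f"unknown endpoint {spec.name!r}")

    inc = labels.included
    if labels.y is not None:
        n_classes = labels.y[inc].nunique()
        if n_classes < 2:
            raise CohortError(f"endpoint {spec.name!r}: fewer than 2 classes present")
    if not inc.any():
        raise CohortError(f"endpoint {spec.name!r}: all patients excluded")
    return labels
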