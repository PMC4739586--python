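"""Patient-admission cohort container, delimited-text I/O and the exclusion cascade.

A cohort is one row per hospital admission with a binary 30-day mortality
outcome, patient covariates (age, comorbidity-history flags, a combined
sex-by-ethnicity category) and two strictly nested cluster labels: the ward
where the patient was treated and the hospital containing that ward.

The raw register extract additionally carries flags used only by the
exclusion cascade (prior heart-failure diagnosis, nursing-home facility);
:func:`apply_exclusions` turns a raw table into the analysis cohort and
records how many admissions each step removed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEX_ETH_LEVELS = (
    "swedish_female",
    "swedish_male",
    "nonswedish_female",
    "nonswedish_male",
)
HOSPITAL_TYPES = ("regional", "provincial", "municipal")
FACILITY_KINDS = ("hospital", "nursing_home")

#: comorbidity-history indicator columns all carry this prefix
COMORBIDITY_PREFIX = "cm_"

#: ICD-10 history groups entering the risk-score candidate set
DEFAULT_COMORBIDITIES = (
    "cerebral_arteries",
    "arrhythmia",
    "hypertension",
    "ischemic_heart",
    "varicose",
    "peripheral_vascular",
    "acute_mi",
    "other_heart",
    "respiratory",
    "digestive",
    "diabetes",
    "infectious",
    "cancer",
    "lung_cancer",
    "chronic_lower_respiratory",
    "immunity",
    "mental",
    "injury",
)

REQUIRED_COLUMNS = ("patient_id", "death30", "age", "sex_eth", "ward_id", "hospital_id")
OPTIONAL_COLUMNS = ("hospital_type", "prior_hf", "facility_kind")

EXCLUSION_STEPS = ("age_window", "prior_hf", "nursing_home", "small_hospital")


class CohortError(Exception):
    """Base class for cohort-layer failures."""


class SchemaError(CohortError):
    """A required column is absent or mis-mapped."""


class RowValidationError(CohortError):
    """A row holds an out-of-domain value; carries the offending row index."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = rows


class NestingError(CohortError):
    """A ward identifier appears under more than one hospital."""


class EmptyCohortError(CohortError):
    """The exclusion cascade removed every admission."""


def _check_binary(df: pd.DataFrame, col: str) -> None:
    vals = df[col]
    if vals.isna().any():
        bad = df.index[vals.isna()][:5].tolist()
        raise RowValidationError(f"column {col!r} has missing values (rows {bad})", rows=bad)
    ok = vals.isin((0, 1))
    if not ok.all():
        bad = df.index[~ok][:5].tolist()
        raise RowValidationError(
            f"column {col!r} must be 0/1; offending rows {bad}", rows=bad
        )


@dataclasses.dataclass
class CohortTable:
    """An admissions table plus its comorbidity column list and provenance.

    Parameters
    ----------
    data
        One row per admission.  Required columns: ``patient_id``, ``death30``,
        ``age``, ``sex_eth``, ``ward_id``, ``hospital_id``.  Optional:
        ``hospital_type``, ``prior_hf``, ``facility_kind``.  Comorbidity flags
        carry the ``cm_`` prefix.
    provenance
        Exclusion-cascade bookkeeping (raw count, per-step removals, retained
        count); empty for a table that never passed through the cascade.
    """

    data: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def comorbidity_cols(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(COMORBIDITY_PREFIX)]

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_wards(self) -> int:
        return self.data["ward_id"].nunique()

    @property
    def n_hospitals(self) -> int:
        return self.data["hospital_id"].nunique()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.provenance))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing from cohort table")
        _check_binary(df, "death30")
        for col in self.comorbidity_cols:
            _check_binary(df, col)
        if "prior_hf" in df.columns:
            _check_binary(df, "prior_hf")
        if df["age"].isna().any():
            bad = df.index[df["age"].isna()][:5].tolist()
            raise RowValidationError(f"missing age values (rows {bad})", rows=bad)
        bad_sex = ~df["sex_eth"].isin(SEX_ETH_LEVELS)
        if bad_sex.any():
            raise RowValidationError(
                f"unknown sex_eth level(s) {sorted(df.loc[bad_sex, 'sex_eth'].unique())}",
                rows=df.index[bad_sex][:5].tolist(),
            )
        if "hospital_type" in df.columns:
            bad_t = ~df["hospital_type"].isin(HOSPITAL_TYPES)
            if bad_t.any():
                raise RowValidationError(
                    f"unknown hospital_type {sorted(df.loc[bad_t, 'hospital_type'].unique())}",
                    rows=df.index[bad_t][:5].tolist(),
                )
        if "facility_kind" in df.columns:
            bad_f = ~df["facility_kind"].isin(FACILITY_KINDS)
            if bad_f.any():
                raise RowValidationError(
                    f"unknown facility_kind {sorted(df.loc[bad_f, 'facility_kind'].unique())}",
                    rows=df.index[bad_f][:5].tolist(),
                )
        # strict nesting: every ward under exactly one hospital
        nh = df.groupby("ward_id")["hospital_id"].nunique()
        if (nh > 1).any():
            offenders = nh.index[nh > 1].tolist()
            raise NestingError(
                f"ward(s) {offenders} appear under more than one hospital"
            )

    # -- I/O -------------------------------------------------------------
    def write(self, path) -> None:
        """Write the table as CSV with header (identifiers kept as strings)."""
        self.data.to_csv(path, index=False)

    def write_provenance(self, path) -> None:
        """Write the exclusion-cascade report as a small JSON flow diagram."""
        Path(path).write_text(json.dumps(self.provenance, indent=2) + "\n")


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if "columns" in schema:
        schema = schema["columns"]
    return dict(schema)


def read_cohort(path, schema=None) -> CohortTable:
    """Read a delimited-text admissions file into a :class:`CohortTable`.

    ``schema`` maps canonical column names to the file's column names, either
    as a dict or a YAML/JSON file with a ``columns:`` mapping; omitted entries
    are assumed to already use canonical names.  Identifier columns are read
    as opaque strings.
    """
    mapping = _load_schema(schema)
    df = pd.read_csv(
        path,
        dtype={
            mapping.get(c, c): str
            for c in ("patient_id", "ward_id", "hospital_id")
        },
    )
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    missing = [k for k, v in mapping.items() if v not in df.columns]
    if missing:
        raise SchemaError(
            f"mapped column(s) missing from file: "
            + ", ".join(f"{k} -> {mapping[k]!r}" for k in missing)
        )
    df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    return CohortTable(df, provenance={"source": str(path), "raw": len(df)})


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.write(path)


def apply_exclusions(
    raw: CohortTable,
    min_hospital_size: int = 50,
    age_range: tuple[int, int] = (45, 80),
) -> CohortTable:
    """Run the exclusion cascade on a raw admissions table.

    Steps, in fixed order: (1) restrict to the age window; (2) drop patients
    with a prior heart-failure diagnosis; (3) drop nursing-home admissions;
    (4) drop hospitals whose remaining patient count falls below
    ``min_hospital_size``.  The hospital-size rule is evaluated on the table
    that survives the patient-level filters, and the per-step removal counts
    are recorded in the returned table's provenance.

    Raises
    ------
    EmptyCohortError
        if no admission survives the cascade.
    """
    df = raw.data
    removed = {}

    lo, hi = age_range
    keep = df["age"].between(lo, hi)
    removed["age_window"] = int((~keep).sum())
    df = df[keep]

    if "prior_hf" in df.columns:
        keep = df["prior_hf"] == 0
        removed["prior_hf"] = int((~keep).sum())
        df = df[keep]
    else:
        removed["prior_hf"] = 0

    if "facility_kind" in df.columns:
        keep = df["facility_kind"] != "nursing_home"
        removed["nursing_home"] = int((~keep).sum())
        df = df[keep]
    else:
        removed["nursing_home"] = 0

    sizes = df.groupby("hospital_id")["patient_id"].size()
    small = sizes.index[sizes < min_hospital_size]
    keep = ~df["hospital_id"].isin(small)
    removed["small_hospital"] = int((~keep).sum())
    df = df[keep]

    if len(df) == 0:
        raise EmptyCohortError("exclusion cascade removed every admission")

    provenance = {
        "raw": raw.n_patients,
        "steps": [{"step": s, "removed": removed[s]} for s in EXCLUSION_STEPS],
        "retained": int(len(df)),
        "min_hospital_size": min_hospital_size,
        "age_range": list(age_range),
    }
    assert provenance["raw"] - sum(removed.values()) == provenance["retained"]
    return CohortTable(df.reset_index(drop=True), provenance)


def ward_volume_tertiles(cohort: CohortTable) -> pd.Series:
    """Per-admission ward-volume tertile label (1..3) from realized ward sizes.

    The ward volume is the number of cohort admissions at the ward; wards are
    cut into three groups at the tertiles of the ward-level (not
    patient-level) volume distribution, first tertile = smallest wards.
    """
    sizes = cohort.data.groupby("ward_id")["patient_id"].size()
    tert = pd.qcut(sizes.rank(method="first"), 3, labels=[1, 2, 3]).astype(int)
    return cohort.data["ward_id"].map(tert).rename("ward_volume_tertile")
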