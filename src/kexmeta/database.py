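"""Treatment-mean database: records, validation, derivation and summaries.

The unit of analysis throughout the package is the *treatment mean*: one
published group-level average (one diet within one study).  Each record
carries the response (urinary or fecal potassium excretion, g/d), candidate
predictors, and the number of animals contributing to the mean, which later
becomes the mixed-model weight.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Iterable

__all__ = [
    "PREDICTOR_FIELDS",
    "RESPONSE_FIELDS",
    "TreatmentMeanRecord",
    "StudyDatabase",
    "SummaryRow",
    "DatabaseSummary",
    "RowRejection",
    "ValidationReport",
    "DatabaseError",
    "validate_record",
    "derive_k_intake",
    "load_database",
    "write_database",
    "summarize",
]

#: candidate predictors of Y; units: kg/d except k_intake (g/d), dietary_k (% of DM)
PREDICTOR_FIELDS = ("dmi", "k_intake", "dietary_k", "water_intake", "urine_volume", "milk_yield")
#: the two response variables, g/d
RESPONSE_FIELDS = ("k_ur", "k_fa")

_NUMERIC_FIELDS = PREDICTOR_FIELDS + RESPONSE_FIELDS

#: default relative tolerance between reported K intake and DMI x dietary K x 10
K_INTAKE_TOLERANCE = 0.05


class DatabaseError(ValueError):
    """Raised for unusable inputs (unreadable file, too few studies, ...)."""


@dataclass(frozen=True)
class TreatmentMeanRecord:
    """One study-level treatment mean.

    All quantities are group means; ``n_obs`` is the number of animals behind
    the mean and serves as the model weight.  Missing measurements are None.
    """

    record_id: str
    study_id: str
    n_obs: int
    lactating: bool | None = None
    dmi: float | None = None            # dry-matter intake, kg/d
    k_intake: float | None = None       # potassium intake, g/d
    dietary_k: float | None = None      # dietary K, % of DM
    water_intake: float | None = None   # kg/d
    urine_volume: float | None = None   # kg/d
    milk_yield: float | None = None     # kg/d
    k_ur: float | None = None           # urinary K excretion, g/d
    k_fa: float | None = None           # fecal K excretion, g/d
    k_intake_derived: bool = False      # True if k_intake was filled from dmi x dietary_k
    derive_failed: bool = False         # True if derivation was requested but inputs missing

    def get(self, name: str) -> float | None:
        return getattr(self, name)


def validate_record(rec: TreatmentMeanRecord, *, k_intake_tolerance: float = K_INTAKE_TOLERANCE) -> list[str]:
    """Return a list of invariant violations (empty list = valid).

    Checks: n_obs >= 1; every present quantity strictly positive; at least one
    response present; and, when dmi, dietary_k and k_intake are all reported,
    internal consistency |k_intake - dmi*dietary_k*10| / k_intake <= tolerance.
    A k_intake the package itself derived is exact by construction and is not
    re-checked.
    """
    problems: list[str] = []
    if rec.n_obs < 1:
        problems.append(f"n_obs must be >= 1 (got {rec.n_obs})")
    for name in _NUMERIC_FIELDS:
        v = rec.get(name)
        if v is not None:
            if not math.isfinite(v):
                problems.append(f"{name} is not finite ({v})")
            elif v <= 0:
                problems.append(f"{name} must be strictly positive (got {v})")
    if rec.k_ur is None and rec.k_fa is None:
        problems.append("at least one of k_ur, k_fa must be present")
    if (
        not rec.k_intake_derived
        and rec.dmi is not None
        and rec.dietary_k is not None
        and rec.k_intake is not None
        and rec.k_intake > 0
    ):
        expected = rec.dmi * rec.dietary_k * 10.0
        rel = abs(rec.k_intake - expected) / rec.k_intake
        if rel > k_intake_tolerance:
            problems.append(
                f"k_intake={rec.k_intake:g} inconsistent with dmi x dietary_k x 10 = "
                f"{expected:g} (relative deviation {rel:.3f} > {k_intake_tolerance:g})"
            )
    return problems


def derive_k_intake(rec: TreatmentMeanRecord) -> TreatmentMeanRecord:
    """Fill a missing K intake from DMI and dietary K.

    K intake (g/d) = DMI (kg/d) x dietary K (% of DM) x 10; the factor 10
    converts kg x % to grams.  A reported k_intake is never overwritten.  If
    the inputs needed for derivation are missing the record comes back
    unchanged except for ``derive_failed=True``.
    """
    if rec.k_intake is not None:
        return rec
    if rec.dmi is None or rec.dietary_k is None:
        return replace(rec, derive_failed=True)
    return replace(rec, k_intake=rec.dmi * rec.dietary_k * 10.0, k_intake_derived=True)


@dataclass(frozen=True)
class StudyDatabase:
    """Ordered collection of treatment means grouped by study.

    ``response_name`` designates which excretion variable ('k_ur' or 'k_fa')
    this database predicts; the urinary and fecal databases are separate
    objects even when built from the same source table.
    """

    records: tuple[TreatmentMeanRecord, ...]
    response_name: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.response_name not in RESPONSE_FIELDS:
            raise DatabaseError(f"unknown response_name {self.response_name!r}; expected one of {RESPONSE_FIELDS}")
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatabaseError(f"duplicate record_id values: {dup}")
        if len(self.study_ids()) < 2:
            raise DatabaseError("a StudyDatabase needs >= 2 distinct studies (random effect undefined otherwise)")

    def study_ids(self) -> tuple[str, ...]:
        """Distinct study ids in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.study_id, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.records)

    def map_records(self, fn) -> "StudyDatabase":
        return replace(self, records=tuple(fn(r) for r in self.records))

    def complete_cases(self, predictor_name: str) -> tuple[TreatmentMeanRecord, ...]:
        """Records with both the response and the given predictor present."""
        return tuple(
            r for r in self.records
            if r.get(self.response_name) is not None and r.get(predictor_name) is not None
        )


@dataclass(frozen=True)
class RowRejection:
    row_index: int           # 0-based position in the source file (excluding header)
    record_id: str
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    rejections: tuple[RowRejection, ...] = ()

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _parse_float(cell: str, sentinel: str) -> float | None:
    cell = cell.strip()
    if cell == "" or cell == sentinel:
        return None
    return float(cell)


def _parse_bool(cell: str, sentinel: str) -> bool | None:
    cell = cell.strip().lower()
    if cell == "" or cell == sentinel.lower():
        return None
    if cell in {"true", "1", "yes", "t"}:
        return True
    if cell in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean {cell!r}")


def load_database(
    path,
    response_name: str,
    *,
    sentinel: str = "NA",
    k_intake_tolerance: float = K_INTAKE_TOLERANCE,
    provenance: str | None = None,
) -> tuple[StudyDatabase, ValidationReport]:
    """Read a treatment-mean CSV and return (validated database, rejection report).

    The file must be RFC-4180 CSV with a header row; missing cells are empty
    or the ``sentinel`` string.  Rows violating record invariants are rejected
    and listed in the report — never silently dropped.
    """
    if response_name not in RESPONSE_FIELDS:
        raise DatabaseError(f"unknown response_name {response_name!r}; expected one of {RESPONSE_FIELDS}")
    try:
        fh = open(path, newline="", encoding="utf-8")
    except OSError as exc:
        raise DatabaseError(f"cannot read {path}: {exc}") from exc
    records: list[TreatmentMeanRecord] = []
    rejections: list[RowRejection] = []
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise DatabaseError(f"{path}: missing header row with at least record_id, study_id, n_obs")
        for i, row in enumerate(reader):
            rid = (row.get("record_id") or f"row{i}").strip()
            try:
                rec = TreatmentMeanRecord(
                    record_id=rid,
                    study_id=(row.get("study_id") or "").strip(),
                    n_obs=int(float(row.get("n_obs") or "0")),
                    lactating=_parse_bool(row.get("lactating", ""), sentinel),
                    **{
                        name: _parse_float(row.get(name, ""), sentinel)
                        for name in _NUMERIC_FIELDS
                    },
                )
            except ValueError as exc:
                rejections.append(RowRejection(i, rid, (f"unparseable row: {exc}",)))
                continue
            problems = validate_record(rec, k_intake_tolerance=k_intake_tolerance)
            if problems:
                rejections.append(RowRejection(i, rid, tuple(problems)))
            else:
                records.append(rec)
    studies = {r.study_id for r in records}
    if len(studies) < 2:
        raise DatabaseError(
            f"{path}: only {len(studies)} distinct study after validation; >= 2 required"
        )
    db = StudyDatabase(
        records=tuple(records),
        response_name=response_name,
        provenance=provenance if provenance is not None else f"loaded from {path}",
    )
    return db, ValidationReport(tuple(rejections))


_CSV_COLUMNS = ("record_id", "study_id", "n_obs", "lactating") + _NUMERIC_FIELDS


def write_database(db: StudyDatabase, path) -> None:
    """Write the database in the same CSV dialect ``load_database`` reads.

    Floats are written with ``repr`` so numeric fields round-trip exactly.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in db.records:
            row: list[str] = [r.record_id, r.study_id, str(r.n_obs)]
            row.append("" if r.lactating is None else str(r.lactating).lower())
            for name in _NUMERIC_FIELDS:
                v = r.get(name)
                row.append("" if v is None else repr(float(v)))
            writer.writerow(row)


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one variable over its non-missing values."""

    variable: str
    n: int
    mean: float | None
    sd: float | None     # sample SD (n-1); None when n < 2
    min: float | None
    max: float | None
    cv_pct: float | None  # 100 * sd / mean

    @property
    def degenerate(self) -> bool:
        return self.n < 2


@dataclass(frozen=True)
class DatabaseSummary:
    rows: tuple[SummaryRow, ...]
    #: mean response / mean K intake x 100 — the share of consumed K excreted
    #: by the database's route (urine or feces); None when K intake is absent.
    excretion_share_pct: float | None

    def row(self, variable: str) -> SummaryRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


def summarize(db: StudyDatabase, variables: Iterable[str] | None = None) -> DatabaseSummary:
    """Descriptive statistics per variable, plus the excretion share of intake.

    Means, sample SDs (n-1 denominator), min, max and CV are computed over
    non-missing values only.  Variables with no data yield an n=0 row with the
    moments undefined; a single value yields mean=min=max with SD undefined.
    The result does not depend on record order.
    """
    if variables is None:
        variables = (db.response_name,) + PREDICTOR_FIELDS
    valid = set(_NUMERIC_FIELDS) | {"n_obs"}
    rows: list[SummaryRow] = []
    for name in variables:
        if name not in valid:
            raise KeyError(f"unknown variable {name!r}")
        vals = [float(r.get(name)) for r in db.records if r.get(name) is not None]
        n = len(vals)
        if n == 0:
            rows.append(SummaryRow(name, 0, None, None, None, None, None))
            continue
        mean = math.fsum(vals) / n
        if n >= 2:
            sd = math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / (n - 1))
            cv = 100.0 * sd / mean if mean != 0 else None
        else:
            sd = None
            cv = None
        rows.append(SummaryRow(name, n, mean, sd, min(vals), max(vals), cv))
    resp_vals = [float(r.get(db.response_name)) for r in db.records if r.get(db.response_name) is not None]
    ki_vals = [float(r.k_intake) for r in db.records if r.k_intake is not None]
    share = None
    if resp_vals and ki_vals:
        share = 100.0 * (math.fsum(resp_vals) / len(resp_vals)) / (math.fsum(ki_vals) / len(ki_vals))
    return DatabaseSummary(tuple(rows), share)
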