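"""Case schema, validation, file format and model encodings.

A *case* is one restored posterior tooth: a 43-attribute record in which
attributes 1-41 form the problem descriptor (patient demographics, habits
and sicknesses; tooth identity and restoration history) and attributes
42-43 are the solution (the longevity in years of the restoration that was
placed, and its material, amalgam or composite).

Restorations that have not failed by the reference date are right-censored:
their observed longevity is the time from placement to the reference date,
and they carry ``censored=True``.  Censored durations are used as-is in
averages and model training; the flag is retained so stricter handling can
be layered on later.

Dates are ISO-8601 in files and are converted to fractional years with a
365.25-day year everywhere internally; no model encoding ever sees a raw
calendar date, only durations derived from them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

AMALGAM = "amalgam"
COMPOSITE = "composite"
RESTORATION_TYPES = (AMALGAM, COMPOSITE)

#: dental sicknesses scored 0 (absent) or 1-10 (present, by severity)
DENTAL_SICKNESSES = (
    "gingivitis",
    "abrasion",
    "attrition",
    "amelogenesis",
    "dentinogenesis",
    "pressed_dental",
    "multicaries",
    "other_dental_sickness",
)

#: systemic / patient-level conditions recorded as yes/no
PATIENT_SICKNESSES = (
    "diabetes",
    "high_blood_pressure",
    "cardiac_disease",
    "infectious_disease",
    "liver_complaint",
    "aids",
    "allergic_pharmacology",
    "allergic_antibiotic",
    "allergic_analgesic",
    "allergic_anaesthetic",
    "allergic_metal",
    "allergic_latex",
    "mental_illness",
    "epilepsy",
    "malignant_tumors",
    "surgical_operation",
    "family_history",
)

FAILURE_FLAGS = (
    "failure_fracture_restoration",
    "failure_fracture_tooth",
    "failure_accident",
    "failure_caries",
)

AttributeKind = Literal["identifier", "boolean", "ordinal_1_10", "nominal", "date", "real"]
AttributeRole = Literal["problem", "solution"]


@dataclass(frozen=True)
class AttributeSpec:
    """One of the 43 case attributes."""

    name: str
    index: int  # 1-based position in the case schema
    kind: AttributeKind
    role: AttributeRole


def _build_schema() -> tuple[AttributeSpec, ...]:
    specs: list[AttributeSpec] = []
    i = 1

    def add(name: str, kind: AttributeKind, role: AttributeRole = "problem") -> None:
        nonlocal i
        specs.append(AttributeSpec(name, i, kind, role))
        i += 1

    add("patient_number", "identifier")
    add("sex", "nominal")
    add("smoke", "boolean")
    add("drink", "boolean")
    add("date_of_birth", "date")
    for s in DENTAL_SICKNESSES:
        add(s, "ordinal_1_10")
    for s in PATIENT_SICKNESSES:
        add(s, "boolean")
    add("tooth_number", "nominal")
    add("prior_restoration_date", "date")
    add("prior_restoration_longevity", "real")
    add("prior_restoration_type", "nominal")
    add("restoration_level", "ordinal_1_10")
    for f in FAILURE_FLAGS:
        add(f, "boolean")
    add("aesthetic_importance", "boolean")
    add("restoration_date", "date")
    add("restoration_longevity", "real", "solution")
    add("restoration_type", "nominal", "solution")
    return tuple(specs)


#: the full 43-attribute schema, in attribute-index order
SCHEMA: tuple[AttributeSpec, ...] = _build_schema()
assert len(SCHEMA) == 43
assert all(s.role == ("solution" if s.index >= 42 else "problem") for s in SCHEMA)


class CaseValidationError(ValueError):
    """A cell or row violates the case schema."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        where = ""
        if row is not None:
            where += f" (row {row}"
            if column is not None:
                where += f", column '{column}'"
            where += ")"
        elif column is not None:
            where = f" (column '{column}')"
        super().__init__(message + where)


class SchemaError(ValueError):
    """The case-base file header does not match the schema."""


@dataclass
class Case:
    """One dental-restoration record (one restored tooth)."""

    patient_number: int
    sex: str
    smoke: bool
    drink: bool
    date_of_birth: dt.date
    # dental sickness severities: 0 = absent, 1-10 = present severity
    gingivitis: int
    abrasion: int
    attrition: int
    amelogenesis: int
    dentinogenesis: int
    pressed_dental: int
    multicaries: int
    other_dental_sickness: int
    diabetes: bool
    high_blood_pressure: bool
    cardiac_disease: bool
    infectious_disease: bool
    liver_complaint: bool
    aids: bool
    allergic_pharmacology: bool
    allergic_antibiotic: bool
    allergic_analgesic: bool
    allergic_anaesthetic: bool
    allergic_metal: bool
    allergic_latex: bool
    mental_illness: bool
    epilepsy: bool
    malignant_tumors: bool
    surgical_operation: bool
    family_history: bool
    tooth_number: int
    prior_restoration_date: dt.date
    prior_restoration_longevity: float
    prior_restoration_type: str
    restoration_level: int
    failure_fracture_restoration: bool
    failure_fracture_tooth: bool
    failure_accident: bool
    failure_caries: bool
    aesthetic_importance: bool
    restoration_date: dt.date
    restoration_longevity: float
    restoration_type: str
    censored: bool

    @property
    def key(self) -> tuple[int, int, dt.date]:
        """Unique case identifier: patient, tooth and placement date."""
        return (self.patient_number, self.tooth_number, self.restoration_date)

    @property
    def restoration_year(self) -> int:
        return self.restoration_date.year


def validate_case(case: Case, reference_date: dt.date, row: int | None = None) -> None:
    """Raise :class:`CaseValidationError` if ``case`` violates the schema."""

    def err(msg: str, col: str) -> None:
        raise CaseValidationError(msg, row=row, column=col)

    if case.sex not in ("male", "female"):
        err(f"sex must be male/female, got {case.sex!r}", "sex")
    if not 1 <= case.tooth_number <= 32:
        err(f"tooth number {case.tooth_number} outside [1, 32]", "tooth_number")
    if not 1 <= case.restoration_level <= 10:
        err(f"restoration level {case.restoration_level} outside [1, 10]", "restoration_level")
    for s in DENTAL_SICKNESSES:
        v = getattr(case, s)
        if not 0 <= v <= 10:
            err(f"severity {v} outside [0, 10]", s)
    for t_col in ("prior_restoration_type", "restoration_type"):
        if getattr(case, t_col) not in RESTORATION_TYPES:
            err(f"restoration type must be amalgam/composite, got {getattr(case, t_col)!r}", t_col)
    if case.restoration_longevity < 0:
        err(f"longevity {case.restoration_longevity} is negative", "restoration_longevity")
    if case.prior_restoration_longevity < 0:
        err(
            f"longevity {case.prior_restoration_longevity} is negative",
            "prior_restoration_longevity",
        )
    if case.date_of_birth >= case.restoration_date:
        err("date of birth is not before the restoration date", "date_of_birth")
    if case.prior_restoration_date > case.restoration_date:
        err("prior restoration date is after the current restoration date", "prior_restoration_date")
    if case.restoration_date > reference_date:
        err("restoration date is after the reference date", "restoration_date")


@dataclass
class CaseBase:
    """An ordered collection of validated cases plus the reference date.

    The reference date is the "present" against which censored longevities
    are measured.  Case keys (patient, tooth, restoration date) are unique.
    """

    cases: list[Case]
    reference_date: dt.date

    def __post_init__(self) -> None:
        keys = [c.key for c in self.cases]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise CaseValidationError(f"duplicate case key {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def __getitem__(self, i: int) -> Case:
        return self.cases[i]

    def subset(self, indices: Iterable[int]) -> "CaseBase":
        return CaseBase([self.cases[i] for i in indices], self.reference_date)

    def longevities(self) -> np.ndarray:
        return np.array([c.restoration_longevity for c in self.cases], dtype=float)

    def types(self) -> np.ndarray:
        return np.array([c.restoration_type for c in self.cases], dtype=object)

    def years(self) -> np.ndarray:
        return np.array([c.restoration_year for c in self.cases], dtype=int)


def compute_longevity(
    restoration_date: dt.date, end_date: dt.date, failed: bool
) -> tuple[float, bool]:
    """Longevity in fractional years between placement and failure/present.

    ``end_date`` is the failure date for failed restorations and the
    reference ("present") date for surviving ones, in which case the result
    is right-censored.
    """
    if end_date < restoration_date:
        raise ValueError(
            f"end date {end_date.isoformat()} precedes restoration date "
            f"{restoration_date.isoformat()}"
        )
    years = (end_date - restoration_date).days / DAYS_PER_YEAR
    return years, (not failed)


# ---------------------------------------------------------------------------
# CSV case-base format
# ---------------------------------------------------------------------------
#
# UTF-8, comma-separated, header row.  One column per attribute in schema
# order, except that each dental sickness occupies two columns: a yes/no
# flag and a severity column that is empty when the flag is "no".  A final
# "failed" yes/no column records whether the restoration failed (failed=no
# means right-censored).

def _csv_columns() -> list[str]:
    cols: list[str] = []
    for spec in SCHEMA:
        if spec.name in DENTAL_SICKNESSES:
            cols.append(spec.name)
            cols.append(spec.name + "_severity")
        else:
            cols.append(spec.name)
    cols.append("failed")
    return cols


CSV_COLUMNS = _csv_columns()

_BOOL_FIELDS = ("smoke", "drink") + PATIENT_SICKNESSES + FAILURE_FLAGS + ("aesthetic_importance",)
_DATE_FIELDS = ("date_of_birth", "prior_restoration_date", "restoration_date")


def _parse_bool(raw: str, row: int, col: str) -> bool:
    if raw == "yes":
        return True
    if raw == "no":
        return False
    raise CaseValidationError(f"expected yes/no, got {raw!r}", row=row, column=col)


def _parse_date(raw: str, row: int, col: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw)
    except ValueError:
        raise CaseValidationError(f"invalid ISO date {raw!r}", row=row, column=col) from None


def _parse_int(raw: str, row: int, col: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise CaseValidationError(f"expected an integer, got {raw!r}", row=row, column=col) from None


def _parse_float(raw: str, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise CaseValidationError(f"expected a number, got {raw!r}", row=row, column=col) from None


def _row_to_case(raw: dict[str, str], reference_date: dt.date, row: int) -> Case:
    def cell(col: str, required: bool = True) -> str:
        v = raw.get(col, "")
        v = "" if v is None else str(v).strip()
        if required and v == "":
            raise CaseValidationError("cell is empty", row=row, column=col)
        return v

    kwargs: dict = {}
    kwargs["patient_number"] = _parse_int(cell("patient_number"), row, "patient_number")
    kwargs["sex"] = cell("sex")
    for col in _BOOL_FIELDS:
        kwargs[col] = _parse_bool(cell(col), row, col)
    for col in _DATE_FIELDS:
        kwargs[col] = _parse_date(cell(col), row, col)
    for s in DENTAL_SICKNESSES:
        flag = _parse_bool(cell(s), row, s)
        sev_raw = cell(s + "_severity", required=False)
        if flag:
            if sev_raw == "":
                raise CaseValidationError(
                    "severity required when the flag is yes", row=row, column=s + "_severity"
                )
            sev = _parse_int(sev_raw, row, s + "_severity")
            if not 1 <= sev <= 10:
                raise CaseValidationError(
                    f"severity {sev} outside [1, 10]", row=row, column=s + "_severity"
                )
        else:
            if sev_raw != "":
                raise CaseValidationError(
                    "severity must be empty when the flag is no", row=row, column=s + "_severity"
                )
            sev = 0
        kwargs[s] = sev
    kwargs["tooth_number"] = _parse_int(cell("tooth_number"), row, "tooth_number")
    kwargs["prior_restoration_longevity"] = _parse_float(
        cell("prior_restoration_longevity"), row, "prior_restoration_longevity"
    )
    kwargs["prior_restoration_type"] = cell("prior_restoration_type")
    kwargs["restoration_level"] = _parse_int(cell("restoration_level"), row, "restoration_level")
    kwargs["restoration_type"] = cell("restoration_type")

    failed = _parse_bool(cell("failed"), row, "failed")
    kwargs["censored"] = not failed
    if failed:
        kwargs["restoration_longevity"] = _parse_float(
            cell("restoration_longevity"), row, "restoration_longevity"
        )
    else:
        # censored: duration runs to the present (reference) date
        longevity, _ = compute_longevity(kwargs["restoration_date"], reference_date, failed=False)
        kwargs["restoration_longevity"] = longevity

    case = Case(**kwargs)
    validate_case(case, reference_date, row=row)
    return case


def _case_to_row(case: Case) -> dict[str, str]:
    def b(v: bool) -> str:
        return "yes" if v else "no"

    row: dict[str, str] = {
        "patient_number": str(case.patient_number),
        "sex": case.sex,
        "tooth_number": str(case.tooth_number),
        "prior_restoration_longevity": repr(case.prior_restoration_longevity),
        "prior_restoration_type": case.prior_restoration_type,
        "restoration_level": str(case.restoration_level),
        "restoration_longevity": repr(case.restoration_longevity),
        "restoration_type": case.restoration_type,
        "failed": b(not case.censored),
    }
    for col in _BOOL_FIELDS:
        row[col] = b(getattr(case, col))
    for col in _DATE_FIELDS:
        row[col] = getattr(case, col).isoformat()
    for s in DENTAL_SICKNESSES:
        sev = getattr(case, s)
        row[s] = b(sev > 0)
        row[s + "_severity"] = str(sev) if sev > 0 else ""
    return row


def load_casebase(path, reference_date: dt.date) -> CaseBase:
    """Read a case-base CSV file, validating every row.

    Censored longevities are (re)computed against ``reference_date``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if missing or unknown:
        raise SchemaError(
            f"case-base header mismatch: missing columns {missing}, unknown columns {unknown}"
        )
    cases = [
        _row_to_case(rec, reference_date, row=i + 1)
        for i, rec in enumerate(df.to_dict(orient="records"))
    ]
    return CaseBase(cases, reference_date)


def save_casebase(cb: CaseBase, path) -> None:
    """Write a case-base to CSV; :func:`load_casebase` inverts it exactly."""
    rows = [_case_to_row(c) for c in cb.cases]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS, dtype=str)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model encodings
# ---------------------------------------------------------------------------

#: upper/lower x molar/premolar/canine/incisor, universal tooth numbering
def _tooth_class(tooth: int) -> int:
    upper = tooth <= 16
    pos = tooth if upper else 33 - tooth  # 1..16 from the rear of each arch
    if pos <= 3:
        kind = 0  # molar
    elif pos <= 5:
        kind = 1  # premolar
    elif pos in (6, 11):
        kind = 2  # canine
    else:
        kind = 3  # incisor
    return kind + (0 if upper else 4)


@dataclass
class EncodedFrame:
    """Column-typed numeric view of a set of cases.

    ``cat`` holds integer category codes (one column per categorical
    attribute, with ``cat_levels[j]`` possible codes ``0..L-1``); ``real``
    holds continuous columns.  This is the common input container for the
    EM and Bayesian-network stages.
    """

    cat: np.ndarray
    cat_names: list[str]
    cat_levels: list[int]
    real: np.ndarray
    real_names: list[str]

    @property
    def n(self) -> int:
        return self.cat.shape[0] if self.cat.size else self.real.shape[0]

    def row(self, i: int) -> "EncodedFrame":
        return EncodedFrame(
            self.cat[i : i + 1], self.cat_names, self.cat_levels, self.real[i : i + 1], self.real_names
        )

    def select(self, idx) -> "EncodedFrame":
        idx = np.asarray(idx)
        return EncodedFrame(
            self.cat[idx], self.cat_names, self.cat_levels, self.real[idx], self.real_names
        )


# categorical attribute -> number of levels, in descriptor order
_CAT_LEVELS: list[tuple[str, int]] = (
    [("sex", 2), ("smoke", 2), ("drink", 2)]
    + [(s, 11) for s in DENTAL_SICKNESSES]
    + [(s, 2) for s in PATIENT_SICKNESSES]
    + [("tooth_number", 32), ("prior_restoration_type", 2), ("restoration_level", 10)]
    + [(f, 2) for f in FAILURE_FLAGS]
    + [("aesthetic_importance", 2)]
)

_REAL_NAMES = ["age_at_restoration", "years_since_prior_restoration", "prior_restoration_longevity"]


def _cat_code(case: Case, name: str) -> int:
    if name == "sex":
        return 0 if case.sex == "male" else 1
    if name == "tooth_number":
        return case.tooth_number - 1
    if name == "restoration_level":
        return case.restoration_level - 1
    if name in ("prior_restoration_type", "restoration_type"):
        return RESTORATION_TYPES.index(getattr(case, name))
    v = getattr(case, name)
    return int(v)


def _real_value(case: Case, name: str) -> float:
    if name == "age_at_restoration":
        return (case.restoration_date - case.date_of_birth).days / DAYS_PER_YEAR
    if name == "years_since_prior_restoration":
        return (case.restoration_date - case.prior_restoration_date).days / DAYS_PER_YEAR
    if name == "prior_restoration_longevity":
        return case.prior_restoration_longevity
    raise KeyError(name)


class CaseEncoder:
    """Fitted numeric encoder for cases.

    Three targets are supported:

    ``em``
        categorical codes for booleans, nominals and 1-10 ordinals; reals
        for the derived durations (age at restoration, years since the
        prior restoration, prior longevity).
    ``bn``
        as ``em`` but fully discrete: reals are equal-frequency binned
        (default 4 bins, edges fitted on the training case-base), the
        32-level tooth number is grouped into 8 anatomical classes, and the
        longevity solution maps onto fixed 2-year bins 0-20+.
    ``mlp``
        a fixed-length real vector (one-hot for the tooth number, 0/1 for
        binary attributes, raw values elsewhere) min-max scaled into the
        sigmoid working range [0.2, 0.8].
    """

    #: fixed 2-year longevity bins used by the Bayesian-network expert
    LONGEVITY_BIN_EDGES = np.arange(0.0, 22.0, 2.0)  # last bin is [20, inf)

    def __init__(self, n_real_bins: int = 4):
        self.n_real_bins = n_real_bins
        self._real_bin_edges: dict[str, np.ndarray] = {}
        self._real_min: np.ndarray | None = None
        self._real_max: np.ndarray | None = None
        self._mlp_scaler = None  # fitted lazily to avoid a circular import

    # -- fitting ----------------------------------------------------------
    @classmethod
    def fit(cls, cb: CaseBase, n_real_bins: int = 4) -> "CaseEncoder":
        from .mlp import RangeScaler

        enc = cls(n_real_bins=n_real_bins)
        reals = np.array([[_real_value(c, n) for n in _REAL_NAMES] for c in cb.cases], dtype=float)
        if len(cb) == 0:
            raise ValueError("cannot fit an encoder on an empty case-base")
        enc._real_min = reals.min(axis=0)
        enc._real_max = reals.max(axis=0)
        for j, name in enumerate(_REAL_NAMES):
            qs = np.linspace(0, 1, n_real_bins + 1)[1:-1]
            edges = np.unique(np.quantile(reals[:, j], qs))
            enc._real_bin_edges[name] = edges
        enc._mlp_scaler = RangeScaler.fit(enc._mlp_raw_matrix(cb.cases))
        return enc

    # -- em / bn ----------------------------------------------------------
    def encode_frame(self, cases: Sequence[Case], target: str = "em") -> EncodedFrame:
        """Encode the problem descriptors of ``cases`` for EM or BN use."""
        if target not in ("em", "bn"):
            raise ValueError(f"unknown frame target {target!r}")
        n = len(cases)
        cat_names = [name for name, _ in _CAT_LEVELS]
        cat_levels = [lv for _, lv in _CAT_LEVELS]
        cat = np.empty((n, len(cat_names)), dtype=np.int64)
        for j, name in enumerate(cat_names):
            cat[:, j] = [_cat_code(c, name) for c in cases]
        real = np.array([[_real_value(c, nm) for nm in _REAL_NAMES] for c in cases], dtype=float)
        real = real.reshape(n, len(_REAL_NAMES))
        if target == "em":
            return EncodedFrame(cat, cat_names, cat_levels, real, list(_REAL_NAMES))
        # bn: everything discrete
        j_tooth = cat_names.index("tooth_number")
        cat = cat.copy()
        cat[:, j_tooth] = [_tooth_class(c.tooth_number) for c in cases]
        cat_levels = list(cat_levels)
        cat_levels[j_tooth] = 8
        extra_cols = []
        for jr, name in enumerate(_REAL_NAMES):
            edges = self._real_bin_edges[name]
            extra_cols.append(np.digitize(real[:, jr], edges))
            cat_names = cat_names + [name]
            cat_levels.append(len(edges) + 1)
        if extra_cols:
            cat = np.hstack([cat] + [c.reshape(n, 1) for c in extra_cols])
        return EncodedFrame(cat, cat_names, cat_levels, np.empty((n, 0)), [])

    def bn_solution_columns(self, cases: Sequence[Case]) -> tuple[np.ndarray, np.ndarray]:
        """Discrete (restoration type code, longevity bin) solution columns."""
        types = np.array([RESTORATION_TYPES.index(c.restoration_type) for c in cases], dtype=np.int64)
        lon = np.array([c.restoration_longevity for c in cases], dtype=float)
        bins = self.longevity_bin(lon)
        return types, bins

    def longevity_bin(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        edges = self.LONGEVITY_BIN_EDGES[1:]  # internal edges 2,4,...,20
        return np.digitize(years, edges)

    @property
    def longevity_bin_midpoints(self) -> np.ndarray:
        edges = self.LONGEVITY_BIN_EDGES
        mids = (edges[:-1] + edges[1:]) / 2.0
        return np.append(mids, edges[-1] + 1.0)  # open-ended 20+ bin

    # -- mlp --------------------------------------------------------------
    def _mlp_raw_matrix(self, cases: Sequence[Case], types: Sequence[str] | None = None) -> np.ndarray:
        n = len(cases)
        cols: list[np.ndarray] = []
        for name, levels in _CAT_LEVELS:
            codes = np.array([_cat_code(c, name) for c in cases], dtype=float)
            if name == "tooth_number":
                onehot = np.zeros((n, 32))
                onehot[np.arange(n), codes.astype(int)] = 1.0
                cols.append(onehot)
            else:
                cols.append(codes.reshape(n, 1))
        reals = np.array([[_real_value(c, nm) for nm in _REAL_NAMES] for c in cases], dtype=float)
        cols.append(reals.reshape(n, len(_REAL_NAMES)))
        if types is not None:
            tcodes = np.array([RESTORATION_TYPES.index(t) for t in types], dtype=float)
            cols.append(tcodes.reshape(n, 1))
        return np.hstack(cols)

    def encode_mlp(self, cases: Sequence[Case]) -> np.ndarray:
        """Problem descriptors as rows of a [0.2, 0.8]-scaled real matrix."""
        return self._mlp_scaler.transform(self._mlp_raw_matrix(cases))

    def encode_mlp_with_type(self, cases: Sequence[Case], types: Sequence[str]) -> np.ndarray:
        """As :meth:`encode_mlp` plus a candidate restoration-type input.

        The type column is binary so it is passed through the 0/1 ->
        0.2/0.8 mapping directly rather than through the fitted scaler.
        """
        base = self.encode_mlp(cases)
        tcodes = np.array([RESTORATION_TYPES.index(t) for t in types], dtype=float)
        tcol = 0.2 + 0.6 * tcodes.reshape(len(cases), 1)
        return np.hstack([base, tcol])

    # -- similarity support ----------------------------------------------
    @property
    def real_ranges(self) -> np.ndarray:
        return np.asarray(self._real_max) - np.asarray(self._real_min)


def encode_case(case: Case, encoder: CaseEncoder, target: str):
    """Encode one case for the given model family (``em``, ``bn``, ``mlp``)."""
    if target in ("em", "bn"):
        return encoder.encode_frame([case], target=target)
    if target == "mlp":
        return encoder.encode_mlp([case])[0]
    raise ValueError(f"unknown encoding target {target!r}")
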