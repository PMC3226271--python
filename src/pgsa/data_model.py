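"""Cohort data schema, covariate codings, score transforms and artifact I/O.

The placebo-group simulation approach (PGSA) forecasts the untreated course of
a mild-cognitive-impairment (MCI) trial cohort from its own baseline data.
This module defines the subject-level schema those forecasts consume: baseline
demographics and clinical scores, longitudinal visit records on a 6-month
visit-number time axis, the neuropsychological composite (NP-Batt), the
square-root transform used for the modified ADAScog endpoint, and plain-text
readers/writers for cohort tables and fitted-model artifacts.

Score conventions
-----------------
* modified ADAScog: 0-85, higher = worse cognition.
* NP-Batt: mean of nine subtest z-scores against normal controls, higher =
  better performance.
* MMSE: 0-30, higher = better.  FAQ: 0-50, higher = more functional
  impairment.  Modified Hachinski: 0-12.
* Time: visit number in units of 6 months; month 36 is visit 6 and there is
  no month-30 visit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants and errors
# --------------------------------------------------------------------------

#: Visit month -> visit number (6-month units).  Month 30 has no visit.
VISIT_MONTH_TO_NUMBER: dict[int, int] = {0: 0, 6: 1, 12: 2, 18: 3, 24: 4, 36: 6}
VISIT_NUMBER_TO_MONTH: dict[int, int] = {v: m for m, v in VISIT_MONTH_TO_NUMBER.items()}
LEGAL_VISIT_NUMBERS: frozenset[int] = frozenset(VISIT_MONTH_TO_NUMBER.values())

ADASCOG_MAX = 85.0
MMSE_MAX = 30
FAQ_MAX = 50
HACHINSKI_MAX = 12

#: Canonical cohort-file columns (csf_ab42_ttau and medication are optional).
COHORT_COLUMNS = [
    "subject_id", "visit_month", "age", "gender", "education_years", "bmi",
    "apoe4", "hachinski", "faq", "mmse", "adascog", "npbatt",
    "csf_ab42_ttau", "medication",
]
_REQUIRED_COLUMNS = COHORT_COLUMNS[:12]


class CohortError(ValueError):
    """Base class for cohort-data problems."""


class SchemaError(CohortError):
    """A mandatory column is missing or a file is structurally unreadable."""


class IntegrityError(CohortError):
    """Duplicate subject/visit keys or dangling subject references."""


class CohortValidationError(CohortError):
    """One or more rows violate field invariants; carries a per-row report."""

    def __init__(self, report: list[str]):
        self.report = list(report)
        super().__init__(
            "cohort validation failed for %d row(s):\n%s"
            % (len(report), "\n".join(report))
        )


class ArtifactError(ValueError):
    """A serialized model artifact is malformed."""


# --------------------------------------------------------------------------
# Coding configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingConfig:
    """How categorical baseline covariates enter design matrices.

    Parameters
    ----------
    gender_reference:
        The gender mapped to indicator 0.  Default ``"male"``, i.e. the
        gender dummy is 1 for women.
    bmi_cutoffs:
        The two strictly increasing BMI thresholds (kg/m^2) splitting the
        cohort into three classes: <25, 25 to <30, and >=30 by default.
    obesity_definition:
        Which BMI class maps to the binary obesity flag: ``"bmi3"`` (the
        top class, >=30, default) or ``"bmi2"`` (everything >= the lower
        cutoff).
    """

    gender_reference: str = "male"
    bmi_cutoffs: tuple[float, float] = (25.0, 30.0)
    obesity_definition: str = "bmi3"

    def __post_init__(self) -> None:
        if self.gender_reference not in ("male", "female"):
            raise ValueError("gender_reference must be 'male' or 'female'")
        lo, hi = self.bmi_cutoffs
        if not lo < hi:
            raise ValueError("bmi_cutoffs must be strictly increasing")
        if self.obesity_definition not in ("bmi2", "bmi3"):
            raise ValueError("obesity_definition must be 'bmi2' or 'bmi3'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodingConfig":
        d = dict(d)
        if "bmi_cutoffs" in d:
            d["bmi_cutoffs"] = tuple(d["bmi_cutoffs"])
        return cls(**d)


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------

def _check(cond: bool, msg: str, problems: list[str]) -> None:
    if not cond:
        problems.append(msg)


@dataclass
class SubjectBaseline:
    """One subject's baseline record.

    ``csf_ratio`` is the cerebrospinal-fluid Abeta42/total-tau quotient,
    available only for the lumbar-puncture subsample, hence optional.
    """

    subject_id: str
    age: float
    gender: str
    education: float
    bmi: float
    apoe4_count: int
    hachinski: int
    faq: int
    mmse: int
    adascog_bl: float
    npbatt_bl: float
    csf_ratio: float | None = None
    on_medication: bool | None = None

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        p: list[str] = []
        _check(self.age > 0, "age must be > 0", p)
        _check(self.gender in ("female", "male"), "gender must be 'female' or 'male'", p)
        _check(self.education >= 0, "education must be >= 0", p)
        _check(self.bmi > 0, "bmi must be > 0", p)
        _check(self.apoe4_count in (0, 1, 2), "apoe4_count must be 0, 1 or 2", p)
        _check(0 <= self.hachinski <= HACHINSKI_MAX, "hachinski out of range 0-12", p)
        _check(0 <= self.faq <= FAQ_MAX, "faq out of range 0-50", p)
        _check(0 <= self.mmse <= MMSE_MAX, "mmse out of range 0-30", p)
        _check(0 <= self.adascog_bl <= ADASCOG_MAX, "adascog_bl out of range 0-85", p)
        _check(math.isfinite(self.npbatt_bl), "npbatt_bl must be finite", p)
        if self.csf_ratio is not None:
            _check(self.csf_ratio > 0, "csf_ratio must be > 0 when present", p)
        return p

    def validate(self) -> "SubjectBaseline":
        p = self.problems()
        if p:
            raise CohortValidationError(
                [f"subject {self.subject_id}: {msg}" for msg in p]
            )
        return self


@dataclass
class VisitRecord:
    """One outcome assessment: visit number (6-month units) plus at least one
    of the two outcome scores."""

    subject_id: str
    visit_number: int
    adascog: float | None = None
    npbatt: float | None = None

    def problems(self) -> list[str]:
        p: list[str] = []
        _check(self.visit_number in LEGAL_VISIT_NUMBERS,
               f"visit_number {self.visit_number} not in {sorted(LEGAL_VISIT_NUMBERS)}", p)
        _check(self.adascog is not None or self.npbatt is not None,
               "at least one outcome (adascog, npbatt) required", p)
        if self.adascog is not None:
            _check(0 <= self.adascog <= ADASCOG_MAX, "adascog out of range 0-85", p)
        if self.npbatt is not None:
            _check(math.isfinite(self.npbatt), "npbatt must be finite", p)
        return p

    def validate(self) -> "VisitRecord":
        p = self.problems()
        if p:
            raise CohortValidationError(
                [f"subject {self.subject_id} visit {self.visit_number}: {m}" for m in p]
            )
        return self


@dataclass
class LongitudinalDataset:
    """A cohort: baseline records plus subject-visit outcome records."""

    baselines: list[SubjectBaseline]
    visits: list[VisitRecord]

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity ---------------------------------------------------------
    def validate(self) -> "LongitudinalDataset":
        ids = [b.subject_id for b in self.baselines]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate subject_ids in baselines: {dup}")
        known = set(ids)
        dangling = sorted({v.subject_id for v in self.visits} - known)
        if dangling:
            raise IntegrityError(f"visits reference unknown subjects: {dangling}")
        seen: set[tuple[str, int]] = set()
        for v in self.visits:
            key = (v.subject_id, v.visit_number)
            if key in seen:
                raise IntegrityError(f"duplicate (subject, visit) record: {key}")
            seen.add(key)
        return self

    # -- views -------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.baselines)

    def baseline_frame(self, coding: CodingConfig | None = None) -> pd.DataFrame:
        """Encoded baseline covariates, one row per subject, indexed by id."""
        coding = coding or CodingConfig()
        rows = [encode_covariates(b, coding) for b in self.baselines]
        return pd.DataFrame(rows, index=[b.subject_id for b in self.baselines])

    def visit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [v.subject_id for v in self.visits],
                "visit": [v.visit_number for v in self.visits],
                "adascog": [v.adascog for v in self.visits],
                "npbatt": [v.npbatt for v in self.visits],
            }
        )

    def merged_frame(self, coding: CodingConfig | None = None) -> pd.DataFrame:
        """Row-per-visit frame joining encoded baseline covariates."""
        bf = self.baseline_frame(coding)
        vf = self.visit_frame()
        return vf.join(bf, on="subject_id")


# --------------------------------------------------------------------------
# NP-Batt composite
# --------------------------------------------------------------------------

#: The nine subtests entering the composite.
NP_BATT_SUBTESTS = (
    "logical_memory_ii",
    "digit_span_forward",
    "digit_span_backward",
    "category_fluency_animals",
    "category_fluency_vegetables",
    "trail_making_b",
    "boston_naming",
    "auditory_verbal_learning",
    "digit_symbol",
)

#: Subtests where a lower raw score means better performance (timed tests);
#: their z-scores are sign-flipped so higher composite = better.
LOWER_IS_BETTER = frozenset({"trail_making_b"})


def compute_np_batt(
    subtest_scores: Mapping[str, float],
    norms: Mapping[str, tuple[float, float]],
) -> float:
    """Average of nine subtest z-scores standardized against normal controls.

    Parameters
    ----------
    subtest_scores:
        Raw score per subtest; all nine of :data:`NP_BATT_SUBTESTS` required.
    norms:
        Per-subtest ``(mean, sd)`` of the cognitively normal reference group.

    Returns
    -------
    float
        Mean of the oriented z-scores; higher = better performance.
    """
    missing = [s for s in NP_BATT_SUBTESTS if s not in subtest_scores or s not in norms]
    if missing:
        raise ValueError(f"incomplete NP-Batt input, missing subtests/norms: {missing}")
    zs = []
    for name in NP_BATT_SUBTESTS:
        mean, sd = norms[name]
        if not sd > 0:
            raise ValueError(f"degenerate norm SD for subtest {name!r}: {sd}")
        z = (subtest_scores[name] - mean) / sd
        if name in LOWER_IS_BETTER:
            z = -z
        zs.append(z)
    return float(np.mean(zs))


# --------------------------------------------------------------------------
# Score transform
# --------------------------------------------------------------------------

def sqrt_transform(score):
    """Square-root transform for the right-skewed ADAScog endpoint."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("sqrt_transform requires scores >= 0")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def inverse_sqrt_transform(value):
    """Back-transform to the original ADAScog scale, clipped to [0, 85].

    Negative sqrt-scale values are floored at 0 before squaring.
    """
    arr = np.asarray(value, dtype=float)
    out = np.clip(np.square(np.clip(arr, 0.0, None)), 0.0, ADASCOG_MAX)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


# --------------------------------------------------------------------------
# Covariate encoding
# --------------------------------------------------------------------------

def encode_covariates(b: SubjectBaseline, coding: CodingConfig | None = None) -> dict:
    """Map a baseline record to named design values.

    Emits the gender indicator (0/1 per the coding's reference level), the
    ApoE4 allele count as a numeric 0/1/2 predictor, BMI class dummies
    ``bmi2`` (middle class) and ``bmi3`` (top class) with the lowest class as
    reference, the binary ``obesity`` flag, and pass-through continuous
    covariates.  ``csf_ratio`` is NaN when absent.
    """
    coding = coding or CodingConfig()
    lo, hi = coding.bmi_cutoffs
    bmi2 = 1.0 if lo <= b.bmi < hi else 0.0
    bmi3 = 1.0 if b.bmi >= hi else 0.0
    obesity = bmi3 if coding.obesity_definition == "bmi3" else (bmi2 + bmi3 > 0) * 1.0
    return {
        "gender": 0.0 if b.gender == coding.gender_reference else 1.0,
        "age": float(b.age),
        "education": float(b.education),
        "bmi2": bmi2,
        "bmi3": bmi3,
        "obesity": float(obesity),
        "apoe4": float(b.apoe4_count),
        "hachinski": float(b.hachinski),
        "faq": float(b.faq),
        "mmse": float(b.mmse),
        "adascog_bl": float(b.adascog_bl),
        "npbatt_bl": float(b.npbatt_bl),
        "csf_ratio": float(b.csf_ratio) if b.csf_ratio is not None else np.nan,
    }


def design_matrix(frame: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Evaluate model terms on an encoded covariate frame.

    A term is either ``"intercept"``, a column name, or a ``":"``-joined
    product of column names (e.g. ``"faq:npbatt_bl"`` or ``"visit:apoe4"``).
    """
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(frame)))
            continue
        val = np.ones(len(frame))
        for part in term.split(":"):
            if part not in frame.columns:
                raise KeyError(f"term {term!r} needs column {part!r}")
            val = val * frame[part].to_numpy(dtype=float)
        cols.append(val)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    if not np.all(np.isfinite(X)):
        bad = [t for t, c in zip(terms, X.T) if not np.all(np.isfinite(c))]
        raise ValueError(f"missing covariate values for terms: {bad}")
    return X


# --------------------------------------------------------------------------
# Cohort file I/O
# --------------------------------------------------------------------------

def _none_if_nan(x):
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def read_cohort(
    source: str | IO[str],
    coding: CodingConfig | None = None,
    sep: str = ",",
) -> LongitudinalDataset:
    """Read a delimited cohort table into a validated dataset.

    One row per subject-visit; the ``visit_month 0`` row carries the baseline
    covariates (repeating them on later rows is accepted and ignored).
    Rows violating field invariants are collected into a single
    :class:`CohortValidationError` naming each offending row and field.
    """
    try:
        df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as schema problem
        raise SchemaError(f"could not parse cohort table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    dup = df.duplicated(subset=["subject_id", "visit_month"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "visit_month"]].to_records(index=False)
        raise IntegrityError(f"duplicate (subject, visit) rows: {list(keys)[:10]}")

    report: list[str] = []
    baselines: list[SubjectBaseline] = []
    visits: list[VisitRecord] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        base_rows = grp[grp["visit_month"] == 0]
        if len(base_rows) == 0:
            report.append(f"subject {sid}: no visit_month 0 (baseline) row")
            continue
        r = base_rows.iloc[0]
        try:
            b = SubjectBaseline(
                subject_id=str(sid),
                age=float(r["age"]),
                gender=str(r["gender"]),
                education=float(r["education_years"]),
                bmi=float(r["bmi"]),
                apoe4_count=int(r["apoe4"]),
                hachinski=int(r["hachinski"]),
                faq=int(r["faq"]),
                mmse=int(r["mmse"]),
                adascog_bl=float(r["adascog"]),
                npbatt_bl=float(r["npbatt"]),
                csf_ratio=_none_if_nan(
                    float(r["csf_ab42_ttau"]) if "csf_ab42_ttau" in grp.columns
                    and pd.notna(r.get("csf_ab42_ttau")) else None
                ),
                on_medication=(
                    bool(r["medication"]) if "medication" in grp.columns
                    and pd.notna(r.get("medication")) else None
                ),
            )
        except (TypeError, ValueError) as exc:
            report.append(f"subject {sid} baseline row: unparseable ({exc})")
            continue
        problems = b.problems()
        if problems:
            report.extend(f"subject {sid} baseline row: {p}" for p in problems)
            continue
        baselines.append(b)
        for _, row in grp.iterrows():
            month = int(row["visit_month"])
            if month not in VISIT_MONTH_TO_NUMBER:
                report.append(
                    f"subject {sid} visit_month {month}: not a scheduled visit month"
                )
                continue
            v = VisitRecord(
                subject_id=str(sid),
                visit_number=VISIT_MONTH_TO_NUMBER[month],
                adascog=_none_if_nan(row["adascog"]),
                npbatt=_none_if_nan(row["npbatt"]),
            )
            problems = v.problems()
            if problems:
                report.extend(
                    f"subject {sid} visit_month {month}: {p}" for p in problems
                )
                continue
            visits.append(v)
    if report:
        raise CohortValidationError(report)
    return LongitudinalDataset(baselines=baselines, visits=visits)


def write_cohort(
    data: LongitudinalDataset,
    dest: str | IO[str],
    sep: str = ",",
) -> None:
    """Write a cohort in the canonical file layout.

    The visit-month-0 row carries the baseline covariates; its outcome
    columns are by definition the baseline ADAScog/NP-Batt values.  A
    visit-0 outcome record deviating from the baseline values cannot be
    represented in this layout and raises.  Round-trips with
    :func:`read_cohort` are lossless.
    """
    base = {b.subject_id: b for b in data.baselines}
    rows = []
    for v in sorted(data.visits, key=lambda v: (v.subject_id, v.visit_number)):
        if v.visit_number == 0:
            b = base[v.subject_id]
            for attr, ref in (("adascog", b.adascog_bl), ("npbatt", b.npbatt_bl)):
                val = getattr(v, attr)
                if val is not None and abs(val - ref) > 1e-9:
                    raise CohortError(
                        f"subject {v.subject_id}: visit-0 {attr} {val} differs "
                        f"from baseline {ref}; the cohort layout stores baseline "
                        "scores in the visit-0 row"
                    )
            continue
        rows.append(_cohort_row(base[v.subject_id], v))
    for sid, b in sorted(base.items()):
        rows.append(_cohort_row(b, VisitRecord(sid, 0, b.adascog_bl, b.npbatt_bl)))
    rows.sort(key=lambda r: (r["subject_id"], r["visit_month"]))
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    # shortest-repr floats so read -> write round-trips bit-exactly
    df.to_csv(dest, sep=sep, index=False,
              float_format=lambda v: repr(float(v)))


def _cohort_row(b: SubjectBaseline, v: VisitRecord) -> dict:
    return {
        "subject_id": b.subject_id,
        "visit_month": VISIT_NUMBER_TO_MONTH[v.visit_number],
        "age": b.age,
        "gender": b.gender,
        "education_years": b.education,
        "bmi": b.bmi,
        "apoe4": b.apoe4_count,
        "hachinski": b.hachinski,
        "faq": b.faq,
        "mmse": b.mmse,
        "adascog": v.adascog,
        "npbatt": v.npbatt,
        "csf_ab42_ttau": b.csf_ratio,
        "medication": b.on_medication,
    }


# --------------------------------------------------------------------------
# Model artifact I/O (JSON)
# --------------------------------------------------------------------------

def save_artifact(fit, dest: str | IO[str]) -> None:
    """Serialize an EndpointFit or TrajectoryFit as a JSON document."""
    doc = fit.to_dict()
    if isinstance(dest, (str,)):
        with open(dest, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        json.dump(doc, dest, indent=1)


def load_artifact(source: str | IO[str]):
    """Load a model artifact; dispatches on its ``kind`` field."""
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        with open(source) as fh:
            doc = json.load(fh)
    elif isinstance(source, str):
        doc = json.loads(source)
    else:
        doc = json.load(source)
    kind = doc.get("kind")
    if kind == "endpoint":
        from .endpoint_model import EndpointFit

        return EndpointFit.from_dict(doc)
    if kind == "trajectory":
        from .trajectory_model import TrajectoryFit

        return TrajectoryFit.from_dict(doc)
    raise ArtifactError(f"unknown artifact kind: {kind!r}")
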