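"""Reading, writing and validating NONMEM-style longitudinal PK datasets.

The on-disk dialect is one row per event with columns
``ID, TIME, AMT, DUR, DV, EVID, MDV, WT, AGE, SEX, SCR, HT``:
``EVID=1`` rows are infusion doses (``AMT`` mg over ``DUR`` h), ``EVID=0``
rows are concentration observations (``DV`` mg/L).  Covariates are baseline
(constant within subject): weight (kg), age (years), sex (0=male,
1=female), serum creatinine (umol/L) and optional height (cm).  Times are
hours since first dose.  Missing values are coded ``.`` or left empty.

Derived covariates: eGFR via the bedside Schwartz formula and the
augmented-renal-clearance (ARC) flag, eGFR >= 130 mL/min/1.73 m2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LLOQ_MG_L",
    "ARC_EGFR_THRESHOLD",
    "SCHWARTZ_K",
    "SubjectRecord",
    "DoseEvent",
    "Observation",
    "SubjectData",
    "PKDataset",
    "DatasetSchemaError",
    "DatasetValidationError",
    "compute_egfr",
    "classify_arc",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

#: Assay lower limit of quantification, mg/L (30 ng/mL).
LLOQ_MG_L = 0.03

#: Pediatric augmented-renal-clearance threshold, mL/min/1.73 m2.
ARC_EGFR_THRESHOLD = 130.0

#: Bedside Schwartz constant (2009 single-constant form).
SCHWARTZ_K = 0.413

#: umol/L per mg/dL for creatinine.
_SCR_UMOL_PER_MGDL = 88.4

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "WT", "AGE", "SEX", "SCR")
OPTIONAL_COLUMNS = ("DUR", "MDV", "HT")
MISSING_CODES = {".", "", "NA", "nan"}


class DatasetSchemaError(ValueError):
    """The file cannot be interpreted as a PK dataset (missing columns etc.)."""


class DatasetValidationError(ValueError):
    """The file parses but violates dataset invariants (negative time, ...)."""


def compute_egfr(scr: float, height: float, k: float = SCHWARTZ_K) -> float:
    """Estimated GFR (mL/min/1.73 m2) from the bedside Schwartz formula.

    Parameters
    ----------
    scr : serum creatinine in umol/L (converted internally to mg/dL).
    height : body length/height in cm.
    k : Schwartz constant; 0.413 is the 2009 single-constant value and can
        be replaced by the original age-banded constants if desired.
    """
    scr_arr, height_arr = np.asarray(scr, float), np.asarray(height, float)
    if np.any(scr_arr <= 0) or np.any(height_arr <= 0):
        raise ValueError("scr and height must be positive")
    out = k * height_arr / (scr_arr / _SCR_UMOL_PER_MGDL)
    return float(out) if out.ndim == 0 else out


def classify_arc(egfr, threshold: float = ARC_EGFR_THRESHOLD):
    """Augmented renal clearance flag: eGFR >= threshold (inclusive)."""
    egfr_arr = np.asarray(egfr, float)
    if np.any(egfr_arr <= 0):
        raise ValueError("egfr must be positive")
    out = egfr_arr >= threshold
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SubjectRecord:
    """Baseline covariates of one infant."""

    subject_id: str
    weight: float  # kg
    age: float  # years
    sex: int  # 0 = male, 1 = female
    serum_creatinine: float  # umol/L
    height: float | None = None  # cm, optional (not always recorded)

    def __post_init__(self):
        if self.weight <= 0 or self.age <= 0 or self.serum_creatinine <= 0:
            raise ValueError(
                f"subject {self.subject_id}: weight, age and serum creatinine "
                "must be positive"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: sex must be 0 or 1")
        if self.height is not None and self.height <= 0:
            raise ValueError(f"subject {self.subject_id}: height must be positive")

    @property
    def egfr(self) -> float | None:
        """Schwartz eGFR; None when height was not recorded."""
        if self.height is None:
            return None
        return compute_egfr(self.serum_creatinine, self.height)

    @property
    def arc_flag(self) -> bool:
        egfr = self.egfr
        if egfr is None:
            raise ValueError(
                f"subject {self.subject_id}: ARC classification requires height"
            )
        return classify_arc(egfr)


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h since first dose
    amount: float  # mg
    duration: float = 0.5  # infusion length, h

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")

    @property
    def rate(self) -> float:
        """Zero-order infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Observation:
    time: float  # h
    concentration: float  # total drug, mg/L
    below_lloq: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.below_lloq and self.concentration < LLOQ_MG_L:
            raise ValueError(
                f"concentration {self.concentration} below LLOQ {LLOQ_MG_L} "
                "but not flagged below_lloq"
            )


@dataclass(frozen=True)
class SubjectData:
    """One subject's covariates plus dose and observation history."""

    record: SubjectRecord
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))


@dataclass(frozen=True)
class PKDataset:
    """Ordered collection of subjects; the modelling unit."""

    subjects: tuple[SubjectData, ...]

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None):
    """Rename user columns to the canonical NONMEM-style names."""
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    df = df.rename(columns={c: c.upper() for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetSchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _num(value, row: int, col: str, allow_missing: bool = True):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip() in MISSING_CODES:
            return None
        value = value.strip()
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DatasetValidationError(
            f"row {row}: column {col} value {value!r} is not numeric"
        ) from None


def read_dataset(path, column_map: Mapping[str, str] | None = None) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"ID": "patient", "DV": "conc"}``.
    """
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise DatasetSchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise DatasetSchemaError(f"{path}: file contains no event rows")
    df = _resolve_columns(df, column_map)

    subjects: list[SubjectData] = []
    for sid, grp in df.groupby("ID", sort=False):
        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        first = grp.iloc[0]
        row0 = int(grp.index[0])
        weight = _num(first.get("WT"), row0, "WT")
        age = _num(first.get("AGE"), row0, "AGE")
        sex = _num(first.get("SEX"), row0, "SEX")
        scr = _num(first.get("SCR"), row0, "SCR")
        height = _num(first.get("HT"), row0, "HT") if "HT" in grp.columns else None
        if weight is None or age is None or sex is None or scr is None:
            raise DatasetValidationError(
                f"subject {sid}: WT, AGE, SEX and SCR must be present"
            )
        try:
            record = SubjectRecord(str(sid), weight, age, int(sex), scr, height)
        except ValueError as exc:
            raise DatasetValidationError(str(exc)) from None

        for idx, row in grp.iterrows():
            time = _num(row["TIME"], idx, "TIME")
            evid = _num(row["EVID"], idx, "EVID")
            if time is None or evid is None:
                raise DatasetValidationError(f"row {idx}: TIME and EVID required")
            if time < 0:
                raise DatasetValidationError(f"row {idx}: negative TIME {time}")
            if int(evid) == 1:
                amt = _num(row["AMT"], idx, "AMT")
                dur = _num(row.get("DUR"), idx, "DUR") if "DUR" in grp.columns else 0.5
                if amt is None:
                    raise DatasetValidationError(f"row {idx}: dose row without AMT")
                if amt <= 0:
                    raise DatasetValidationError(f"row {idx}: non-positive AMT {amt}")
                doses.append(DoseEvent(time, amt, dur if dur is not None else 0.5))
            elif int(evid) == 0:
                mdv = _num(row.get("MDV"), idx, "MDV") if "MDV" in grp.columns else 0
                if mdv is not None and int(mdv) == 1:
                    continue
                dv = _num(row["DV"], idx, "DV")
                if dv is None:
                    continue  # missing-data code on an observation row
                if dv < 0:
                    raise DatasetValidationError(f"row {idx}: negative DV {dv}")
                observations.append(Observation(time, dv, below_lloq=dv < LLOQ_MG_L))
            else:
                raise DatasetValidationError(
                    f"row {idx}: unsupported EVID {int(evid)} (only 0/1)"
                )
        subjects.append(SubjectData(record, tuple(doses), tuple(observations)))

    ds = PKDataset(tuple(subjects))
    issues = validate_dataset(ds)
    errors = [msg for level, msg in issues if level == "error"]
    if errors:
        raise DatasetValidationError("; ".join(errors))
    return ds


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a :class:`PKDataset` back to the NONMEM-style CSV dialect."""
    rows = []
    for subj in dataset:
        rec = subj.record
        events: list[tuple[float, int, dict]] = []
        for d in subj.doses:
            events.append((d.time, 0, {"AMT": d.amount, "DUR": d.duration}))
        for o in subj.observations:
            events.append((o.time, 1, {"DV": o.concentration}))
        events.sort(key=lambda e: (e[0], e[1]))  # dose before obs at ties
        for time, kind, payload in events:
            rows.append(
                {
                    "ID": rec.subject_id,
                    "TIME": time,
                    "AMT": payload.get("AMT", "."),
                    "DUR": payload.get("DUR", "."),
                    "DV": payload.get("DV", "."),
                    "EVID": 0 if kind == 1 else 1,
                    "MDV": 0 if kind == 1 else 1,
                    "WT": rec.weight,
                    "AGE": rec.age,
                    "SEX": rec.sex,
                    "SCR": rec.serum_creatinine,
                    "HT": rec.height if rec.height is not None else ".",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


#: nominal per-dose mg/kg for the prescribed 100 mg/kg/day q12h regimen;
#: doses above this are surfaced as warnings, never silently corrected.
_NOMINAL_DOSE_MG_KG = 50.0


def validate_dataset(dataset: PKDataset) -> list[tuple[str, str]]:
    """Check dataset invariants; returns (level, message) pairs.

    Levels are ``"error"`` (invariant violation) and ``"warning"``
    (suspicious but tolerated, e.g. per-dose mg/kg above the nominal
    regimen share).
    """
    issues: list[tuple[str, str]] = []
    for subj in dataset:
        sid = subj.record.subject_id
        dose_times = [d.time for d in subj.doses]
        obs_times = [o.time for o in subj.observations]
        if any(b < a for a, b in zip(dose_times, dose_times[1:])):
            issues.append(("error", f"subject {sid}: dose times not non-decreasing"))
        if any(b < a for a, b in zip(obs_times, obs_times[1:])):
            issues.append(
                ("error", f"subject {sid}: observation times not non-decreasing")
            )
        if subj.observations:
            if not subj.doses:
                issues.append(
                    ("error", f"subject {sid}: observations without any dose event")
                )
            elif min(obs_times) <= min(dose_times):
                issues.append(
                    (
                        "error",
                        f"subject {sid}: first observation at t={min(obs_times)} "
                        "does not follow a dose",
                    )
                )
        for d in subj.doses:
            mg_kg = d.amount / subj.record.weight
            if mg_kg > _NOMINAL_DOSE_MG_KG * 1.05:
                issues.append(
                    (
                        "warning",
                        f"subject {sid}: dose {d.amount:.0f} mg is "
                        f"{mg_kg:.0f} mg/kg, above the nominal "
                        f"{_NOMINAL_DOSE_MG_KG:.0f} mg/kg per dose",
                    )
                )
        for o in subj.observations:
            if o.below_lloq:
                issues.append(
                    (
                        "warning",
                        f"subject {sid}: observation at t={o.time} is below "
                        f"the LLOQ ({LLOQ_MG_L} mg/L)",
                    )
                )
    return issues
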