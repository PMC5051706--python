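"""Patient-level data model, delimited-text I/O and analysis populations.

A cohort is a list of :class:`PatientRecord`; analyses operate on the
equivalent flat :class:`pandas.DataFrame` (one row per patient, one column
per field, device fields prefixed ``swe_`` / ``te_m_`` / ``te_xl_``).
Missing values are encoded by the empty string on disk and NaN/None in
memory.

Population derivation follows the study flow chart: FibroTest is the
reference, so patients whose FibroTest is not reliable leave the
intention-to-diagnose population; the 2D-SWE reliability population then
requires both transient-elastography probes and FibroTest applicable and a
present 2D-SWE signal; the concordance population additionally drops
not-reliable 2D-SWE results (minimal region-of-interest signal below the
reliability cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Device(str, Enum):
    """Elastography device / probe."""

    SWE = "swe"
    TE_M = "te_m"
    TE_XL = "te_xl"


class Disease(str, Enum):
    CHC = "CHC"
    CHB = "CHB"
    NAFLD = "NAFLD"
    ALD = "ALD"
    OTHER = "OTHER"


class PopulationLabel(str, Enum):
    INVESTIGATED = "INVESTIGATED"
    INTENTION_TO_DIAGNOSE = "INTENTION_TO_DIAGNOSE"
    SWE_RELIABILITY = "SWE_RELIABILITY"
    CONCORDANCE = "CONCORDANCE"
    CONCORDANCE_ST = "CONCORDANCE_ST"
    NOT_APPLICABLE = "NOT_APPLICABLE"


#: kPa ceiling of each device's measurement range.
DEVICE_RANGE_KPA = {Device.SWE: 300.0, Device.TE_M: 75.0, Device.TE_XL: 75.0}


class CohortError(ValueError):
    """Schema, parse or invariant violation in cohort data."""


@dataclass
class BloodPanel:
    """Serum biomarker panel: scores on [0, 1].

    ``fibrotest`` presumes fibrosis stage, ``actitest`` necro-inflammatory
    activity, ``steatotest`` steatosis grade (may be absent).
    """

    fibrotest: float
    actitest: float
    steatotest: float | None = None
    ft_reliable: bool = True

    @property
    def at_present(self) -> bool:
        return self.actitest is not None and not math.isnan(self.actitest)

    @property
    def st_present(self) -> bool:
        return self.steatotest is not None and not math.isnan(self.steatotest)

    def validate(self) -> None:
        for name in ("fibrotest", "actitest", "steatotest"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"{name}={v} outside [0, 1]")


@dataclass
class ElastoMeasurement:
    """One device's measurement session: stiffness summaries in kPa.

    ``cv`` is sd/mean over shots; ``iqr_kpa`` the inter-quartile range of
    shot stiffness; ``failed`` means signal absence (stiffness fields absent).
    """

    device: Device
    mean_kpa: float | None = None
    median_kpa: float | None = None
    min_kpa: float | None = None
    max_kpa: float | None = None
    cv: float | None = None
    depth_mm: float | None = None
    n_valid: int = 0
    n_attempts: int = 0
    iqr_kpa: float | None = None
    failed: bool = False

    @property
    def iqr_over_median(self) -> float | None:
        """IQR/M reliability ratio for transient elastography."""
        if self.iqr_kpa is None or not self.median_kpa:
            return None
        return self.iqr_kpa / self.median_kpa

    def validate(self) -> None:
        dev = Device(self.device)
        stiff = (self.mean_kpa, self.median_kpa, self.min_kpa, self.max_kpa)
        present = [v for v in stiff if v is not None and not math.isnan(v)]
        if self.failed:
            if present:
                raise CohortError(f"{dev.value}: failed measurement carries stiffness values")
            return
        if len(present) != 4:
            raise CohortError(f"{dev.value}: non-failed measurement missing stiffness fields")
        lo, hi = 0.0, DEVICE_RANGE_KPA[dev]
        for v in present:
            if not lo <= v <= hi:
                raise CohortError(f"{dev.value}: stiffness {v} kPa outside [{lo}, {hi}]")
        if not (self.min_kpa <= self.median_kpa <= self.max_kpa):
            raise CohortError(f"{dev.value}: min/median/max ordering violated")
        if not (self.min_kpa <= self.mean_kpa <= self.max_kpa):
            raise CohortError(f"{dev.value}: mean outside [min, max]")
        if self.n_attempts < self.n_valid:
            raise CohortError(f"{dev.value}: n_attempts < n_valid")
        for name in ("cv", "iqr_kpa", "depth_mm"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise CohortError(f"{dev.value}: {name} negative")


@dataclass
class SyntheticTruth:
    """Latent ground truth carried by simulated patients only."""

    stage: int  # METAVIR fibrosis F0-F4
    inflam_grade: int  # activity A0-A3
    steat_grade: int  # steatosis S0-S4
    swe_dead_signal: bool = False
    te_m_failure_cause: str = "NONE"  # NONE | OBESITY | OTHER


@dataclass
class PatientRecord:
    """One subject: demographics, blood panel, three elastography sessions."""

    id: str
    age: float
    sex: str
    bmi: float
    disease: Disease
    interval_days: float
    blood: BloodPanel
    swe: ElastoMeasurement
    te_m: ElastoMeasurement
    te_xl: ElastoMeasurement
    truth: SyntheticTruth | None = None

    def measurement(self, device: Device) -> ElastoMeasurement:
        return {Device.SWE: self.swe, Device.TE_M: self.te_m, Device.TE_XL: self.te_xl}[
            Device(device)
        ]

    def validate(self) -> None:
        if self.bmi <= 10:
            raise CohortError(f"patient {self.id}: bmi {self.bmi} <= 10")
        if self.interval_days < 0:
            raise CohortError(f"patient {self.id}: negative test interval")
        self.blood.validate()
        for m in (self.swe, self.te_m, self.te_xl):
            m.validate()


# ---------------------------------------------------------------------------
# Flat-frame schema

_DEVICE_FIELDS = [
    ("mean_kpa", float),
    ("median_kpa", float),
    ("min_kpa", float),
    ("max_kpa", float),
    ("cv", float),
    ("depth_mm", float),
    ("n_valid", int),
    ("n_attempts", int),
    ("iqr_kpa", float),
    ("failed", bool),
]

_BASE_FIELDS = [
    ("id", str),
    ("age", float),
    ("sex", str),
    ("bmi", float),
    ("disease", str),
    ("interval_days", float),
    ("fibrotest", float),
    ("actitest", float),
    ("steatotest", float),
    ("ft_reliable", bool),
]

_TRUTH_FIELDS = [
    ("truth_stage", int),
    ("truth_inflam", int),
    ("truth_steat", int),
    ("truth_swe_dead", bool),
    ("truth_te_m_cause", str),
]

#: Mandatory CSV columns, in canonical order.
MANDATORY_COLUMNS: list[str] = [n for n, _ in _BASE_FIELDS] + [
    f"{dev.value}_{n}" for dev in Device for n, _ in _DEVICE_FIELDS
]
OPTIONAL_COLUMNS: list[str] = [n for n, _ in _TRUTH_FIELDS]

_COLUMN_TYPES: dict[str, type] = dict(_BASE_FIELDS + _TRUTH_FIELDS)
_COLUMN_TYPES.update({f"{d.value}_{n}": t for d in Device for n, t in _DEVICE_FIELDS})


def record_to_row(rec: PatientRecord) -> dict:
    row: dict = {
        "id": rec.id,
        "age": rec.age,
        "sex": rec.sex,
        "bmi": rec.bmi,
        "disease": Disease(rec.disease).value,
        "interval_days": rec.interval_days,
        "fibrotest": rec.blood.fibrotest,
        "actitest": rec.blood.actitest,
        "steatotest": rec.blood.steatotest,
        "ft_reliable": rec.blood.ft_reliable,
    }
    for dev in Device:
        m = rec.measurement(dev)
        for name, _ in _DEVICE_FIELDS:
            row[f"{dev.value}_{name}"] = getattr(m, name)
    if rec.truth is not None:
        row.update(
            truth_stage=rec.truth.stage,
            truth_inflam=rec.truth.inflam_grade,
            truth_steat=rec.truth.steat_grade,
            truth_swe_dead=rec.truth.swe_dead_signal,
            truth_te_m_cause=rec.truth.te_m_failure_cause,
        )
    return row


def row_to_record(row: Mapping) -> PatientRecord:
    def get(name, default=None):
        v = row.get(name, default)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    measurements = {}
    for dev in Device:
        kw = {}
        for name, typ in _DEVICE_FIELDS:
            v = get(f"{dev.value}_{name}")
            if v is not None and typ in (int, bool):
                v = typ(int(v))
            kw[name] = v if v is not None else (0 if typ is int else (False if typ is bool else None))
        measurements[dev] = ElastoMeasurement(device=dev, **kw)
    truth = None
    if get("truth_stage") is not None:
        truth = SyntheticTruth(
            stage=int(row["truth_stage"]),
            inflam_grade=int(row["truth_inflam"]),
            steat_grade=int(row["truth_steat"]),
            swe_dead_signal=bool(int(row.get("truth_swe_dead", 0))),
            te_m_failure_cause=str(row.get("truth_te_m_cause", "NONE")),
        )
    return PatientRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        bmi=float(row["bmi"]),
        disease=Disease(str(row["disease"])),
        interval_days=float(row["interval_days"]),
        blood=BloodPanel(
            fibrotest=float(row["fibrotest"]),
            actitest=float(row["actitest"]),
            steatotest=get("steatotest"),
            ft_reliable=bool(int(row["ft_reliable"])),
        ),
        swe=measurements[Device.SWE],
        te_m=measurements[Device.TE_M],
        te_xl=measurements[Device.TE_XL],
        truth=truth,
    )


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the canonical analysis frame."""
    rows = [record_to_row(r) for r in cohort]
    cols = MANDATORY_COLUMNS + (
        OPTIONAL_COLUMNS if any("truth_stage" in r for r in rows) else []
    )
    return pd.DataFrame(rows, columns=cols)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    return [row_to_record(row) for row in df.to_dict(orient="records")]


# ---------------------------------------------------------------------------
# Delimited-text I/O (UTF-8 CSV, "." decimal, empty string = absent)


def _format_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return repr(v) if v != int(v) else str(int(v))
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    return str(v)


def write_cohort(cohort: Sequence[PatientRecord] | pd.DataFrame, path) -> None:
    """Write a cohort CSV; floats use shortest round-tripping decimal form."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    out = df.map(_format_cell)
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort(path, validate: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Malformed rows raise :class:`CohortError` naming the offending row
    (0-based data row index) and column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing mandatory columns {missing}")
    records: list[PatientRecord] = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        parsed: dict = {}
        for col, s in raw.items():
            typ = _COLUMN_TYPES.get(col)
            if typ is None:
                continue
            if s == "":
                parsed[col] = None
                continue
            if typ is str:
                parsed[col] = s
            else:
                try:
                    parsed[col] = float(s)
                except ValueError:
                    raise CohortError(
                        f"{path}: row {i}, column {col!r}: cannot parse {s!r} as number"
                    ) from None
        try:
            rec = row_to_record(parsed)
            if validate:
                rec.validate()
        except (CohortError, KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, CohortError) and "row" in str(exc):
                raise
            raise CohortError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Analysis populations

_STATUS_COLUMNS = ["status_swe", "status_te_m", "status_te_xl", "status_ft"]


def derive_populations(frame: pd.DataFrame) -> dict[PopulationLabel, set]:
    """Derive the nested analysis populations from applicability statuses.

    Expects the per-device ``status_*`` columns produced by
    :func:`elastoconcord.applicability.apply_applicability`. Returns a
    mapping from :class:`PopulationLabel` to the set of patient ids.
    """
    missing = [c for c in _STATUS_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortError(
            f"applicability statuses not computed (missing columns {missing}); "
            "run applicability.apply_applicability first"
        )
    ids = frame["id"]
    investigated = set(ids)
    ft_ok = frame["status_ft"] == "APPLICABLE"
    itd = set(ids[ft_ok])
    swe_present = frame["status_swe"] != "FAILURE"
    te_ok = (frame["status_te_m"] == "APPLICABLE") & (frame["status_te_xl"] == "APPLICABLE")
    reliability = set(ids[ft_ok & te_ok & swe_present])
    swe_ok = frame["status_swe"] == "APPLICABLE"
    concordance = set(ids[ft_ok & te_ok & swe_ok])
    st_present = frame["steatotest"].notna()
    concordance_st = set(ids[ft_ok & te_ok & swe_ok & st_present])
    return {
        PopulationLabel.INVESTIGATED: investigated,
        PopulationLabel.INTENTION_TO_DIAGNOSE: itd,
        PopulationLabel.SWE_RELIABILITY: reliability,
        PopulationLabel.CONCORDANCE: concordance,
        PopulationLabel.CONCORDANCE_ST: concordance_st,
        PopulationLabel.NOT_APPLICABLE: itd - concordance,
    }


def write_populations(populations: Mapping[PopulationLabel, Iterable], path) -> None:
    """Export population assignments as a two-column CSV (id, population)."""
    rows = [
        {"id": pid, "population": PopulationLabel(label).value}
        for label, members in populations.items()
        for pid in sorted(members)
    ]
    pd.DataFrame(rows, columns=["id", "population"]).to_csv(path, index=False)
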