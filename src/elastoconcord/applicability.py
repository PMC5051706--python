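"""Per-device applicability classification and rate comparison.

Each investigated patient receives, per test, exactly one of three statuses:
``FAILURE`` (no signal / no sample), ``NOT_RELIABLE`` (signal present but a
device-specific quality rule is violated) or ``APPLICABLE``. The quality
rules are the field standards: for transient elastography IQR/M < 0.30,
at least 10 valid shots and a success rate >= 60%; for 2D-SWE a minimal
region-of-interest signal >= 0.2 kPa; for FibroTest an internal reliability
flag (the component-level extreme-value rule needs serum components that are
not modelled).

Rates are summarised with Wilson score intervals and compared with the
pooled two-proportion z-test (a McNemar option is provided for the paired
design but is not the default, which reproduces the published unpaired
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Device, PatientRecord


class Status(str, Enum):
    APPLICABLE = "APPLICABLE"
    FAILURE = "FAILURE"
    NOT_RELIABLE = "NOT_RELIABLE"


#: Pseudo-device key for the serum reference test in status tables.
FIBROTEST = "ft"


@dataclass(frozen=True)
class ReliabilityRules:
    """Thresholds of the per-test quality rules (field-standard defaults)."""

    te_iqr_over_m_max: float = 0.30
    te_min_shots: int = 10
    te_min_success_rate: float = 0.60
    swe_min_kpa: float = 0.2
    ft_delta_max: float = 0.30  # documented; needs serum components to evaluate

    def __post_init__(self):
        for f in ("te_iqr_over_m_max", "te_min_shots", "te_min_success_rate", "swe_min_kpa", "ft_delta_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"rule threshold {f} must be positive")


@dataclass(frozen=True)
class ProportionResult:
    """A rate with its Wilson 95% interval, on the percent scale."""

    numerator: int
    denominator: int
    rate: float
    ci_low: float
    ci_high: float


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the published tables)."""
    factor = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def classify_status(
    patient: PatientRecord, device, rules: ReliabilityRules = ReliabilityRules()
) -> Status:
    """Classify one patient's measurement for one test.

    ``device`` is a :class:`Device` or the string ``"ft"`` for FibroTest.
    """
    if device == FIBROTEST:
        # Serum sampling failure is not modelled; reliability is a flag.
        return Status.APPLICABLE if patient.blood.ft_reliable else Status.NOT_RELIABLE
    dev = Device(device)
    m = patient.measurement(dev)
    if m.failed:
        return Status.FAILURE
    if dev is Device.SWE:
        if m.min_kpa is not None and m.min_kpa < rules.swe_min_kpa:
            return Status.NOT_RELIABLE
        return Status.APPLICABLE
    # transient elastography (M or XL probe)
    iqr_m = m.iqr_over_median
    if iqr_m is None or iqr_m >= rules.te_iqr_over_m_max:
        return Status.NOT_RELIABLE
    if m.n_valid < rules.te_min_shots:
        return Status.NOT_RELIABLE
    if m.n_attempts > 0 and m.n_valid / m.n_attempts < rules.te_min_success_rate:
        return Status.NOT_RELIABLE
    return Status.APPLICABLE


def apply_applicability(
    frame: pd.DataFrame, rules: ReliabilityRules = ReliabilityRules()
) -> pd.DataFrame:
    """Vectorised classification: add ``status_<test>`` columns to a copy."""
    out = frame.copy()
    for dev in Device:
        p = dev.value
        failed = frame[f"{p}_failed"].astype(bool)
        if dev is Device.SWE:
            nr = frame[f"{p}_min_kpa"] < rules.swe_min_kpa
        else:
            iqr_m = frame[f"{p}_iqr_kpa"] / frame[f"{p}_median_kpa"]
            success = frame[f"{p}_n_valid"] / frame[f"{p}_n_attempts"].replace(0, np.nan)
            nr = (
                iqr_m.isna()
                | (iqr_m >= rules.te_iqr_over_m_max)
                | (frame[f"{p}_n_valid"] < rules.te_min_shots)
                | (success < rules.te_min_success_rate)
            )
        out[f"status_{p}"] = np.where(
            failed, Status.FAILURE.value, np.where(nr, Status.NOT_RELIABLE.value, Status.APPLICABLE.value)
        )
    out["status_ft"] = np.where(
        frame["ft_reliable"].astype(bool), Status.APPLICABLE.value, Status.NOT_RELIABLE.value
    )
    return out


def wilson_ci(numerator: int, denominator: int, level: float = 0.95) -> ProportionResult:
    """Wilson score interval, reported as percents."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    lo, hi = proportion_confint(numerator, denominator, alpha=1 - level, method="wilson")
    rate = 100.0 * numerator / denominator
    return ProportionResult(
        numerator=int(numerator),
        denominator=int(denominator),
        rate=rate,
        ci_low=min(max(100.0 * lo, 0.0), rate),
        ci_high=max(min(100.0 * hi, 100.0), rate),
    )


def two_proportion_z(n1_num: int, n1_den: int, n2_num: int, n2_den: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    Sign follows argument order: positive when the first rate is larger.
    """
    p1, p2 = n1_num / n1_den, n2_num / n2_den
    pooled = (n1_num + n2_num) / (n1_den + n2_den)
    if pooled in (0.0, 1.0):
        raise ZeroDivisionError("pooled proportion is degenerate (0 or 1); z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1_den + 1 / n2_den))
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mcnemar_applicability(a_applicable: np.ndarray, b_applicable: np.ndarray) -> tuple[float, float]:
    """Paired (McNemar) alternative for comparing applicability of two tests."""
    a = np.asarray(a_applicable, bool)
    b = np.asarray(b_applicable, bool)
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    if n01 + n10 == 0:
        return 0.0, 1.0
    chi2 = (n10 - n01) ** 2 / (n10 + n01)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


_TESTS = [Device.SWE.value, Device.TE_M.value, Device.TE_XL.value, FIBROTEST]


def applicability_table(frame: pd.DataFrame, rules: ReliabilityRules = ReliabilityRules()):
    """Applicability summary of the investigated population, per test.

    Returns ``(table, ztests)``: a tidy DataFrame with counts, one-decimal
    percents and Wilson intervals for the applicable row, and a DataFrame of
    pairwise pooled z-tests among the four tests.
    """
    if not any(c.startswith("status_") for c in frame.columns):
        frame = apply_applicability(frame, rules)
    n = len(frame)
    rows = []
    applicable_counts = {}
    for test in _TESTS:
        status = frame[f"status_{test}"]
        counts = {s.value: int((status == s.value).sum()) for s in Status}
        applicable_counts[test] = counts["APPLICABLE"]
        ci = wilson_ci(counts["APPLICABLE"], n)
        rows.append(
            {
                "test": test,
                "investigated": n,
                "applicable": counts["APPLICABLE"],
                "applicable_pct": round_half_away(ci.rate),
                "applicable_ci_low": round_half_away(ci.ci_low),
                "applicable_ci_high": round_half_away(ci.ci_high),
                "not_applicable": counts["FAILURE"] + counts["NOT_RELIABLE"],
                "not_applicable_pct": round_half_away(100 * (counts["FAILURE"] + counts["NOT_RELIABLE"]) / n),
                "failure": counts["FAILURE"],
                "failure_pct": round_half_away(100 * counts["FAILURE"] / n),
                "not_reliable": counts["NOT_RELIABLE"],
                "not_reliable_pct": round_half_away(100 * counts["NOT_RELIABLE"] / n),
            }
        )
    zrows = []
    for i, a in enumerate(_TESTS):
        for b in _TESTS[i + 1 :]:
            try:
                z, p = two_proportion_z(applicable_counts[a], n, applicable_counts[b], n)
                zrows.append({"test_a": a, "test_b": b, "z": z, "p": p, "defined": True})
            except ZeroDivisionError:
                zrows.append({"test_a": a, "test_b": b, "z": np.nan, "p": np.nan, "defined": False})
    return pd.DataFrame(rows), pd.DataFrame(zrows)
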