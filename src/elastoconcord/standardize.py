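"""Elasticity standardization to the unit interval.

Stiffness in kPa is right-skewed and device ranges differ (2D-SWE reads up
to 300 kPa, transient elastography up to 75 kPa), so raw values are not
comparable with blood-test scores on [0, 1]. The default transform clamps
to [1, 75] kPa, takes log10, and rescales so 1 kPa -> 0 and 75 kPa -> 1:

    s(e) = log10(clamp(e, 1, 75)) / log10(75)

Two alternative variants are kept for sensitivity analysis: a purely linear
rescaling over the same range, and an unscaled log10. Missing measurements
can be imputed worst-case as 1 - FibroTest for intention-to-diagnose
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import Device


class Variant(str, Enum):
    LOG_RANGE = "LOG_RANGE"  # log10 then rescale to [0, 1] (default)
    LINEAR_74 = "LINEAR_74"  # (clamp(e, 1, 75) - 1) / 74
    LOG_ONLY = "LOG_ONLY"  # log10(max(e, 0.1)); not unit-range


class Source(str, Enum):
    MEASURED = "MEASURED"
    IMPUTED_WORST_CASE = "IMPUTED_WORST_CASE"


@dataclass(frozen=True)
class StandardizedValue:
    value: float
    source: Source = Source.MEASURED


def log_standardize(e_kpa, lower_kpa: float = 1.0, upper_kpa: float = 75.0):
    """Log-range standardization of stiffness to [0, 1].

    Scalar in, :class:`StandardizedValue` out; array in, ndarray out.
    """
    if lower_kpa <= 0 or lower_kpa >= upper_kpa:
        raise ValueError("need 0 < lower_kpa < upper_kpa")
    arr = np.asarray(e_kpa, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("negative stiffness")
    clamped = np.clip(arr, lower_kpa, upper_kpa)
    value = np.log10(clamped / lower_kpa) / np.log10(upper_kpa / lower_kpa)
    if np.ndim(e_kpa) == 0:
        return StandardizedValue(float(value), Source.MEASURED)
    return value


def worst_case_impute(fibrotest: float) -> StandardizedValue:
    """Worst-case substitute for a missing elasticity: 1 - FibroTest."""
    if not 0.0 <= fibrotest <= 1.0:
        raise ValueError(f"FibroTest {fibrotest} outside [0, 1]")
    return StandardizedValue(1.0 - fibrotest, Source.IMPUTED_WORST_CASE)


def _transform(arr: np.ndarray, variant: Variant) -> np.ndarray:
    if variant is Variant.LOG_RANGE:
        return np.log10(np.clip(arr, 1.0, 75.0)) / math.log10(75.0)
    if variant is Variant.LINEAR_74:
        return (np.clip(arr, 1.0, 75.0) - 1.0) / 74.0
    if variant is Variant.LOG_ONLY:
        return np.log10(np.maximum(arr, 0.1))
    raise ValueError(f"unknown standardization variant {variant!r}")


def standardize_cohort(
    frame: pd.DataFrame,
    device,
    variant: Variant | str = Variant.LOG_RANGE,
    statistic: str = "mean",
    impute_missing: bool = False,
) -> pd.Series:
    """Standardized elasticity per patient for one device.

    ``statistic`` picks the per-session summary fed downstream (``"mean"``,
    the default, or ``"median"``). Failed/absent measurements yield NaN
    unless ``impute_missing``, in which case they get 1 - FibroTest
    (only meaningful for the LOG_RANGE / LINEAR_74 unit-range variants).
    """
    variant = Variant(variant)
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    dev = Device(device)
    raw = frame[f"{dev.value}_{statistic}_kpa"].to_numpy(dtype=float)
    if np.any(raw[~np.isnan(raw)] < 0):
        raise ValueError("negative stiffness in cohort")
    with np.errstate(invalid="ignore"):
        std = _transform(raw, variant)
    if impute_missing:
        missing = np.isnan(raw)
        std = np.where(missing, 1.0 - frame["fibrotest"].to_numpy(dtype=float), std)
    return pd.Series(std, index=frame.index, name=f"std_elasticity_{dev.value}")


def add_standardized_columns(
    frame: pd.DataFrame,
    variant: Variant | str = Variant.LOG_RANGE,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Copy of ``frame`` with ``std_elasticity_<device>`` columns added."""
    out = frame.copy()
    for dev in Device:
        out[f"std_elasticity_{dev.value}"] = standardize_cohort(frame, dev, variant, statistic)
    return out
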