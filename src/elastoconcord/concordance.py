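"""Lin concordance correlation coefficient (CCC) and stratified tables.

The CCC measures agreement between two quantitative readings on the same
subjects, combining precision (Pearson correlation) with accuracy (the
location/scale shift between them):

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with n-divisor moments (Lin's original estimator). Confidence intervals use
the Fisher z-transform with Lin's asymptotic variance. Dependent CCCs
(two devices against the same reference on the same patients) are compared
by a seeded paired bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Device

logger = logging.getLogger(__name__)

#: analysis-frame column holding each reference score
REFERENCE_COLUMNS = {
    "fibrotest": "fibrotest",
    "actitest": "actitest",
    "steatotest": "steatotest",
}


@dataclass(frozen=True)
class LCCResult:
    estimate: float
    n: int
    ci_low: float
    ci_high: float
    stratum: str = ""


@dataclass(frozen=True)
class CCCComparison:
    """Paired-bootstrap comparison of two dependent CCCs."""

    ccc_a: float
    ccc_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int
    warning: str | None = None


class StratVariable(str, Enum):
    DISEASE = "DISEASE"
    INFLAMMATION = "INFLAMMATION"
    STEATOSIS = "STEATOSIS"
    FIBROSIS = "FIBROSIS"
    INTERVAL = "INTERVAL"
    CUSTOM = "CUSTOM"


_VARIABLE_COLUMNS = {
    StratVariable.DISEASE: "disease",
    StratVariable.INFLAMMATION: "actitest",
    StratVariable.STEATOSIS: "steatotest",
    StratVariable.FIBROSIS: "fibrotest",
    StratVariable.INTERVAL: "interval_days",
}


@dataclass(frozen=True)
class StratificationScheme:
    """Cutpoint-based (or categorical) patient stratification.

    For a numeric variable with cutpoints (c1, ..., ck) the strata are the
    half-open intervals (-inf, c1), [c1, c2), ..., [ck, inf) and ``labels``
    must have k + 1 entries. For DISEASE the cutpoints are ignored and
    strata are the disease categories.
    """

    variable: StratVariable
    cutpoints: tuple = ()
    labels: tuple = ()
    column: str | None = None  # for CUSTOM

    def __post_init__(self):
        cp = tuple(self.cutpoints)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if self.variable is not StratVariable.DISEASE:
            if self.labels and len(self.labels) != len(cp) + 1:
                raise ValueError("need len(cutpoints) + 1 labels")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique")

    def assign(self, frame: pd.DataFrame) -> pd.Series:
        """Label each patient with its stratum (NaN where unassignable)."""
        col = self.column if self.variable is StratVariable.CUSTOM else _VARIABLE_COLUMNS[self.variable]
        values = frame[col]
        if self.variable is StratVariable.DISEASE:
            return values.astype(str)
        edges = [-np.inf, *self.cutpoints, np.inf]
        labels = list(self.labels) if self.labels else [f"bin{i}" for i in range(len(edges) - 1)]
        idx = np.searchsorted(np.asarray(self.cutpoints, float), values.to_numpy(float), side="right")
        out = pd.Series([labels[i] for i in idx], index=frame.index, dtype=object)
        out[values.isna()] = np.nan
        return out


def _moments(x: np.ndarray, y: np.ndarray):
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    cxy = ((x - mx) * (y - my)).mean()
    return mx, my, vx, vy, cxy


def ccc_estimate(x, y) -> float:
    """Point estimate of Lin's CCC (n-divisor moments)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my, vx, vy, cxy = _moments(x, y)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ZeroDivisionError("CCC undefined: both inputs constant with equal means")
    return float(2 * cxy / denom)


def lin_ccc(x, y, level: float = 0.95, stratum: str = "") -> LCCResult:
    """Lin's CCC with a bilateral confidence interval.

    The interval applies the Fisher z-transform with Lin's asymptotic
    variance (the standard large-sample treatment), back-transformed to the
    CCC scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = len(x)
    mx, my, vx, vy, cxy = _moments(x, y)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ZeroDivisionError("CCC undefined: both inputs constant with equal means")
    ccc = 2 * cxy / denom
    if vx == 0.0 or vy == 0.0 or abs(ccc) >= 1.0 - 1e-12:
        # degenerate: no sampling interval available from the asymptotics
        return LCCResult(float(ccc), n, float(ccc), float(ccc), stratum)
    r = cxy / np.sqrt(vx * vy)
    u = (mx - my) / (vx * vy) ** 0.25
    z = np.arctanh(ccc)
    r2 = r * r
    c2 = ccc * ccc
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r2 * (1 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * np.sqrt(var_z)), np.tanh(z + zcrit * np.sqrt(var_z))
    return LCCResult(float(ccc), n, float(lo), float(hi), stratum)


def _ccc_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise CCC for bootstrap matrices (replicates x n)."""
    mx = x.mean(axis=1, keepdims=True)
    my = y.mean(axis=1, keepdims=True)
    vx = ((x - mx) ** 2).mean(axis=1)
    vy = ((y - my) ** 2).mean(axis=1)
    cxy = ((x - mx) * (y - my)).mean(axis=1)
    denom = vx + vy + (mx[:, 0] - my[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2 * cxy / denom
    return np.where(denom == 0.0, 0.0, out)


def compare_ccc_paired(
    frame: pd.DataFrame,
    device_a,
    device_b,
    reference: str,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> CCCComparison:
    """Paired bootstrap comparison of CCC(device_a, ref) - CCC(device_b, ref).

    Both devices must be measured (standardized) on the same patients; rows
    with any missing value are dropped. The p-value is the two-sided
    bootstrap tail probability of the difference crossing zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    cols = [
        f"std_elasticity_{Device(device_a).value}",
        f"std_elasticity_{Device(device_b).value}",
        REFERENCE_COLUMNS.get(reference, reference),
    ]
    data = frame[cols].dropna()
    xa = data.iloc[:, 0].to_numpy(float)
    xb = data.iloc[:, 1].to_numpy(float)
    ref = data.iloc[:, 2].to_numpy(float)
    n = len(data)
    if n < 3:
        raise ValueError("need n >= 3 complete pairs")

    def safe_ccc(u, v):
        try:
            return ccc_estimate(u, v)
        except ZeroDivisionError:
            return 0.0

    ccc_a = safe_ccc(xa, ref)
    ccc_b = safe_ccc(xb, ref)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    diffs = _ccc_rows(xa[idx], ref[idx]) - _ccc_rows(xb[idx], ref[idx])
    lo, hi = np.quantile(diffs, [(1 - level) / 2, 0.5 + level / 2])
    frac_le = np.mean(diffs <= 0)
    frac_ge = np.mean(diffs >= 0)
    p = min(1.0, 2 * min(frac_le, frac_ge))
    warning = None
    if n < 30:
        warning = f"n={n} < 30: bootstrap comparison unstable"
    elif np.allclose(diffs, 0.0):
        warning = "degenerate bootstrap distribution (no variation)"
    return CCCComparison(ccc_a, ccc_b, ccc_a - ccc_b, float(lo), float(hi), float(p), n, n_boot, warning)


def stratified_ccc_table(
    frame: pd.DataFrame,
    devices: Sequence,
    reference: str,
    scheme: StratificationScheme,
    min_n: int = 3,
) -> pd.DataFrame:
    """CCC of each device against a reference, per stratum.

    One row per stratum with the stratum size and per-device estimate and
    95% interval; strata with fewer than ``min_n`` complete pairs are
    skipped with a log notice.
    """
    ref_col = REFERENCE_COLUMNS.get(reference, reference)
    strata = scheme.assign(frame)
    rows = []
    for label in pd.unique(strata.dropna()):
        sub = frame[strata == label]
        row: dict = {"stratum": label, "n": int(len(sub))}
        any_ok = False
        for dev in devices:
            col = f"std_elasticity_{Device(dev).value}"
            pair = sub[[col, ref_col]].dropna()
            if len(pair) < min_n:
                logger.info("stratum %r skipped for %s: n=%d < %d", label, col, len(pair), min_n)
                row[f"{Device(dev).value}_ccc"] = np.nan
                continue
            res = lin_ccc(pair[col], pair[ref_col], stratum=str(label))
            row[f"{Device(dev).value}_ccc"] = res.estimate
            row[f"{Device(dev).value}_ci_low"] = res.ci_low
            row[f"{Device(dev).value}_ci_high"] = res.ci_high
            row[f"{Device(dev).value}_n"] = res.n
            any_ok = True
        if any_ok:
            rows.append(row)
    return pd.DataFrame(rows)
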