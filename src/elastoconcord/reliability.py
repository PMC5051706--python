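"""Screening of candidate 2D-SWE quality criteria by strength of concordance.

With no histological gold standard, the concordance between two imperfect
references can screen quality criteria: a genuine reliability factor of one
test should weaken its concordance with an independent test in the affected
subgroup only. Patients (restricted to the 2D-SWE reliability population)
are binned by a candidate criterion (minimal Qbox elasticity, shot CV,
measurement depth, BMI); within each bin the Lin CCC of standardized 2D-SWE
elasticity against each reference (FibroTest, TE-M, TE-XL) is computed with
its 95% interval. A bin is *flagged* when the interval with the primary
reference contains zero; the criterion is *discriminant* when some bins are
flagged and others are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import Device
from .concordance import LCCResult, lin_ccc

logger = logging.getLogger(__name__)


class Criterion(str, Enum):
    MIN_ELASTICITY = "MIN_ELASTICITY"  # kPa
    CV = "CV"  # sd/mean ratio
    DEPTH = "DEPTH"  # mm
    BMI = "BMI"  # kg/m2


_CRITERION_COLUMNS = {
    Criterion.MIN_ELASTICITY: "swe_min_kpa",
    Criterion.CV: "swe_cv",
    Criterion.DEPTH: "swe_depth_mm",
    Criterion.BMI: "bmi",
}

#: default bin edges: minimal-elasticity cutoffs under evaluation, CV/depth
#: quartile-like splits, WHO BMI classes
DEFAULT_BIN_EDGES = {
    Criterion.MIN_ELASTICITY: (0.2, 0.5, 1.0),
    Criterion.CV: (0.10, 0.15, 0.25),
    Criterion.DEPTH: (25.0, 35.0, 45.0),
    Criterion.BMI: (18.5, 25.0, 30.0),
}


@dataclass(frozen=True)
class CriterionSpec:
    name: Criterion
    bin_edges: tuple

    def __post_init__(self):
        edges = tuple(self.bin_edges)
        if len(edges) < 1:
            raise ValueError("need >= 1 edge (>= 2 bins)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def default(cls, name: Criterion) -> "CriterionSpec":
        name = Criterion(name)
        return cls(name, DEFAULT_BIN_EDGES[name])

    def bin_labels(self) -> list[str]:
        edges = list(self.bin_edges)
        labels = [f"<{edges[0]:g}"]
        labels += [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
        labels.append(f">={edges[-1]:g}")
        return labels

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Half-open bins [lo, hi): index of each value's bin."""
        return np.searchsorted(np.asarray(self.bin_edges, float), values, side="right")


@dataclass(frozen=True)
class ScreenReport:
    criterion: Criterion
    grid: pd.DataFrame  # one row per (bin, reference) with LCC estimate + CI
    flagged_bins: tuple  # bins whose primary-reference CI contains 0
    tested_bins: tuple  # bins with enough patients to test
    discriminant: bool

    def to_table(self) -> pd.DataFrame:
        """Wide table: references as rows, bins as columns (estimate [CI])."""
        g = self.grid
        cells = g.assign(
            cell=[
                f"{e:.3f} [{lo:.3f};{hi:.3f}] (n={n})"
                for e, lo, hi, n in zip(g.estimate, g.ci_low, g.ci_high, g.n)
            ]
        )
        return cells.pivot(index="reference", columns="bin", values="cell")


def _reference_series(frame: pd.DataFrame, reference: str) -> pd.Series:
    if reference == "fibrotest":
        return frame["fibrotest"]
    dev = Device(reference)
    return frame[f"std_elasticity_{dev.value}"]


def screen_criterion(
    frame: pd.DataFrame,
    criterion: CriterionSpec | Criterion,
    references=("fibrotest", Device.TE_M, Device.TE_XL),
    min_bin_n: int = 10,
) -> ScreenReport:
    """Bin the reliability population by a criterion and test concordance.

    ``frame`` must carry ``std_elasticity_swe`` (see standardize module) and
    be restricted to the 2D-SWE reliability population. The first reference
    is primary and drives flagging/discriminance; bins with fewer than
    ``min_bin_n`` complete pairs are excluded with a notice.
    """
    if isinstance(criterion, (Criterion, str)):
        criterion = CriterionSpec.default(Criterion(criterion))
    col = _CRITERION_COLUMNS[criterion.name]
    values = frame[col].to_numpy(float)
    swe = frame["std_elasticity_swe"]
    bins = criterion.assign(values)
    labels = criterion.bin_labels()
    rows = []
    flagged, tested = [], []
    primary = references[0]
    for b, label in enumerate(labels):
        in_bin = (bins == b) & ~np.isnan(values)
        for ref in references:
            ref_name = ref if isinstance(ref, str) and ref == "fibrotest" else Device(ref).value
            pair = pd.DataFrame({"x": swe[in_bin], "y": _reference_series(frame, ref)[in_bin]}).dropna()
            if len(pair) < min_bin_n:
                logger.info("bin %s excluded for %s: n=%d < %d", label, ref_name, len(pair), min_bin_n)
                continue
            res = lin_ccc(pair["x"], pair["y"], stratum=label)
            rows.append(
                {
                    "bin": label,
                    "reference": ref_name,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                }
            )
            if ref is primary:
                tested.append(label)
                if res.ci_low <= 0.0 <= res.ci_high:
                    flagged.append(label)
    discriminant = bool(flagged) and len(flagged) < len(tested)
    return ScreenReport(
        criterion=criterion.name,
        grid=pd.DataFrame(rows),
        flagged_bins=tuple(flagged),
        tested_bins=tuple(tested),
        discriminant=discriminant,
    )


def classify_swe_reliability(m, min_cutoff_kpa: float = 0.2) -> bool:
    """Reliability of one 2D-SWE measurement by the minimal-signal rule.

    Reliable iff the minimal region-of-interest value is at or above the
    cutoff (the 0.2 kPa boundary itself is reliable). A failed measurement
    is *not applicable*, which is distinct from not reliable.
    """
    if m.failed:
        raise ValueError("failed measurement: applicability, not reliability, applies")
    if m.min_kpa is None:
        raise ValueError("min_kpa absent")
    return m.min_kpa >= min_cutoff_kpa
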