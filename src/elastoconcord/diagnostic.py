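"""Diagnostic performance: logistic adjustment, nonparametric AUROC with
paired comparison, intention-to-diagnose analysis and presumed prevalence.

The endpoint throughout is severe fibrosis (F3F4) presumed by the
FibroTest cutoff (a configurable assumption; the published manuals' value
is the default). AUROCs use the Mann-Whitney estimator with midrank tie
handling; variances and the paired device comparison follow the
DeLong placement-value approach, the covariance-based method for
correlated ROC curves described in Zhou, Obuchowski & McClish.

Intention-to-diagnose analyses retain patients whose measurement failed or
was not reliable, substituting the worst-case value 1 - FibroTest for the
missing standardized elasticity; per-protocol analyses keep applicable
measurements only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .applicability import ProportionResult, wilson_ci
from .cohort import Device

#: default FibroTest cutoff presuming METAVIR F3F4 (published manual value)
DEFAULT_F3F4_FT_CUTOFF = 0.58


@dataclass(frozen=True)
class AurocResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    variance: float


@dataclass(frozen=True)
class AurocComparison:
    auroc_a: float
    auroc_b: float
    difference: float
    z: float
    p_value: float


@dataclass
class LogisticModel:
    """Thin result wrapper around the IRLS binomial fit."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    loglik: float
    linear_predictor: np.ndarray
    results: object  # underlying statsmodels results, for diagnostics

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self):
        return self.results.summary()


class Combiner(str, Enum):
    SINGLE = "SINGLE"
    WORST_OF_THREE = "WORST_OF_THREE"
    CONCORDANT_ONLY = "CONCORDANT_ONLY"


def fit_logistic(y, X, tol: float = 1e-8, max_iter: int = 100, add_constant: bool = True) -> LogisticModel:
    """Binomial GLM by iteratively reweighted least squares.

    ``X`` may be a DataFrame (column names kept) or array. Perfect
    separation is flagged via ``converged=False`` rather than raised.
    """
    y = np.asarray(y, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("endpoint must be binary 0/1")
    if isinstance(X, pd.DataFrame):
        exog = X.astype(float)
    else:
        exog = pd.DataFrame(np.asarray(X, float))
        exog.columns = [f"x{i}" for i in range(exog.shape[1])]
    if add_constant:
        exog = sm.add_constant(exog, has_constant="skip")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("singular design matrix")
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
            converged = bool(getattr(res, "converged", True))
            # near-separation shows up as exploding coefficients
            if (
                np.any(np.abs(res.params) > 1e3)
                or np.any(res.bse > 1e3)
                or not np.all(np.isfinite(res.bse))
            ):
                converged = False
        except Exception:
            res = model.fit(maxiter=max_iter, tol=tol, method="lbfgs")
            converged = False
        loglik = float(res.llf)
    return LogisticModel(
        params=res.params,
        bse=res.bse,
        converged=converged,
        loglik=loglik,
        linear_predictor=np.asarray(exog.to_numpy() @ res.params.to_numpy(), float),
        results=res,
    )


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (per case) and V01 (per control)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # midrank computation over the pooled sample
    order = np.concatenate([pos, neg])
    ranks = stats.rankdata(order)
    rank_pos = ranks[:m]
    rank_neg = ranks[m:]
    v10 = (rank_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (rank_neg - stats.rankdata(neg)) / m
    return v10, v01


def auroc(scores, y, level: float = 0.95) -> AurocResult:
    """Nonparametric (Mann-Whitney) AUROC with DeLong variance and CI."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    if scores.shape != y.shape:
        raise ValueError("length mismatch")
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    v10, v01 = _placements(scores, y)
    # rank-sum form: one division, exact agreement with pair counting
    ranks = stats.rankdata(scores)
    u = float(ranks[y == 1].sum()) - m * (m + 1) / 2
    a = u / (m * n)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    zc = stats.norm.ppf(0.5 + level / 2)
    half = zc * np.sqrt(var)
    return AurocResult(a, max(0.0, a - half), min(1.0, a + half), m, n, float(var))


def compare_auroc_paired(scores_a, scores_b, y) -> AurocComparison:
    """Paired comparison of two AUROCs on the same patients (DeLong)."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    y = np.asarray(y, int)
    if scores_a.shape != scores_b.shape or scores_a.shape != y.shape:
        raise ValueError("length mismatch")
    v10a, v01a = _placements(scores_a, y)
    v10b, v01b = _placements(scores_b, y)
    aa, ab = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    diff = aa - ab
    if var <= 0.0:
        z = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return AurocComparison(aa, ab, diff, float(z), p)


def itd_analysis(
    frame: pd.DataFrame,
    device,
    ft_cutoff: float = DEFAULT_F3F4_FT_CUTOFF,
) -> dict:
    """Per-protocol vs intention-to-diagnose AUROC for one device.

    ``frame`` must carry applicability statuses and standardized elasticity
    and be restricted to the intention-to-diagnose population (reliable
    FibroTest). Returns ``{"per_protocol": AurocResult, "itd": AurocResult}``.
    """
    dev = Device(device)
    required = (f"status_{dev.value}", f"std_elasticity_{dev.value}", "fibrotest")
    for c in required:
        if c not in frame.columns:
            raise ValueError(f"missing column {c}; run applicability/standardization first")
    y = (frame["fibrotest"] >= ft_cutoff).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("degenerate endpoint: all patients on one side of the cutoff")
    applicable = (frame[f"status_{dev.value}"] == "APPLICABLE").to_numpy()
    std = frame[f"std_elasticity_{dev.value}"].to_numpy(float)
    pp = auroc(std[applicable], y[applicable]) if applicable.any() else None
    itd_scores = np.where(applicable, std, 1.0 - frame["fibrotest"].to_numpy(float))
    itd = auroc(itd_scores, y)
    return {"per_protocol": pp, "itd": itd}


def presumed_prevalence(
    frame: pd.DataFrame,
    devices,
    stiffness_cutoff_kpa: float = 9.5,
    combiner: Combiner | str = Combiner.SINGLE,
    statistic: str = "mean",
) -> ProportionResult:
    """Presumed F3F4 prevalence from raw-kPa elasticity cutoffs.

    SINGLE classifies by the first device in ``devices``; WORST_OF_THREE by
    the maximum across devices; CONCORDANT_ONLY restricts to patients whose
    per-device classifications all agree and reports prevalence among them.
    Patients missing a required measurement are excluded.
    """
    combiner = Combiner(combiner)
    devs = [Device(d) for d in devices]
    cols = [f"{d.value}_{statistic}_kpa" for d in devs]
    data = frame[cols].dropna()
    if combiner is Combiner.SINGLE:
        cls = data[cols[0]] >= stiffness_cutoff_kpa
        num, den = int(cls.sum()), len(cls)
    elif combiner is Combiner.WORST_OF_THREE:
        cls = data.max(axis=1) >= stiffness_cutoff_kpa
        num, den = int(cls.sum()), len(cls)
    else:
        per_dev = data.ge(stiffness_cutoff_kpa)
        agree = per_dev.nunique(axis=1) == 1
        cls = per_dev.loc[agree].iloc[:, 0]
        num, den = int(cls.sum()), int(agree.sum())
    if den == 0:
        raise ValueError("no classifiable patients")
    return wilson_ci(num, den)
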