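"""Curve fitting of standardized elasticity against reference scores.

The relation between elasticity and a blood-test score is poorly served by
a single straight line (elasticity keeps rising steeply in severe
fibrosis), so the model of interest is a continuous piecewise-linear
("three-part") regression with two free breakpoints, compared against
ordinary least squares by R². Breakpoints are chosen by exhaustive grid
search over quantile-spaced candidates minimising the residual sum of
squares; continuity at the breakpoints is enforced through a truncated
power basis {1, x, (x-b1)+, (x-b2)+}.

:class:`SegmentedRegression` is the model object; ``fit()`` returns a
:class:`SegmentedRegressionResults` carrying breakpoints, per-segment
slopes/intercepts, R², SSE, a ``predict`` method and a ``summary`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Device


@dataclass(frozen=True)
class R2Comparison:
    r2_a: float
    r2_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int


class SegmentedRegressionResults:
    """Fit results of a (piecewise-)linear regression.

    Attributes
    ----------
    k_segments : 1 or 3
    breakpoints : tuple of breakpoint abscissae (empty for k=1)
    slopes, intercepts : per-segment line parameters, left to right
    r2, sse : goodness of fit
    """

    def __init__(self, model, coefs, breakpoints, sse):
        self.model = model
        self._coefs = np.asarray(coefs, float)
        self.breakpoints = tuple(float(b) for b in breakpoints)
        self.k_segments = 1 if not self.breakpoints else len(self.breakpoints) + 1
        self.sse = float(sse)
        sst = float(((model.y - model.y.mean()) ** 2).sum())
        self.r2 = 0.0 if sst == 0.0 else max(0.0, 1.0 - self.sse / sst)
        self.nobs = len(model.y)
        # derive per-segment slope/intercept from the truncated-power coefs
        c = self._coefs
        slopes = [c[1]]
        intercepts = [c[0]]
        for j, b in enumerate(self.breakpoints):
            slopes.append(slopes[-1] + c[2 + j])
            intercepts.append(intercepts[-1] - c[2 + j] * b)
        self.slopes = tuple(float(s) for s in slopes)
        self.intercepts = tuple(float(a) for a in intercepts)

    def predict(self, x) -> np.ndarray:
        X = self.model._design(np.asarray(x, float), self.breakpoints)
        return X @ self._coefs

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.predict(self.model.x)

    def summary(self) -> pd.DataFrame:
        rows = []
        edges = (-np.inf, *self.breakpoints, np.inf)
        for i, (s, a) in enumerate(zip(self.slopes, self.intercepts)):
            rows.append(
                {
                    "segment": i + 1,
                    "from": edges[i],
                    "to": edges[i + 1],
                    "slope": s,
                    "intercept": a,
                }
            )
        out = pd.DataFrame(rows)
        out.attrs.update(r2=self.r2, sse=self.sse, nobs=self.nobs)
        return out


class SegmentedRegression:
    """Continuous piecewise-linear model of y on x.

    Parameters
    ----------
    y, x : 1-d response and predictor vectors
    n_segments : 1 (ordinary least squares) or 3 (two free breakpoints)
    grid_points : candidate breakpoints per axis, quantile-spaced over the
        5th-95th percentile range of x
    min_per_segment : minimum points each segment must contain
    """

    def __init__(self, y, x, n_segments: int = 3, grid_points: int = 40, min_per_segment: int = 4):
        y = np.asarray(y, float)
        x = np.asarray(x, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d vectors of equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[keep], y[keep]
        if n_segments not in (1, 3):
            raise ValueError("n_segments must be 1 or 3")
        self.n_segments = n_segments
        self.grid_points = int(grid_points)
        self.min_per_segment = int(min_per_segment)
        nmin = 3 if n_segments == 1 else 12
        if len(self.x) < nmin:
            raise ValueError(f"need n >= {nmin} finite points for {n_segments} segments")
        if np.ptp(self.x) == 0.0:
            raise ValueError("constant predictor")

    @staticmethod
    def _design(x: np.ndarray, breakpoints) -> np.ndarray:
        cols = [np.ones_like(x), x]
        for b in breakpoints:
            cols.append(np.maximum(x - b, 0.0))
        return np.column_stack(cols)

    def _lstsq(self, breakpoints):
        X = self._design(self.x, breakpoints)
        coefs, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        sse = float(((self.y - X @ coefs) ** 2).sum())
        return coefs, sse

    def _candidates(self) -> np.ndarray:
        qs = np.linspace(0.05, 0.95, self.grid_points)
        return np.unique(np.quantile(self.x, qs))

    def fit(self) -> SegmentedRegressionResults:
        if self.n_segments == 1:
            coefs, sse = self._lstsq(())
            return SegmentedRegressionResults(self, coefs, (), sse)
        cand = self._candidates()
        xs = np.sort(self.x)
        best = None
        # exhaustive search, ties broken toward the smaller first breakpoint
        # by strict-improvement iteration in grid order
        for i in range(len(cand)):
            b1 = cand[i]
            n_left = np.searchsorted(xs, b1, side="left")
            if n_left < self.min_per_segment:
                continue
            for j in range(i + 1, len(cand)):
                b2 = cand[j]
                n_mid = np.searchsorted(xs, b2, side="left") - n_left
                n_right = len(xs) - n_left - n_mid
                if n_mid < self.min_per_segment or n_right < self.min_per_segment:
                    continue
                coefs, sse = self._lstsq((b1, b2))
                if best is None or sse < best[2] - 1e-15:
                    best = ((b1, b2), coefs, sse)
        if best is None:
            raise ValueError("no feasible segmentation (too few points per segment)")
        (b1, b2), coefs, sse = best
        return SegmentedRegressionResults(self, coefs, (b1, b2), sse)


def fit_linear(x, y) -> SegmentedRegressionResults:
    """Ordinary least-squares line, as a 1-segment fit."""
    return SegmentedRegression(y, x, n_segments=1).fit()


def fit_segmented3(x, y, grid_points: int = 40) -> SegmentedRegressionResults:
    """Continuous three-part linear fit with grid-searched breakpoints."""
    return SegmentedRegression(y, x, n_segments=3, grid_points=grid_points).fit()


def compare_r2(fit_a, fit_b, n_boot: int = 500, seed: int | None = None, level: float = 0.95) -> R2Comparison:
    """Paired bootstrap of R²(fit_a) - R²(fit_b) over patients.

    Both fits must be on the same patients (same x ordering/length). The
    breakpoints of each fit are held fixed; segment coefficients are
    refitted per replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    n = fit_a.nobs
    if fit_b.nobs != n or not np.array_equal(fit_a.model.x, fit_b.model.x):
        raise ValueError("fits must be computed on the same patients")
    rng = np.random.default_rng(seed)

    def r2_of(fit, idx):
        x, y = fit.model.x[idx], fit.model.y[idx]
        X = fit.model._design(x, fit.breakpoints)
        coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ coefs) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        return 0.0 if sst == 0.0 else 1.0 - sse / sst

    diffs = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[k] = r2_of(fit_a, idx) - r2_of(fit_b, idx)
    lo, hi = np.quantile(diffs, [(1 - level) / 2, 0.5 + level / 2])
    p = min(1.0, 2 * min(np.mean(diffs <= 0), np.mean(diffs >= 0)))
    return R2Comparison(
        fit_a.r2, fit_b.r2, fit_a.r2 - fit_b.r2, float(lo), float(hi), float(p), n, n_boot
    )


def impact_table(
    frame: pd.DataFrame,
    devices,
    covariate: str,
    fibrosis_cutoff: float = 0.58,
    model: str = "linear",
    min_n: int = 30,
) -> pd.DataFrame:
    """R² of elasticity on a covariate within fibrosis strata, per device.

    ``covariate`` is ``"actitest"`` or ``"steatotest"``; strata are
    F0F1F2 / F3F4 presumed by FibroTest at ``fibrosis_cutoff``. A flat
    curve (R² near 0) means the device is not impacted by the covariate.
    """
    if covariate not in ("actitest", "steatotest"):
        raise ValueError("covariate must be 'actitest' or 'steatotest'")
    strata = {
        "F0F1F2": frame["fibrotest"] < fibrosis_cutoff,
        "F3F4": frame["fibrotest"] >= fibrosis_cutoff,
    }
    rows = []
    for label, mask in strata.items():
        row: dict = {"stratum": label}
        for dev in devices:
            col = f"std_elasticity_{Device(dev).value}"
            sub = frame.loc[mask, [col, covariate]].dropna()
            if len(sub) < min_n:
                row[f"{Device(dev).value}_r2"] = np.nan
                row[f"{Device(dev).value}_n"] = len(sub)
                continue
            if model == "linear":
                fit = fit_linear(sub[covariate], sub[col])
            elif model == "segmented3":
                fit = fit_segmented3(sub[covariate], sub[col])
            else:
                raise ValueError("model must be 'linear' or 'segmented3'")
            row[f"{Device(dev).value}_r2"] = fit.r2
            row[f"{Device(dev).value}_n"] = fit.nobs
        rows.append(row)
    return pd.DataFrame(rows)


def plot_fit(fit: SegmentedRegressionResults, ax=None, **scatter_kw):
    """Scatter of the data with the fitted curve overlaid (SVG-friendly)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = np.argsort(fit.model.x)
    ax.scatter(fit.model.x, fit.model.y, s=6, alpha=0.3, **scatter_kw)
    ax.plot(fit.model.x[order], fit.predict(fit.model.x[order]), lw=2, color="crimson")
    for b in fit.breakpoints:
        ax.axvline(b, ls=":", color="grey", lw=1)
    ax.set_xlabel("reference score")
    ax.set_ylabel("standardized elasticity")
    return ax
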