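"""Time-series analysis of breeding values and production statistics.

Change-point piecewise regression of breeding values on birth years (single
continuous knot, free slopes, exhaustive least-squares search over candidate
years), percent-change summaries of the fitted population means, a variance
trend from transformed residuals, and ordinary linear trend/percent-change
analysis of year-indexed production series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._rng import substream

__all__ = [
    "ChangePointModel",
    "ChangePointResults",
    "LinearTrend",
    "LinearTrendResults",
    "percent_change_summary",
    "percent_change_predicted",
    "variance_trend",
]


class ChangePointModel:
    """Two-segment linear regression with an estimated change-point year.

    The default model is continuous at the knot with free slopes on both
    sides; a discontinuous variant (independent lines per segment) is
    available for sensitivity analysis. The change point is chosen by
    exhaustive search over observed candidate years minimizing SSE, with ties
    broken toward the earliest year.

    Parameters
    ----------
    years, values : observation pairs (years need not be distinct).
    guard : minimum number of observations required strictly on each side of
        a candidate change point (default 5).
    continuous : if False, fit independent segment lines.
    """

    def __init__(self, years, values, guard: int = 5, continuous: bool = True):
        self.years = np.asarray(years, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values have different lengths")
        if self.years.size < 2 * guard + 4:
            raise ValueError(f"need at least {2 * guard + 4} observations for guard={guard}")
        self.guard = int(guard)
        self.continuous = continuous
        self._candidates = self._candidate_years()
        if self._candidates.size == 0:
            raise ValueError("too few distinct years for a guarded change-point search")

    def _candidate_years(self) -> np.ndarray:
        yrs = np.unique(self.years)
        ok = []
        for c in yrs:
            pre, post = np.sum(self.years < c), np.sum(self.years > c)
            pre_d, post_d = np.unique(self.years[self.years < c]).size, \
                np.unique(self.years[self.years >= c]).size
            if pre >= self.guard and post >= self.guard and pre_d >= 2 and post_d >= 2:
                ok.append(c)
        return np.asarray(ok)

    def _design(self, c: float) -> np.ndarray:
        x = self.years - c
        return np.column_stack([np.ones_like(x), np.minimum(x, 0.0), np.maximum(x, 0.0)])

    def _sse_at(self, c: float) -> tuple[float, np.ndarray]:
        if self.continuous:
            X = self._design(c)
            beta, *_ = np.linalg.lstsq(X, self.values, rcond=None)
            resid = self.values - X @ beta
            return float(resid @ resid), beta
        pre = self.years < c
        beta = np.zeros(4)
        sse = 0.0
        for seg, sl in ((pre, slice(0, 2)), (~pre, slice(2, 4))):
            Xs = np.column_stack([np.ones(seg.sum()), self.years[seg]])
            b, *_ = np.linalg.lstsq(Xs, self.values[seg], rcond=None)
            r = self.values[seg] - Xs @ b
            sse += float(r @ r)
            beta[sl] = b
        return sse, beta

    def fit(self) -> "ChangePointResults":
        best = None
        for c in self._candidates:  # ascending, so ties keep the earliest year
            sse, beta = self._sse_at(c)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, c, beta)
        sse, cp, beta = best
        if self.continuous:
            pre_slope, post_slope = float(beta[1]), float(beta[2])
            pre_int = float(beta[0]) - pre_slope * cp
            post_int = float(beta[0]) - post_slope * cp
        else:
            pre_int, pre_slope, post_int, post_slope = map(float, beta)
        return ChangePointResults(self, float(cp), pre_int, pre_slope, post_int, post_slope,
                                  sse, int(self.years.size))


@dataclass
class ChangePointResults:
    """Fitted two-segment model. Can also be constructed directly from known
    segment parameters (e.g., published fitted values) for percent-change
    arithmetic; model-dependent methods then raise."""

    model: ChangePointModel | None
    cp_year: float
    pre_intercept: float
    pre_slope: float
    post_intercept: float
    post_slope: float
    sse: float
    n: int
    _boot: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_fitted_values(cls, start_year: float, cp_year: float, end_year: float,
                           y_start: float, y_cp: float, y_end: float) -> "ChangePointResults":
        """Reconstruct segment lines from fitted population means at the
        start, change-point and end years (e.g., published values)."""
        pre_slope = (y_cp - y_start) / (cp_year - start_year)
        post_slope = (y_end - y_cp) / (end_year - cp_year)
        return cls(None, cp_year, y_cp - pre_slope * cp_year, pre_slope,
                   y_cp - post_slope * cp_year, post_slope, float("nan"), 0)

    def _require_model(self) -> ChangePointModel:
        if self.model is None:
            raise ValueError("these results were built from fitted values, not data")
        return self.model

    def predict(self, years) -> np.ndarray:
        x = np.asarray(years, dtype=float)
        pre = self.pre_intercept + self.pre_slope * x
        post = self.post_intercept + self.post_slope * x
        return np.where(x < self.cp_year, pre, post)

    def residuals(self) -> np.ndarray:
        m = self._require_model()
        return m.values - self.predict(m.years)

    def single_line_sse(self) -> float:
        m = self._require_model()
        X = np.column_stack([np.ones_like(m.years), m.years])
        beta, *_ = np.linalg.lstsq(X, m.values, rcond=None)
        r = m.values - X @ beta
        return float(r @ r)

    def bootstrap_cp_interval(self, n_boot: int = 200, seed: int = 0,
                              level: float = 0.95) -> tuple[float, float]:
        """Percentile bootstrap interval for the change-point year."""
        rng = substream(seed, "cp-bootstrap")
        m = self.model
        cps = []
        for _ in range(n_boot):
            idx = rng.integers(0, m.years.size, size=m.years.size)
            try:
                sub = ChangePointModel(m.years[idx], m.values[idx], m.guard, m.continuous)
                cps.append(sub.fit().cp_year)
            except ValueError:
                continue
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        cps = np.asarray(cps)
        self._boot = cps
        return float(np.quantile(cps, lo)), float(np.quantile(cps, hi))

    def summary(self) -> str:
        return "\n".join([
            "Change-point piecewise regression",
            f"  n = {self.n}, change-point year = {self.cp_year:.0f}",
            f"  pre:  slope {self.pre_slope:+.5f}/yr, intercept {self.pre_intercept:.3f}",
            f"  post: slope {self.post_slope:+.5f}/yr, intercept {self.post_intercept:.3f}",
            f"  SSE = {self.sse:.4f} (single line: {self.single_line_sse():.4f})",
        ])


def percent_change_summary(fit: ChangePointResults, start_year: float, end_year: float) -> dict:
    """Percent change of the fitted population mean before and after the
    change point: pre = (yhat(CP) - yhat(start))/yhat(start) x 100 and
    post = (yhat(end) - yhat(CP))/yhat(CP) x 100, with per-year rates."""
    cp = fit.cp_year
    if not start_year <= cp <= end_year:
        raise ValueError("change point outside [start_year, end_year]")
    y_start, y_cp, y_end = (float(fit.predict([v])[0]) for v in (start_year, cp, end_year))
    out = {"cp_year": cp, "yhat_start": y_start, "yhat_cp": y_cp, "yhat_end": y_end,
           "undefined": False}
    if y_start == 0 or y_cp == 0:
        out.update(pre_pct=float("nan"), post_pct=float("nan"),
                   pre_pct_per_year=float("nan"), post_pct_per_year=float("nan"),
                   undefined=True)
        return out
    pre = (y_cp - y_start) / y_start * 100.0
    post = (y_end - y_cp) / y_cp * 100.0
    out.update(
        pre_pct=pre, post_pct=post,
        pre_pct_per_year=pre / (cp - start_year) if cp > start_year else float("nan"),
        post_pct_per_year=post / (end_year - cp) if end_year > cp else float("nan"),
    )
    return out


def variance_trend(fit: ChangePointResults) -> ChangePointResults:
    """Change-point regression of transformed residuals on year.

    Residuals are transformed to positive values as sqrt((y - yhat)^2) =
    |y - yhat|; a positive post-change-point slope indicates increasing
    dispersion (additive-variance growth) over time."""
    m = fit._require_model()
    r = np.sqrt(fit.residuals() ** 2)
    return ChangePointModel(m.years, r, guard=m.guard, continuous=m.continuous).fit()


class LinearTrend:
    """Ordinary least-squares trend y = b0 + b1 * year."""

    def __init__(self, years, values):
        self.years = np.asarray(years, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.years.size < 3:
            raise ValueError("need at least three points for a trend")
        if np.unique(self.years).size < 2:
            raise ValueError("all years identical; trend undefined")

    def fit(self) -> "LinearTrendResults":
        X = sm.add_constant(self.years)
        res = sm.OLS(self.values, X).fit()
        return LinearTrendResults(
            beta0=float(res.params[0]), beta1=float(res.params[1]),
            r2=float(res.rsquared), f_stat=float(res.fvalue), p_value=float(res.f_pvalue),
        )


@dataclass
class LinearTrendResults:
    beta0: float
    beta1: float
    r2: float
    f_stat: float
    p_value: float

    def predict(self, years) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(years, dtype=float)

    def summary(self) -> str:
        return (f"Linear trend: yhat = {self.beta0:.6g} + {self.beta1:.6g} * year"
                f"  (R^2 = {self.r2:.3f}, F = {self.f_stat:.1f}, p = {self.p_value:.3g})")


def percent_change_predicted(fit: LinearTrendResults, year0: float, year1: float) -> float:
    """(yhat(year1) - yhat(year0)) / yhat(year0) x 100 on the fitted line."""
    y0 = float(fit.predict([year0])[0])
    y1 = float(fit.predict([year1])[0])
    if y0 == 0:
        raise ZeroDivisionError("predicted value at year0 is zero; percent change undefined")
    return (y1 - y0) / y0 * 100.0
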