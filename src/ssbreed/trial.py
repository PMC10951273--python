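"""Mixed-model analysis of replicated clonal trials.

Fits the linear mixed model with hybrid as the only fixed effect and block,
year, location and their hybrid interactions as random effects (terms absent
from the design are dropped automatically), estimates variance components by
REML, estimated marginal means (EMMs) with Satterthwaite degrees of freedom,
clone-mean broad-sense heritability, genetic-gain contrasts, and AUDPS disease
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RemlResult, reml_factor

__all__ = [
    "VarComps",
    "GainEstimate",
    "TrialModel",
    "TrialResults",
    "heritability_clone_mean",
    "genetic_gain_contrast",
    "gain_percent",
    "audps",
    "harmonic_mean_reps",
]


@dataclass
class VarComps:
    """REML variance components on the observation scale, with the design
    dimensions needed for clone-mean heritability."""

    sigma2_g: float
    sigma2_gxy: float
    sigma2_gxl: float
    sigma2_gxyxl: float
    sigma2_e: float
    y: int
    l: int
    r: float

    def phenotypic_clone_mean(self) -> float:
        """Phenotypic variance on a clone-mean basis."""
        out = self.sigma2_g + self.sigma2_e / (self.r * self.l * self.y)
        if self.y > 1:
            out += self.sigma2_gxy / self.y
        if self.l > 1:
            out += self.sigma2_gxl / self.l + self.sigma2_gxyxl / (self.l * self.y)
        return out


def heritability_clone_mean(vc: VarComps) -> float:
    """Broad-sense heritability on a clone-mean basis:
    H2 = s2_G / (s2_G + s2_GxY/y + s2_GxL/l + s2_GxYxL/(l y) + s2_E/(r l y)).
    Location terms are omitted for single-location designs."""
    denom = vc.phenotypic_clone_mean()
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.sigma2_g / denom


def harmonic_mean_reps(data: pd.DataFrame, y: int, l: int) -> float:
    """Harmonic mean number of replications per hybrid per year-location."""
    counts = data.groupby("hybrid").size().to_numpy() / (y * l)
    return float(len(counts) / np.sum(1.0 / counts))


def _indicator(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(series.astype(str).unique())
    pos = {v: k for k, v in enumerate(levels)}
    Z = np.zeros((len(series), len(levels)))
    Z[np.arange(len(series)), [pos[v] for v in series.astype(str)]] = 1.0
    return Z, levels


class TrialModel:
    """Linear mixed model for long-format clonal trial phenotypes.

    Parameters
    ----------
    data : DataFrame with columns hybrid, block, year, location (optional),
        trait (optional) and value.
    trait : which trait to analyse when several are stacked.
    """

    def __init__(self, data: pd.DataFrame, trait: str | None = None):
        df = data.copy()
        if "location" not in df.columns:
            df["location"] = "L1"
        if "trait" in df.columns:
            traits = df["trait"].unique()
            if trait is None:
                if len(traits) > 1:
                    raise ValueError(f"several traits present, pick one of {list(traits)}")
                trait = traits[0]
            df = df[df["trait"] == trait]
        self.trait = trait
        if df["value"].isna().any() or not np.isfinite(df["value"]).all():
            raise ValueError("phenotype values must be finite")
        key = ["hybrid", "block", "year", "location"]
        if df.duplicated(key).any():
            raise ValueError("duplicated (hybrid, block, year, location) cell")
        if df["hybrid"].nunique() < 2 or len(df) < df["hybrid"].nunique() + 1:
            raise ValueError("need >=2 hybrids and replication to fit the trial model")
        self.data = df.reset_index(drop=True)
        self.n_years = df["year"].nunique()
        self.n_locations = df["location"].nunique()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str | None = None) -> "TrialModel":
        return cls(data, trait=trait)

    def _random_terms(self, include_hybrid: bool) -> dict[str, np.ndarray]:
        df = self.data
        terms: dict[str, np.ndarray] = {}
        if include_hybrid:
            terms["hybrid"] = _indicator(df["hybrid"])[0]
        if df["block"].nunique() > 1:
            terms["block"] = _indicator(df["block"])[0]
        if self.n_years > 1:
            terms["year"] = _indicator(df["year"])[0]
            terms["hybrid:year"] = _indicator(df["hybrid"].astype(str) + "/" + df["year"].astype(str))[0]
        if self.n_locations > 1:
            terms["location"] = _indicator(df["location"])[0]
            terms["hybrid:location"] = _indicator(df["hybrid"].astype(str) + "/" + df["location"].astype(str))[0]
            if self.n_years > 1:
                terms["hybrid:year:location"] = _indicator(
                    df["hybrid"].astype(str) + "/" + df["year"].astype(str) + "/" + df["location"].astype(str))[0]
        return terms

    def fit(self) -> "TrialResults":
        """Fit both parameterizations: hybrid random for variance components
        and clone-mean heritability; hybrid fixed for EMMs and contrasts."""
        df = self.data
        y = df["value"].to_numpy(dtype=float)

        # hybrid random -> variance components
        if df.groupby("hybrid").size().max() < 2:
            raise ValueError("unreplicated design: hybrid variance is inestimable")
        rnd = reml_factor(y, np.ones((len(df), 1)), self._random_terms(include_hybrid=True))
        vc = VarComps(
            sigma2_g=rnd.varcomps.get("hybrid", 0.0),
            sigma2_gxy=rnd.varcomps.get("hybrid:year", 0.0),
            sigma2_gxl=rnd.varcomps.get("hybrid:location", 0.0),
            sigma2_gxyxl=rnd.varcomps.get("hybrid:year:location", 0.0),
            sigma2_e=rnd.varcomps.get("residual", 0.0),
            y=self.n_years, l=self.n_locations,
            r=harmonic_mean_reps(df, self.n_years, self.n_locations),
        )

        # hybrid fixed -> EMMs (cell-means coding; random effects are centered,
        # so GLS hybrid means are least-squares means over the factor margins)
        X, hybrids = _indicator(df["hybrid"])
        fx = reml_factor(y, X, self._random_terms(include_hybrid=False))
        se = np.sqrt(np.diag(fx.cov_beta))
        dfs = np.array([fx.satterthwaite_df(np.eye(len(hybrids))[k]) for k in range(len(hybrids))])
        emm = pd.DataFrame({"hybrid": hybrids, "emm": fx.beta, "se": se, "df": dfs}).set_index("hybrid")
        return TrialResults(self, vc, emm, rnd, fx)


@dataclass
class TrialResults:
    model: TrialModel
    varcomps: VarComps
    emm_table: pd.DataFrame
    reml_random: RemlResult
    reml_fixed: RemlResult

    @property
    def heritability(self) -> float:
        return heritability_clone_mean(self.varcomps)

    def contrast(self, high: str, low: str, n_tests_per_trait: int = 2) -> "GainEstimate":
        return genetic_gain_contrast(self, high, low, n_tests_per_trait)

    def summary(self) -> str:
        vc = self.varcomps
        lines = [
            f"Trial mixed model ({self.model.trait or 'value'})",
            f"  observations: {len(self.model.data)}, hybrids: {len(self.emm_table)}",
            f"  years: {vc.y}, locations: {vc.l}, harmonic-mean reps: {vc.r:.2f}",
            "  variance components (REML):",
            f"    hybrid            {vc.sigma2_g:.4f}",
            f"    hybrid x year     {vc.sigma2_gxy:.4f}",
        ]
        if vc.l > 1:
            lines += [f"    hybrid x location {vc.sigma2_gxl:.4f}",
                      f"    hybrid x yr x loc {vc.sigma2_gxyxl:.4f}"]
        lines += [
            f"    residual          {vc.sigma2_e:.4f}",
            f"  clone-mean H^2: {self.heritability:.3f}",
            f"  REML loglik (hybrid random): {self.reml_random.loglik:.3f}",
        ]
        return "\n".join(lines)


@dataclass
class GainEstimate:
    """Genetic gain contrast between two hybrids' EMMs."""

    high: str
    low: str
    emm_high: float
    emm_low: float
    delta_g: float
    delta_g_pct: float
    se: float | None = None
    t_stat: float | None = None
    df: float | None = None
    p_adj: float | None = None
    pct_reliable: bool = True


def gain_percent(emm_high: float, emm_low: float) -> float:
    """Percent genetic gain: (EMM_1 - EMM_2) / EMM_2 x 100."""
    if emm_low == 0:
        raise ZeroDivisionError("EMM_2 is zero; percent gain undefined")
    return (emm_high - emm_low) / emm_low * 100.0


def genetic_gain_contrast(results: TrialResults, high: str, low: str,
                          n_tests_per_trait: int = 2) -> GainEstimate:
    """Linear contrast EMM_high - EMM_low with a Bonferroni-adjusted p-value
    (default: two tests per trait) and Satterthwaite df."""
    emm = results.emm_table
    for h in (high, low):
        if h not in emm.index:
            raise KeyError(f"hybrid {h!r} not in EMM table")
    e1, e2 = float(emm.loc[high, "emm"]), float(emm.loc[low, "emm"])
    hybrids = list(emm.index)
    c = np.zeros(len(hybrids))
    c[hybrids.index(high)] = 1.0
    c[hybrids.index(low)] = -1.0
    fx = results.reml_fixed
    var = float(c @ fx.cov_beta @ c)
    se = float(np.sqrt(var))
    dg = e1 - e2
    t = dg / se if se > 0 else (0.0 if dg == 0 else np.inf)
    dof = fx.satterthwaite_df(c)
    p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(dof) else 2.0 * stats.norm.sf(abs(t))
    p_adj = min(1.0, p * n_tests_per_trait)
    reliable = e2 > 0
    pct = (dg / e2 * 100.0) if e2 != 0 else float("nan")
    return GainEstimate(high, low, e1, e2, dg, pct, se, t, dof, p_adj, reliable)


def audps(scores, times) -> float:
    """Area under the disease progress stairs.

    AUDPS = AUDPC + (y_1 + y_n)/2 * D/(n-1), where AUDPC is the trapezoid
    area and D = t_n - t_1. For equally spaced times this reduces to
    spacing x sum(y_i).
    """
    y = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("scores and times have different lengths")
    if y.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    audpc = float(np.trapezoid(y, t))
    D = float(t[-1] - t[0])
    return audpc + (y[0] + y[-1]) / 2.0 * D / (y.size - 1)
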