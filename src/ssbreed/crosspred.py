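"""Genomic prediction of cross progeny means and additive variances.

Marker effects are estimated by ridge-regression BLUP (shrinkage from the
REML variance ratio by default); progeny are simulated by meiosis from phased
parents over the genetic map; per-cross predicted means and additive
variances are summarized by parent era relative to a threshold birth year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from ._rng import substream
from .genmap import GeneticMap
from .relmat import GenotypeMatrix
from .reml import reml_dense
from .simulate import HaplotypeSet, gametes

__all__ = [
    "MarkerEffects",
    "CrossPrediction",
    "estimate_marker_effects",
    "simulate_cross",
    "predict_cross",
    "compare_eras",
    "random_phase",
]

DEFAULT_ERA_THRESHOLD = 1953  # logical break point between founder and modern parent eras
DEFAULT_N_PROGENY = 200


@dataclass
class MarkerEffects:
    """Additive marker effects from whole-genome ridge regression."""

    markers: list[str]
    effects: np.ndarray
    intercept: float
    shrinkage: float
    center: np.ndarray  # 2p of the training panel; applied when predicting

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.effects.shape != (len(self.markers),) or self.center.shape != self.effects.shape:
            raise ValueError("effect vector length must equal the marker panel size")

    def gebv(self, dosages: np.ndarray) -> np.ndarray:
        W = np.asarray(dosages, dtype=float) - self.center
        return self.intercept + W @ self.effects


def estimate_marker_effects(geno: GenotypeMatrix, emms: pd.Series,
                            shrinkage: float | str = "reml") -> MarkerEffects:
    """Ridge-regression BLUP of additive marker effects.

    effects = (W'W + lambda I)^-1 W'(y - mu) with W the training dosages
    centered at 2p. ``shrinkage`` is either an explicit positive lambda or
    "reml", in which case lambda = s2_e / s2_beta from a REML fit of the
    equivalent genomic model.
    """
    if len(geno.markers) == 0:
        raise ValueError("no markers in the training panel")
    ids = [str(i) for i in emms.index]
    pos = {v: k for k, v in enumerate(geno.ids)}
    missing = [i for i in ids if i not in pos]
    if missing:
        raise ValueError(f"training ids not genotyped: {missing[:5]}")
    M = geno.imputed()[[pos[i] for i in ids]]
    center = 2.0 * geno.allele_freq
    W = M - center
    y = emms.to_numpy(dtype=float)

    if shrinkage == "reml":
        rml = reml_dense(y, np.ones((len(y), 1)), {"wg": W @ W.T})
        s2b, s2e = rml.varcomps["wg"], rml.varcomps["residual"]
        if s2b <= 0:
            raise ValueError("REML found no marker-associated variance; supply lambda explicitly")
        lam = s2e / s2b
        mu = float(rml.beta[0])
    else:
        lam = float(shrinkage)
        if lam <= 0:
            raise ValueError("ridge shrinkage must be positive")
        mu = float(np.mean(y))

    n, m = W.shape
    resid = y - mu
    if m <= n:
        A = W.T @ W + lam * np.eye(m)
        beta = cho_solve(cho_factor(A), W.T @ resid)
    else:  # dual form for wide panels
        A = W @ W.T + lam * np.eye(n)
        beta = W.T @ cho_solve(cho_factor(A), resid)
    return MarkerEffects(list(geno.markers), beta, mu, lam, center)


def simulate_cross(p1: np.ndarray, p2: np.ndarray, gmap: GeneticMap, n_progeny: int,
                   rng_or_seed=0) -> np.ndarray:
    """Dosage matrix of simulated progeny from two phased parents.

    Each progeny receives one recombinant gamete per parent (Haldane
    recombination from cM distances, no interference).
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else substream(int(rng_or_seed), "cross")
    for p in (p1, p2):
        if np.asarray(p).shape != (2, gmap.n_markers):
            raise ValueError("parents must be phased (2 x n_markers); see random_phase "
                             "for a disclosed heuristic on unphased dosages")
    g1 = gametes(np.asarray(p1), gmap, n_progeny, rng)
    g2 = gametes(np.asarray(p2), gmap, n_progeny, rng)
    return (g1 + g2).astype(float)


@dataclass
class CrossPrediction:
    parent1: str
    parent2: str
    n_progeny: int
    mu_hat: float
    va_hat: float
    era: str | None = None


def predict_cross(p1: np.ndarray, p2: np.ndarray, effects: MarkerEffects, gmap: GeneticMap,
                  n_progeny: int = DEFAULT_N_PROGENY, rng_or_seed=0,
                  parent_ids: tuple[str, str] = ("p1", "p2")) -> CrossPrediction:
    """Predicted progeny mean and additive variance for one cross.

    Progeny GEBVs are intercept + W beta over simulated progeny dosages;
    the additive variance uses the n-1 denominator.
    """
    dos = simulate_cross(p1, p2, gmap, n_progeny, rng_or_seed)
    g = effects.gebv(dos)
    return CrossPrediction(parent_ids[0], parent_ids[1], n_progeny,
                           float(np.mean(g)), float(np.var(g, ddof=1)))


def compare_eras(crosses: list[CrossPrediction], birth_year: pd.Series,
                 threshold_year: int = DEFAULT_ERA_THRESHOLD) -> pd.DataFrame:
    """Summarize predicted means and additive variances by parent era.

    A cross is "pre" iff both parents were born in or before the threshold
    year; crosses with a missing parent birth year are excluded (the count of
    exclusions is reported in the summary attrs).
    """
    year = {str(k): v for k, v in birth_year.items()}
    rows = []
    n_excluded = 0
    for cr in crosses:
        y1, y2 = year.get(cr.parent1), year.get(cr.parent2)
        if y1 is None or y2 is None or np.isnan(y1) or np.isnan(y2):
            n_excluded += 1
            continue
        cr.era = "pre" if (y1 <= threshold_year and y2 <= threshold_year) else "post"
        rows.append({"era": cr.era, "mu_hat": cr.mu_hat, "va_hat": cr.va_hat})
    if not rows:
        raise ValueError("no crosses with known parent birth years")
    df = pd.DataFrame(rows)
    out = df.groupby("era").agg(mean_mu=("mu_hat", "mean"), mean_va=("va_hat", "mean"),
                                n_crosses=("era", "size"))
    out.attrs["n_excluded"] = n_excluded
    out.attrs["threshold_year"] = threshold_year
    return out


def expand_to_panel(effects: MarkerEffects, markers: list[str]) -> MarkerEffects:
    """Align an effect vector to a wider marker panel (e.g., the full map when
    effects were estimated on a QC-filtered subset); absent markers get zero
    effect and zero centering."""
    pos = {m: k for k, m in enumerate(effects.markers)}
    eff = np.zeros(len(markers))
    cen = np.zeros(len(markers))
    for j, m in enumerate(markers):
        k = pos.get(m)
        if k is not None:
            eff[j] = effects.effects[k]
            cen[j] = effects.center[k]
    return MarkerEffects(list(markers), eff, effects.intercept, effects.shrinkage, cen)


def random_phase(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Heuristic phasing of a dosage vector: homozygous sites are fixed and
    heterozygous sites are assigned to a haplotype at random. This destroys
    within-parent linkage phase and is only a disclosed fallback for real
    unphased input; simulated pipelines carry true phase."""
    d = np.asarray(dosage)
    if np.isnan(d).any():
        raise ValueError("impute missing dosages before phasing")
    h1 = np.where(d == 2, 1, 0).astype(np.int8)
    h2 = h1.copy()
    het = d == 1
    pick = rng.integers(0, 2, size=int(het.sum())).astype(bool)
    idx = np.flatnonzero(het)
    h1[idx[pick]] = 1
    h2[idx[~pick]] = 1
    return np.stack([h1, h2])


def crosses_from_program(haps: HaplotypeSet, parent_ids: list[tuple[str, str]],
                         effects: MarkerEffects, n_progeny: int = DEFAULT_N_PROGENY,
                         seed: int = 0) -> list[CrossPrediction]:
    """Predict a batch of crosses from a phased haplotype set."""
    pos = {v: k for k, v in enumerate(haps.ids)}
    rng = substream(seed, "cross-batch")
    out = []
    for p1, p2 in parent_ids:
        cp = predict_cross(haps.haplotypes[pos[p1]], haps.haplotypes[pos[p2]],
                           effects, haps.gmap, n_progeny, rng, (p1, p2))
        out.append(cp)
    return out
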