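"""Additive relationship matrices: pedigree (A), genomic (G), unified (H).

A is built with the tabular method from sorted pedigree records; G with
VanRaden's first method from centered SNP dosages; H by the standard
single-step construction that replaces the genotyped block of A with a tuned,
blended G and propagates the update to pedigree relatives through
A12 A22^-1 corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["GenotypeMatrix", "RelationshipMatrix", "qc_genotypes", "amatrix", "gmatrix", "hmatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix (0/1/2, NaN missing).

    ``allele_freq`` holds per-marker alternate-allele frequencies computed
    from non-missing entries of this matrix.
    """

    ids: list[str]
    markers: list[str]
    dosages: np.ndarray  # float array, NaN for missing
    qc_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError("dosage matrix shape does not match id/marker index")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def allele_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the marker mean 2p
        (used for G construction only; the raw matrix is retained)."""
        out = self.dosages.copy()
        fill = 2.0 * self.allele_freq
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.markers)


@dataclass
class RelationshipMatrix:
    """Symmetric id-indexed additive relationship matrix."""

    kind: str  # "A", "G" or "H"
    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix is not square over its ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        if self.kind not in ("A", "G", "H"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        pos = {v: k for k, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def min_eigenvalue_ratio(self) -> float:
        w = np.linalg.eigvalsh(self.values)
        return float(w[0] / max(w[-1], np.finfo(float).tiny))


def qc_genotypes(geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.10) -> GenotypeMatrix:
    """Drop markers failing minor-allele-frequency or missingness thresholds.

    Markers with MAF < ``maf_min`` (monomorphic markers always fail for any
    positive threshold) or a missing fraction > ``miss_max`` are removed.
    """
    p = geno.allele_freq
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (geno.missing_rate <= miss_max) & ~np.isnan(p)
    if not keep.any():
        raise ValueError("all markers removed by QC; relax maf_min/miss_max")
    return GenotypeMatrix(
        list(geno.ids),
        [m for m, k in zip(geno.markers, keep) if k],
        geno.dosages[:, keep],
        qc_meta={"maf_min": maf_min, "miss_max": miss_max,
                 "n_markers_in": len(geno.markers), "n_markers_out": int(keep.sum())},
    )


def amatrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + a(s,d)/2 with zero contribution from unknown parents;
    a(i,j) = (a(j,s) + a(j,d)) / 2 for previously processed j. Inbreeding is
    F_i = a(i,i) - 1.
    """
    n = len(ped)
    s, d = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return RelationshipMatrix("A", list(ped.ids), A)


def gmatrix(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    W = dosage - 2p per marker (missing entries mean-imputed), then
    G = W W' / (2 * sum_j p_j (1 - p_j)).
    """
    p = geno.allele_freq
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers to build G")
    M = geno.imputed()[:, poly]
    pp = p[poly]
    W = M - 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    G = (W @ W.T) / denom
    return RelationshipMatrix("G", list(geno.ids), G,
                              meta={"n_markers": int(poly.sum()), "denominator": denom})


def _tune_g(G: np.ndarray, A22: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Rescale G to the pedigree scale of the genotyped block: solve
    alpha + beta * mean(diag G) = mean(diag A22) and the same for
    off-diagonal means, then return alpha + beta * G."""
    n = G.shape[0]
    dg, da = float(np.mean(np.diag(G))), float(np.mean(np.diag(A22)))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        og, oa = float(G[off].mean()), float(A22[off].mean())
    else:
        og, oa = 0.0, 0.0
    denom = dg - og
    if abs(denom) < 1e-12:
        return G.copy(), 0.0, 1.0
    beta = (da - oa) / denom
    alpha = da - beta * dg
    return alpha + beta * G, alpha, beta


def hmatrix(A: RelationshipMatrix, G: RelationshipMatrix,
            blend_weight: float = 0.05, tune: bool = True) -> RelationshipMatrix:
    """Unified single-step relationship matrix.

    Steps: (i) optionally tune G to the genotyped block A22 (mean-diagonal and
    mean-off-diagonal matching); (ii) blend Gb = (1-w) G* + w A22; (iii)
    H = A with the genotyped block replaced by Gb and pedigree cross-terms
    updated via A12 A22^-1 (Gb - A22) A22^-1 A21.
    """
    if not 0.0 <= blend_weight <= 1.0:
        raise ValueError("blend_weight must be in [0, 1]")
    missing = set(G.ids) - set(A.ids)
    if missing:
        raise ValueError(f"genotyped ids absent from pedigree matrix: {sorted(missing)[:5]}")
    meta = {"blend_weight": blend_weight, "tune": tune}
    if len(G.ids) == 0:
        return RelationshipMatrix("H", list(A.ids), A.values.copy(), meta)

    pos = {v: k for k, v in enumerate(A.ids)}
    g_idx = np.array([pos[i] for i in G.ids])
    n_idx = np.array([k for k in range(len(A.ids)) if A.ids[k] not in set(G.ids)], dtype=int)

    A22 = A.values[np.ix_(g_idx, g_idx)]
    Gs = G.values
    alpha, beta = 0.0, 1.0
    if tune:
        Gs, alpha, beta = _tune_g(Gs, A22)
    meta.update(tune_alpha=alpha, tune_beta=beta)
    Gb = (1.0 - blend_weight) * Gs + blend_weight * A22

    H = A.values.copy()
    if n_idx.size:
        A12 = A.values[np.ix_(n_idx, g_idx)]
        try:
            A22c = np.linalg.cholesky(A22)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "A22 is singular; use blend_weight > 0 or check duplicate records"
            ) from exc
        # T = A12 A22^-1, via two triangular solves
        from scipy.linalg import solve_triangular

        tmp = solve_triangular(A22c, A12.T, lower=True)
        T = solve_triangular(A22c.T, tmp, lower=False).T
        delta = Gb - A22
        H11_corr = T @ delta @ T.T
        H[np.ix_(n_idx, n_idx)] += H11_corr
        H12 = T @ Gb
        H[np.ix_(n_idx, g_idx)] = H12
        H[np.ix_(g_idx, n_idx)] = H12.T
    H[np.ix_(g_idx, g_idx)] = Gb
    H = 0.5 * (H + H.T)
    return RelationshipMatrix("H", list(A.ids), H, meta)
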