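"""Single-step BLUP of breeding values from EMM phenotypes and a
relationship matrix.

The model is y = 1 mu + Z g + e with g ~ N(0, H s2_g) over every individual
in H (phenotyped or not) and e ~ N(0, I s2_e). Variances are estimated by
REML on the phenotyped subset; breeding values, prediction error variances
and accuracies come from the mixed model equations over all individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relmat import RelationshipMatrix
from .reml import RemlResult, reml_dense

__all__ = ["SingleStepBLUP", "SingleStepResults", "gebv_accuracy", "genetic_correlations"]

_MAX_DENSE_IDS = 5000


def gebv_accuracy(pev, sigma2_a: float) -> tuple[np.ndarray, np.ndarray]:
    """Accuracy = 1 - sqrt(PEV / s2_A), clipped to [0, 1].

    Returns (accuracy, clipped_flag)."""
    if sigma2_a <= 0:
        raise ValueError("additive variance must be positive for accuracy")
    pev = np.asarray(pev, dtype=float)
    if (pev < 0).any():
        raise ValueError("PEV must be non-negative")
    raw = 1.0 - np.sqrt(pev / sigma2_a)
    acc = np.clip(raw, 0.0, 1.0)
    return acc, raw != acc


class SingleStepBLUP:
    """Breeding-value model for all individuals in a relationship matrix.

    Parameters
    ----------
    emms : Series mapping phenotyped id -> EMM (one record per individual).
    relmat : RelationshipMatrix (A, G or H) covering every id to predict.
    birth_year : optional Series id -> year carried through to the output.
    genotyped : optional collection of ids flagged genotyped in the output.
    emm_se : optional Series of EMM standard errors; when given, residual
        variances are proportional to se^2 (normalized to mean one), i.e. the
        EMMs are weighted by their precision. Default is equal weights.
    """

    def __init__(self, emms: pd.Series, relmat: RelationshipMatrix,
                 birth_year: pd.Series | None = None, genotyped=None,
                 emm_se: pd.Series | None = None):
        emms = pd.Series(emms).astype(float)
        if emms.empty:
            raise ValueError("no phenotyped individuals")
        missing = set(map(str, emms.index)) - set(relmat.ids)
        if missing:
            raise ValueError(f"phenotyped ids absent from relationship matrix: {sorted(missing)[:5]}")
        if len(relmat.ids) > _MAX_DENSE_IDS:
            raise ValueError(
                f"{len(relmat.ids)} ids exceeds the dense-solve limit of {_MAX_DENSE_IDS}; "
                "subset the pedigree or analyse cohorts separately")
        self.emms = emms
        self.relmat = relmat
        self.birth_year = birth_year
        self.genotyped = set(map(str, genotyped)) if genotyped is not None else set()
        if emm_se is not None:
            w = pd.Series(emm_se).astype(float).reindex(emms.index).to_numpy() ** 2
            if np.isnan(w).any() or (w <= 0).any():
                raise ValueError("emm_se must be positive and cover every phenotyped id")
            self.res_weights = w / w.mean()
        else:
            self.res_weights = np.ones(len(emms))

    @classmethod
    def from_emm_table(cls, emm_table: pd.DataFrame, relmat: RelationshipMatrix, **kw) -> "SingleStepBLUP":
        return cls(emm_table["emm"], relmat, **kw)

    def fit(self, jitter: float = 1e-8,
            varcomps: tuple[float, float] | None = None) -> "SingleStepResults":
        """REML variances (unless ``varcomps=(s2_g, s2_e)`` is given) followed
        by the mixed-model-equation solve for all individuals."""
        H = self.relmat.values
        ids = list(self.relmat.ids)
        pos = {v: k for k, v in enumerate(ids)}
        ph_idx = np.array([pos[str(i)] for i in self.emms.index])
        y = self.emms.to_numpy()
        n_all, n_ph = len(ids), len(y)

        rw = self.res_weights
        sqw = np.sqrt(rw)
        if varcomps is None:
            Hpp = H[np.ix_(ph_idx, ph_idx)]
            # precision weighting: fold diag(se^2) into the residual by
            # transforming to homoscedastic coordinates
            rml = reml_dense(y / sqw, (1.0 / sqw)[:, None],
                             {"genetic": Hpp / np.outer(sqw, sqw)})
            s2g = rml.varcomps["genetic"]
            s2e = rml.varcomps["residual"]
        else:
            s2g, s2e = map(float, varcomps)
            from .reml import RemlResult

            rml = RemlResult({"genetic": s2g, "residual": s2e}, np.array([np.mean(y)]),
                             np.zeros((1, 1)), float("nan"), [], True, 0)
        mu = float(rml.beta[0])
        if s2g <= 0:
            # no usable genetic signal: everything shrinks to the mean
            gebv = np.zeros(n_all)
            pev = np.full(n_all, 0.0)
            return self._package(mu, s2g, s2e, gebv, pev, rml)

        # a zero residual variance (noise-free EMMs) would make the MME
        # singular for unphenotyped individuals; floor the ratio instead
        lam = max(s2e, 1e-8 * s2g) / s2g
        Hj = H.copy()
        for bump in (0.0, jitter * np.mean(np.diag(H))):
            try:
                cH = cho_factor(Hj + bump * np.eye(n_all))
                break
            except np.linalg.LinAlgError:
                cH = None
        if cH is None:
            w = np.linalg.eigvalsh(H)
            raise np.linalg.LinAlgError(
                f"relationship matrix not PSD beyond jitter (min eig {w[0]:.3e}, max {w[-1]:.3e})")
        Hinv = cho_solve(cH, np.eye(n_all))

        Z = np.zeros((n_ph, n_all))
        Z[np.arange(n_ph), ph_idx] = 1.0
        Dinv = 1.0 / rw
        C = np.zeros((n_all + 1, n_all + 1))
        C[0, 0] = Dinv.sum()
        C[0, 1:] = Z.T @ Dinv
        C[1:, 0] = C[0, 1:]
        C[1:, 1:] = Z.T @ (Dinv[:, None] * Z) + lam * Hinv
        rhs = np.concatenate([[(Dinv * y).sum()], Z.T @ (Dinv * y)])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        mu = float(sol[0])
        gebv = sol[1:]
        pev = s2e * np.diag(Cinv)[1:]
        return self._package(mu, s2g, s2e, gebv, pev, rml)

    def _package(self, mu, s2g, s2e, gebv, pev, rml) -> "SingleStepResults":
        ids = list(self.relmat.ids)
        phenotyped = set(map(str, self.emms.index))
        if s2g > 0:
            acc, clipped = gebv_accuracy(np.maximum(pev, 0.0), s2g)
        else:
            acc = np.zeros(len(ids))
            clipped = np.zeros(len(ids), dtype=bool)
        tbl = pd.DataFrame({
            "id": ids,
            "gebv": gebv,
            "pev": pev,
            "accuracy": acc,
            "accuracy_clipped": clipped,
            "genotyped": [i in self.genotyped for i in ids],
            "phenotyped": [i in phenotyped for i in ids],
        }).set_index("id")
        if self.birth_year is not None:
            tbl.insert(0, "birth_year", self.birth_year.reindex(tbl.index))
        return SingleStepResults(self, mu, s2g, s2e, tbl, rml)


@dataclass
class SingleStepResults:
    model: SingleStepBLUP
    mu: float
    sigma2_g: float
    sigma2_e: float
    gebv_table: pd.DataFrame
    reml: RemlResult

    def summary(self) -> str:
        t = self.gebv_table
        return "\n".join([
            "Single-step BLUP",
            f"  individuals: {len(t)} ({int(t.phenotyped.sum())} phenotyped, "
            f"{int(t.genotyped.sum())} genotyped)",
            f"  mu: {self.mu:.4f}  sigma2_g: {self.sigma2_g:.4f}  sigma2_e: {self.sigma2_e:.4f}",
            f"  mean accuracy: {t.accuracy.mean():.3f}",
            f"  REML converged: {self.reml.converged} in {self.reml.n_iter} iterations",
        ])


def genetic_correlations(gebvs_by_trait: dict[str, pd.Series], ids=None) -> pd.DataFrame:
    """Pairwise Pearson correlations among per-trait GEBVs on the id
    intersection. Pairs with a zero-variance vector are flagged NaN."""
    traits = list(gebvs_by_trait)
    common = None
    for t in traits:
        idx = set(gebvs_by_trait[t].index)
        common = idx if common is None else common & idx
    if ids is not None:
        common &= set(ids)
    common = sorted(common)
    if len(common) < 3:
        raise ValueError("need at least three shared ids across traits")
    M = np.column_stack([gebvs_by_trait[t].loc[common].to_numpy() for t in traits])
    out = np.eye(len(traits))
    sd = M.std(axis=0)
    for a in range(len(traits)):
        for b in range(a + 1, len(traits)):
            if sd[a] == 0 or sd[b] == 0:
                out[a, b] = out[b, a] = np.nan
            else:
                out[a, b] = out[b, a] = float(np.corrcoef(M[:, a], M[:, b])[0, 1])
    return pd.DataFrame(out, index=traits, columns=traits)
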