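"""Cross prediction: ridge marker effects, meiosis simulation, progeny
mean/variance against exhaustive gamete enumeration, era comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ssbreed import (
    CrossPrediction,
    GeneticMap,
    GenotypeMatrix,
    MarkerEffects,
    compare_eras,
    estimate_marker_effects,
    predict_cross,
    simulate_cross,
)
from ssbreed._rng import substream
from ssbreed.crosspred import random_phase


def _training(rng, n=120, m=20, causal=None, noise=0.0):
    dos = rng.integers(0, 3, size=(n, m)).astype(float)
    beta = np.zeros(m)
    if causal:
        for j, a in causal.items():
            beta[j] = a
    y = dos @ beta + rng.normal(0, noise, n) + 3.0
    ids = [f"t{i}" for i in range(n)]
    geno = GenotypeMatrix(ids, [f"m{j}" for j in range(m)], dos)
    return geno, pd.Series(y, index=ids), beta


class TestMarkerEffects:
    def test_small_shrinkage_recovers_noiseless_causal_effect(self, rng):
        geno, y, beta = _training(rng, causal={3: 1.7})
        eff = estimate_marker_effects(geno, y, shrinkage=1e-8)
        assert eff.effects[3] == pytest.approx(1.7, abs=1e-3)
        assert np.allclose(np.delete(eff.effects, 3), 0.0, atol=1e-3)

    def test_duplicate_columns_split_effect_mass(self, rng):
        dos = rng.integers(0, 3, size=(60, 6)).astype(float)
        dos[:, 5] = dos[:, 2]  # duplicate causal column
        y = pd.Series(2.0 * dos[:, 2] + 1.0, index=[f"t{i}" for i in range(60)])
        geno = GenotypeMatrix(list(y.index), [f"m{j}" for j in range(6)], dos)
        eff = estimate_marker_effects(geno, y, shrinkage=1e-6)
        assert eff.effects[2] == pytest.approx(eff.effects[5], rel=1e-6)
        assert eff.effects[2] + eff.effects[5] == pytest.approx(2.0, abs=1e-3)

    def test_reml_shrinkage_recovers_signal(self):
        # median over a seed batch: estimated effects correlate with truth and
        # fitted GEBVs correlate with true breeding values
        r_eff, r_gebv = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            m = 80
            true = rng.normal(0, 0.2, m)
            dos = rng.integers(0, 3, size=(400, m)).astype(float)
            y = pd.Series(dos @ true + rng.normal(0, 1.0, 400),
                          index=[f"t{i}" for i in range(400)])
            geno = GenotypeMatrix(list(y.index), [f"m{j}" for j in range(m)], dos)
            eff = estimate_marker_effects(geno, y)
            r_eff.append(np.corrcoef(eff.effects, true)[0, 1])
            W = dos - eff.center
            r_gebv.append(np.corrcoef(W @ eff.effects, dos @ true)[0, 1])
        assert np.median(r_eff) > 0.5
        assert np.median(r_gebv) > 0.8

    def test_invalid_shrinkage_rejected(self, rng):
        geno, y, _ = _training(rng)
        with pytest.raises(ValueError):
            estimate_marker_effects(geno, y, shrinkage=-1.0)

    def test_ungenotyped_training_id_rejected(self, rng):
        geno, y, _ = _training(rng)
        y2 = pd.concat([y, pd.Series([1.0], index=["missing"])])
        with pytest.raises(ValueError, match="not genotyped"):
            estimate_marker_effects(geno, y2)


class TestSimulateCross:
    def test_homozygous_parents_give_fixed_progeny(self):
        gmap = GeneticMap.uniform(4, n_chrom=2)
        p1 = np.array([[1, 1, 0, 0]] * 2, dtype=np.int8)
        p2 = np.array([[0, 1, 1, 0]] * 2, dtype=np.int8)
        dos = simulate_cross(p1, p2, gmap, 50, 0)
        assert np.allclose(dos, np.tile([1, 2, 1, 0], (50, 1)))

    def test_het_cross_mendelian_mean(self):
        gmap = GeneticMap.uniform(1)
        p1 = np.array([[1], [0]], dtype=np.int8)  # Aa
        p2 = np.array([[0], [0]], dtype=np.int8)  # aa
        dos = simulate_cross(p1, p2, gmap, 200, 1)
        assert set(np.unique(dos)) <= {0.0, 1.0}
        assert abs(dos.mean() - 0.5) < 2.576 * np.sqrt(0.25 / 200)

    def test_unphased_parent_rejected(self):
        gmap = GeneticMap.uniform(3)
        with pytest.raises(ValueError, match="phased"):
            simulate_cross(np.array([1.0, 0.0, 2.0]), np.zeros((2, 3)), gmap, 10)

    def test_random_phase_consistent_with_dosage(self, rng):
        d = np.array([0, 1, 2, 1, 0], dtype=float)
        h = random_phase(d, rng)
        assert np.allclose(h.sum(axis=0), d)


def _enumerate_cross(p1, p2, beta, intercept):
    """Exact progeny GEBV distribution for unlinked markers by enumerating
    all gamete combinations of both parents."""
    def gams(p):
        return [np.array(c) for c in itertools.product(*[(p[0, j], p[1, j])
                                                         for j in range(p.shape[1])])]
    vals = []
    for g1 in gams(p1):
        for g2 in gams(p2):
            vals.append(intercept + float((g1 + g2) @ beta))
    vals = np.array(vals)
    mu = vals.mean()
    var = vals.var(ddof=0)
    mu4 = ((vals - mu) ** 4).mean()
    return mu, var, mu4


class TestPredictCross:
    def test_identical_inbred_parents_no_variance(self):
        gmap = GeneticMap.uniform(5)
        eff = MarkerEffects([f"M{k:05d}" for k in range(5)], np.ones(5), 1.0, 1.0,
                            np.zeros(5))
        hom = np.array([[1, 0, 1, 0, 1]] * 2, dtype=np.int8)
        cp = predict_cross(hom, hom, eff, gmap, n_progeny=100, rng_or_seed=0)
        assert cp.va_hat == 0.0

    def test_single_het_marker_variance_quarter_a_squared(self):
        gmap = GeneticMap.uniform(1)
        a = 1.4
        eff = MarkerEffects(["M00000"], np.array([a]), 0.0, 1.0, np.zeros(1))
        het = np.array([[1], [0]], dtype=np.int8)
        hom = np.array([[0], [0]], dtype=np.int8)
        n = 200
        cp = predict_cross(het, hom, eff, gmap, n_progeny=n, rng_or_seed=2)
        truth = a * a / 4
        se = truth * np.sqrt(2.0 / (n - 1))  # sampling error of a variance
        assert abs(cp.va_hat - truth) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = 3
        gmap = GeneticMap(tuple(f"m{j}" for j in range(m)),
                          tuple(f"chr{j}" for j in range(m)), (0.0,) * m)
        beta = rng.normal(0, 1, m)
        eff = MarkerEffects([f"m{j}" for j in range(m)], beta, 2.0, 1.0, np.zeros(m))
        p1 = rng.integers(0, 2, (2, m)).astype(np.int8)
        p2 = rng.integers(0, 2, (2, m)).astype(np.int8)
        mu, var, mu4 = _enumerate_cross(p1, p2, beta, 2.0)
        n = 200
        cp = predict_cross(p1, p2, eff, gmap, n_progeny=n, rng_or_seed=seed)
        se_mu = np.sqrt(var / n)
        var_of_var = (mu4 - var**2 * (n - 3) / (n - 1)) / n
        assert abs(cp.mu_hat - mu) <= 3 * se_mu + 1e-12
        assert abs(cp.va_hat - var) <= 3 * np.sqrt(max(var_of_var, 0)) + 1e-12

    def test_intercept_shift_moves_mean_not_variance(self):
        gmap = GeneticMap.uniform(4)
        rng = np.random.default_rng(3)
        p1 = rng.integers(0, 2, (2, 4)).astype(np.int8)
        p2 = rng.integers(0, 2, (2, 4)).astype(np.int8)
        beta = rng.normal(0, 1, 4)
        a = MarkerEffects(list(gmap.marker_id), beta, 0.0, 1.0, np.zeros(4))
        b = MarkerEffects(list(gmap.marker_id), beta, 5.0, 1.0, np.zeros(4))
        ca = predict_cross(p1, p2, a, gmap, 100, 7)
        cb = predict_cross(p1, p2, b, gmap, 100, 7)
        assert cb.mu_hat == pytest.approx(ca.mu_hat + 5.0, abs=1e-10)
        assert cb.va_hat == pytest.approx(ca.va_hat, abs=1e-10)

    def test_doubling_effects_quadruples_variance(self):
        gmap = GeneticMap.uniform(4)
        rng = np.random.default_rng(4)
        p1 = rng.integers(0, 2, (2, 4)).astype(np.int8)
        p2 = rng.integers(0, 2, (2, 4)).astype(np.int8)
        beta = rng.normal(0, 1, 4)
        a = MarkerEffects(list(gmap.marker_id), beta, 0.0, 1.0, np.zeros(4))
        b = MarkerEffects(list(gmap.marker_id), 2 * beta, 0.0, 1.0, np.zeros(4))
        ca = predict_cross(p1, p2, a, gmap, 100, 8)
        cb = predict_cross(p1, p2, b, gmap, 100, 8)
        assert cb.va_hat == pytest.approx(4 * ca.va_hat, rel=1e-10)

    def test_reciprocal_crosses_match_in_distribution(self):
        gmap = GeneticMap.uniform(6, n_chrom=2)
        rng = np.random.default_rng(5)
        p1 = rng.integers(0, 2, (2, 6)).astype(np.int8)
        p2 = rng.integers(0, 2, (2, 6)).astype(np.int8)
        beta = rng.normal(0, 1, 6)
        eff = MarkerEffects(list(gmap.marker_id), beta, 0.0, 1.0, np.zeros(6))
        mus_a = [predict_cross(p1, p2, eff, gmap, 200, s).mu_hat for s in range(12)]
        mus_b = [predict_cross(p2, p1, eff, gmap, 200, s + 100).mu_hat for s in range(12)]
        pooled_sd = np.std(mus_a + mus_b, ddof=1)
        assert abs(np.mean(mus_a) - np.mean(mus_b)) < 3 * pooled_sd / np.sqrt(6)


class TestCompareEras:
    @staticmethod
    def _crosses():
        return [CrossPrediction("a", "b", 200, 1.0, 0.1),
                CrossPrediction("a", "c", 200, 2.0, 0.2),
                CrossPrediction("c", "d", 200, 3.0, 0.3)]

    def test_all_pre_threshold_single_era(self):
        by = pd.Series({"a": 1900, "b": 1910, "c": 1920, "d": 1930})
        out = compare_eras(self._crosses(), by, threshold_year=1953)
        assert list(out.index) == ["pre"]
        assert out.loc["pre", "n_crosses"] == 3

    def test_threshold_splits_eras(self):
        by = pd.Series({"a": 1900, "b": 1910, "c": 1970, "d": 1980})
        out = compare_eras(self._crosses(), by, threshold_year=1953)
        assert out.loc["pre", "n_crosses"] == 1
        assert out.loc["post", "n_crosses"] == 2  # mixed-era cross counts as post

    def test_missing_birth_year_excluded_with_count(self):
        by = pd.Series({"a": 1900, "b": 1910, "c": np.nan, "d": 1980})
        out = compare_eras(self._crosses(), by, threshold_year=1953)
        assert out.attrs["n_excluded"] == 2
        assert out["n_crosses"].sum() == 1

    def test_no_usable_crosses_rejected(self):
        by = pd.Series({"a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan})
        with pytest.raises(ValueError):
            compare_eras(self._crosses(), by)
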