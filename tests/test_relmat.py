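"""Relationship matrices: QC filters, tabular-method A, VanRaden G, and the
single-step H construction, checked against textbook values, hand counts and
a gene-dropping IBD oracle."""

import numpy as np
import pandas as pd
import pytest

from ssbreed import (
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
    amatrix,
    gmatrix,
    hmatrix,
    qc_genotypes,
)


def gene_drop_relationship(ped: Pedigree, n_drops: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo IBD oracle: founders carry unique alleles, alleles drop
    through the pedigree, and a_ij = 2 * P(random allele of i IBD to random
    allele of j) estimated over replicates."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    s, d = ped.parent_indices()
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_allele = 1
    for i in range(n):
        for slot, parent in ((0, s[i]), (1, d[i])):
            if parent < 0:
                alleles[:, i, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, slot] = alleles[np.arange(n_drops), parent, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = sum((alleles[:, i, a] == alleles[:, j, b]).mean()
                        for a in range(2) for b in range(2))
            A[i, j] = A[j, i] = match / 2.0
    return A


def random_pedigree(n: int, seed: int) -> Pedigree:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        if i < 6:
            rows.append((f"I{i}", "0", "0", 1900))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            rows.append((f"I{i}", f"I{s}", f"I{d}", 1900 + i))
    return Pedigree.from_frame(pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year"]))


class TestQC:
    def test_monomorphic_marker_dropped(self):
        geno = GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2"],
                              np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=float))
        out = qc_genotypes(geno, maf_min=0.01, miss_max=1.0)
        assert out.markers == ["m2"]

    def test_half_missing_marker_dropped(self):
        dos = np.array([[1, 1], [np.nan, 0], [1, 1], [np.nan, 2]])
        out = qc_genotypes(GenotypeMatrix(list("abcd"), ["m1", "m2"], dos),
                           maf_min=0.0, miss_max=0.10)
        assert out.markers == ["m2"]

    def test_hand_counted_toy_panel(self):
        # five individuals, four markers: m1 monomorphic, m2 MAF=0.1 (<0.2),
        # m3 40% missing, m4 passes (MAF 0.4, no missing)
        dos = np.array([
            [0, 0, 1, 1],
            [0, 0, np.nan, 2],
            [0, 0, 1, 0],
            [0, 1, np.nan, 1],
            [0, 0, 1, 0],
        ], dtype=float)
        out = qc_genotypes(GenotypeMatrix(list("abcde"), ["m1", "m2", "m3", "m4"], dos),
                           maf_min=0.2, miss_max=0.2)
        assert out.markers == ["m4"]
        assert out.qc_meta["n_markers_out"] == 1

    def test_all_filtered_raises(self):
        geno = GenotypeMatrix(["a", "b"], ["m1"], np.array([[0.0], [0.0]]))
        with pytest.raises(ValueError, match="all markers"):
            qc_genotypes(geno)

    def test_imputation_fills_two_p(self):
        dos = np.array([[2, 1], [0, 1], [np.nan, 1]])
        geno = GenotypeMatrix(list("abc"), ["m1", "m2"], dos)
        imp = geno.imputed()
        assert imp[2, 0] == pytest.approx(1.0)  # 2p = 2 * 0.5
        assert np.isnan(geno.dosages[2, 0])  # raw matrix retained


class TestAmatrix:
    def test_unrelated_founders_identity(self):
        ped = Pedigree.from_frame(pd.DataFrame(
            {"id": ["x", "y"], "sire": ["0", "0"], "dam": ["0", "0"], "birth_year": [1, 1]}))
        assert np.allclose(amatrix(ped).values, np.eye(2))

    def test_textbook_relationships(self, toy_pedigree):
        A = amatrix(toy_pedigree)
        df = A.to_frame()
        assert df.loc["A", "C"] == pytest.approx(0.5)   # parent-offspring
        assert df.loc["C", "D"] == pytest.approx(0.5)   # full sibs
        assert df.loc["A", "A"] == pytest.approx(1.0)   # non-inbred founder
        # E's parents are full sibs: F_E = a(C,D)/2 = 0.25
        assert df.loc["E", "E"] == pytest.approx(1.25)

    def test_selfed_offspring_diagonal(self):
        ped = Pedigree.from_frame(pd.DataFrame(
            {"id": ["p", "s"], "sire": ["0", "p"], "dam": ["0", "p"], "birth_year": [1, 2]}))
        A = amatrix(ped)
        assert A.to_frame().loc["s", "s"] == pytest.approx(1.5)

    def test_non_inbred_pedigree_unit_diagonal(self):
        ped = Pedigree.from_frame(pd.DataFrame({
            "id": ["a", "b", "c", "d", "e"],
            "sire": ["0", "0", "a", "a", "0"],
            "dam": ["0", "0", "b", "b", "0"],
            "birth_year": [1, 1, 2, 2, 1]}))
        A = amatrix(ped)
        assert np.allclose(np.diag(A.values), 1.0)

    def test_positive_semidefinite(self):
        A = amatrix(random_pedigree(40, seed=11))
        assert A.min_eigenvalue_ratio() >= -1e-8

    def test_matches_gene_dropping_oracle_quick(self):
        ped = random_pedigree(15, seed=2)
        A = amatrix(ped).values
        drops = 20_000
        est = gene_drop_relationship(ped, drops, seed=3)
        se = np.sqrt(np.maximum(est * (2 - est), 1e-4) / drops)  # conservative
        assert np.all(np.abs(A - est) < 4 * se + 3.0 / np.sqrt(drops))

    def test_cycle_detected(self):
        df = pd.DataFrame({"id": ["a", "b"], "sire": ["b", "a"],
                           "dam": ["0", "0"], "birth_year": [1, 2]})
        with pytest.raises(Exception, match="cycle"):
            Pedigree.from_frame(df)


class TestGmatrix:
    def test_identical_rows_share_diagonal_and_offdiagonal(self):
        dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=float)
        G = gmatrix(GenotypeMatrix(list("abc"), list("wxyz"), dos)).values
        assert G[0, 0] == pytest.approx(G[1, 1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_dosage_row_is_centered_out(self):
        dos = np.array([[0, 0], [2, 2], [1, 1]], dtype=float)  # p = 0.5 each
        G = gmatrix(GenotypeMatrix(list("abc"), ["m1", "m2"], dos)).values
        assert np.allclose(G[2], 0.0)

    def test_full_sib_mean_relationship_near_half(self, rng):
        # one full-sib family embedded in a large unrelated reference panel,
        # so the panel-estimated allele frequencies approximate the base
        # population and the expected sib relationship is 1/2
        m, n_ref, n_sib = 600, 600, 10
        p = rng.uniform(0.1, 0.9, m)
        ref = (rng.random((n_ref, 2, m)) < p).sum(axis=1).astype(float)
        pa = (rng.random((2, m)) < p).astype(np.int8)
        pb = (rng.random((2, m)) < p).astype(np.int8)
        sibs = []
        for _ in range(n_sib):
            g1 = pa[rng.integers(0, 2, m), np.arange(m)]
            g2 = pb[rng.integers(0, 2, m), np.arange(m)]
            sibs.append(g1 + g2)
        dos = np.vstack([ref, np.array(sibs, dtype=float)])
        ids = [f"r{i}" for i in range(n_ref)] + [f"s{i}" for i in range(n_sib)]
        G = gmatrix(GenotypeMatrix(ids, [f"m{j}" for j in range(m)], dos)).values
        sib_block = G[n_ref:, n_ref:]
        vals = sib_block[~np.eye(n_sib, dtype=bool)]
        assert abs(vals.mean() - 0.5) < 0.06

    def test_fixed_panel_raises(self):
        dos = np.array([[0, 2], [0, 2]], dtype=float)
        with pytest.raises(ValueError):
            gmatrix(GenotypeMatrix(["a", "b"], ["m1", "m2"], dos))


class TestHmatrix:
    @staticmethod
    def _toy():
        ped = Pedigree.from_frame(pd.DataFrame({
            "id": ["f1", "f2", "f3", "c1", "c2", "c3"],
            "sire": ["0", "0", "0", "f1", "f1", "c1"],
            "dam": ["0", "0", "0", "f2", "f3", "c2"],
            "birth_year": [1, 1, 1, 2, 2, 3]}))
        A = amatrix(ped)
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(2, 30)).astype(float)
        G = gmatrix(GenotypeMatrix(["c1", "c3"], [f"m{j}" for j in range(30)], dos))
        return A, G

    def test_no_genotyped_returns_a(self):
        A, _ = self._toy()
        empty_G = RelationshipMatrix("G", [], np.zeros((0, 0)))
        H = hmatrix(A, empty_G)
        assert np.allclose(H.values, A.values)

    def test_all_genotyped_untuned_unblended_returns_g(self):
        _, G = self._toy()
        A22 = amatrix(Pedigree.from_frame(pd.DataFrame(
            {"id": ["c1", "c3"], "sire": ["0", "0"], "dam": ["0", "0"],
             "birth_year": [1, 1]})))
        H = hmatrix(A22, G, blend_weight=0.0, tune=False)
        assert np.allclose(H.values, G.values)

    def test_blend_weight_one_restores_a22_block(self):
        A, G = self._toy()
        H = hmatrix(A, G, blend_weight=1.0, tune=False)
        idx = [A.ids.index("c1"), A.ids.index("c3")]
        assert np.allclose(H.values[np.ix_(idx, idx)], A.values[np.ix_(idx, idx)])

    def test_matches_longhand_block_formula(self):
        A, G = self._toy()
        w, tune = 0.05, False
        H = hmatrix(A, G, blend_weight=w, tune=tune)
        # independent long-hand evaluation of the single-step block identity
        gi = [A.ids.index(i) for i in G.ids]
        ni = [k for k in range(len(A.ids)) if A.ids[k] not in G.ids]
        Av = A.values
        A11, A12, A22 = Av[np.ix_(ni, ni)], Av[np.ix_(ni, gi)], Av[np.ix_(gi, gi)]
        Gb = (1 - w) * G.values + w * A22
        A22i = np.linalg.inv(A22)
        expected = np.zeros_like(Av)
        expected[np.ix_(ni, ni)] = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
        expected[np.ix_(ni, gi)] = A12 @ A22i @ Gb
        expected[np.ix_(gi, ni)] = expected[np.ix_(ni, gi)].T
        expected[np.ix_(gi, gi)] = Gb
        assert np.allclose(H.values, expected, atol=1e-10)

    def test_tuning_matches_block_means(self):
        A, G = self._toy()
        H = hmatrix(A, G, blend_weight=0.0, tune=True)
        gi = [A.ids.index(i) for i in G.ids]
        A22 = A.values[np.ix_(gi, gi)]
        H22 = H.values[np.ix_(gi, gi)]
        assert np.mean(np.diag(H22)) == pytest.approx(np.mean(np.diag(A22)))
        off = ~np.eye(2, dtype=bool)
        assert H22[off].mean() == pytest.approx(A22[off].mean())

    def test_unknown_genotyped_id_rejected(self):
        A, G = self._toy()
        bad = RelationshipMatrix("G", ["nope", "c1"], np.eye(2))
        with pytest.raises(ValueError, match="absent"):
            hmatrix(A, bad)
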