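"""Synthetic breeding program generator.

Emulates the statistical structure of a century-scale clonal breeding
program: founders with known allele frequencies, random mating up to a
change-point year, truncation selection on a focal trait afterwards, meiosis
with Haldane recombination on a genetic map, a dominant flowering locus, and
randomized-complete-block multi-year trial phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .genmap import GeneticMap
from .pedigree import Pedigree
from .relmat import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "TrialDesign",
    "HaplotypeSet",
    "simulate_founders",
    "simulate_breeding_program",
    "simulate_trials",
    "classify_pf",
    "pf_segregation",
    "gametes",
]


@dataclass(frozen=True)
class SimConfig:
    """Breeding-program simulation settings.

    Defaults emulate the study system: a pedigree spanning 1775-2015 with
    truncation selection beginning at a 1950 change point, and roughly 1.5k
    individuals at the default per-year cross counts.
    """

    n_founders: int = 60
    n_markers: int = 700
    founder_year: int = 1775
    end_year: int = 2015
    cp_year: int = 1950
    crosses_per_year: int = 2
    progeny_per_cross: int = 3
    selection_fraction: float = 0.5
    genotyped_fraction: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0
    pool_window: int = 10  # parents drawn from individuals born in the last N years
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    # exotic introgression: probability per cross of replacing one parent with
    # a fresh unrelated individual drawn at founder allele frequencies, until
    # the population closes in migration_end_year
    migration_rate: float = 0.05
    migration_end_year: int = 1990

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if not (self.founder_year < self.cp_year < self.end_year):
            raise ValueError("require founder_year < cp_year < end_year")
        for name in ("genotyped_fraction", "missing_rate", "migration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")


@dataclass
class TraitArchitecture:
    """Additive marker-effect architecture with one dominant flowering locus.

    ``marker_effects`` is (n_markers, n_traits); trait correlations are induced
    by drawing each marker's effect vector from a multivariate normal with the
    target correlation. The PF locus adds a dominant deviation to its
    designated trait on top of the additive background.
    """

    marker_effects: np.ndarray
    trait_names: list[str]
    trait_correlation: np.ndarray
    pf_locus: int
    pf_effect: float = 0.0
    pf_trait: int = 0
    intercepts: np.ndarray | None = None

    def __post_init__(self):
        self.marker_effects = np.atleast_2d(np.asarray(self.marker_effects, dtype=float))
        if self.marker_effects.ndim != 2:
            raise ValueError("marker_effects must be markers x traits")
        t = self.marker_effects.shape[1]
        C = np.asarray(self.trait_correlation, dtype=float)
        if C.shape != (t, t) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C)[0] < -1e-10:
            raise ValueError("trait_correlation must be positive semidefinite")
        if not 0 <= self.pf_locus < self.marker_effects.shape[0]:
            raise ValueError("pf_locus is not a valid marker index")
        if self.intercepts is None:
            self.intercepts = np.zeros(t)

    @property
    def n_traits(self) -> int:
        return self.marker_effects.shape[1]

    @classmethod
    def random(cls, gmap: GeneticMap, n_traits: int = 2, trait_corr: float | np.ndarray = 0.0,
               target_va: float = 1.0, pf_effect: float = 0.5, rng: np.random.Generator | None = None,
               seed: int = 0, allele_freq: np.ndarray | None = None,
               favorable_minor_frac: float = 0.7) -> "TraitArchitecture":
        """Draw a random architecture over the map's markers.

        Effects are scaled so the founder-population additive variance per
        trait is approximately ``target_va`` under the default founder allele
        frequency distribution (mean 2pq ~ 0.365 for U[0.05, 0.95]).

        When founder ``allele_freq`` is supplied, a fraction
        ``favorable_minor_frac`` of markers is oriented so the allele that
        raises the focal trait is the rarer founder allele. Directional
        selection then pushes initially rare favorable alleles toward
        intermediate frequencies, which raises per-cross segregation variance
        over the course of the program — the accumulation-of-favorable-alleles
        / transgressive-segregation structure seen in long-running breeding
        populations. Whole marker rows are flipped, preserving the trait
        correlation structure.
        """
        rng = rng if rng is not None else substream(seed, "architecture")
        m = gmap.n_markers
        if np.isscalar(trait_corr):
            C = np.full((n_traits, n_traits), float(trait_corr))
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(trait_corr, dtype=float)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n_traits))
        scale = np.sqrt(target_va / (m * 0.365))
        eff = rng.standard_normal((m, n_traits)) @ L.T * scale
        if allele_freq is not None:
            allele_freq = np.asarray(allele_freq, dtype=float)
            orient = rng.random(m) < favorable_minor_frac
            # make the "1" allele favorable for the focal trait where oriented
            flip = orient & (((allele_freq <= 0.5) & (eff[:, 0] < 0))
                             | ((allele_freq > 0.5) & (eff[:, 0] > 0)))
            eff[flip] *= -1.0
        pf_locus = int(rng.integers(m))
        return cls(eff, [f"trait{k + 1}" for k in range(n_traits)], C, pf_locus, pf_effect)


@dataclass(frozen=True)
class TrialDesign:
    """Replicated clonal trial layout and true variance components."""

    n_blocks: int = 4
    n_years: int = 2
    n_locations: int = 1
    var_gxy: float = 0.1
    var_gxl: float = 0.0
    var_gxyxl: float = 0.0
    var_e: float = 1.0
    var_block: float = 0.25
    var_year: float = 0.25
    var_location: float = 0.0
    intercept: float = 10.0

    def __post_init__(self):
        if min(self.n_blocks, self.n_years, self.n_locations) < 1:
            raise ValueError("blocks, years and locations must each be >= 1")
        for name in ("var_gxy", "var_gxl", "var_gxyxl", "var_e",
                     "var_block", "var_year", "var_location"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes: (n individuals, 2, n markers) in {0,1}."""

    ids: list[str]
    haplotypes: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n = len(self.ids)
        if self.haplotypes.shape != (n, 2, self.gmap.n_markers):
            raise ValueError("haplotype array must be (n, 2, n_markers)")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)

    def subset(self, ids: list[str]) -> "HaplotypeSet":
        pos = {v: k for k, v in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return HaplotypeSet(list(ids), self.haplotypes[idx], self.gmap)


def gametes(haps: np.ndarray, gmap: GeneticMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n`` recombinant gametes from one phased parent.

    One meiosis per gamete, no interference: crossovers occur independently in
    each marker interval with Haldane's recombination fraction, and the
    starting haplotype on each chromosome is chosen uniformly.
    """
    haps = np.asarray(haps)
    if haps.shape != (2, gmap.n_markers):
        raise ValueError("parent must be phased over the full marker panel")
    out = np.empty((n, gmap.n_markers), dtype=np.int8)
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        m = sl.stop - sl.start
        c = gmap.recomb_fractions(chrom)
        start = rng.integers(0, 2, size=n)
        if m > 1:
            cross = rng.random((n, m - 1)) < c
            switches = np.concatenate([np.zeros((n, 1), dtype=np.int64),
                                       np.cumsum(cross, axis=1)], axis=1)
            hap_idx = (start[:, None] + switches) % 2
        else:
            hap_idx = start[:, None]
        h0, h1 = haps[0, sl], haps[1, sl]
        out[:, sl] = np.where(hap_idx == 0, h0[None, :], h1[None, :])
    return out


def simulate_founders(config: SimConfig, gmap: GeneticMap,
                      rng: np.random.Generator | None = None,
                      allele_freq: np.ndarray | None = None) -> tuple[HaplotypeSet, Pedigree]:
    """Draw founder haplotypes site-wise independently (no founder LD).

    Allele frequencies are uniform on ``config.founder_freq_range`` unless
    given explicitly; realized frequencies differ by binomial sampling.
    """
    if gmap.n_markers == 0:
        raise ValueError("genetic map is empty")
    rng = rng if rng is not None else substream(config.seed, "founders")
    m = gmap.n_markers
    if allele_freq is None:
        lo, hi = config.founder_freq_range
        allele_freq = rng.uniform(lo, hi, size=m)
    haps = (rng.random((config.n_founders, 2, m)) < allele_freq).astype(np.int8)
    ids = [f"F{k:04d}" for k in range(config.n_founders)]
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ids, "sire": "0", "dam": "0",
        "birth_year": float(config.founder_year),
    }))
    return HaplotypeSet(ids, haps, gmap), ped


@dataclass
class BreedingProgram:
    """Output bundle of :func:`simulate_breeding_program`."""

    pedigree: Pedigree
    haplotypes: HaplotypeSet
    true_bv: pd.DataFrame         # index id; one column per trait (additive values)
    genetic_values: pd.DataFrame  # additive + PF dominance deviation
    architecture: TraitArchitecture
    config: SimConfig

    @property
    def birth_year(self) -> pd.Series:
        return pd.Series(self.pedigree.birth_year, index=self.pedigree.ids, name="birth_year")

    def genotype_matrix(self, rng: np.random.Generator | None = None) -> tuple[GenotypeMatrix, list[str]]:
        """Dosage matrix for a random genotyped subset with missing entries.

        Returns the matrix and the list of genotyped ids.
        """
        cfg = self.config
        rng = rng if rng is not None else substream(cfg.seed, "genotyping")
        ids = self.haplotypes.ids
        n_geno = int(round(cfg.genotyped_fraction * len(ids)))
        chosen = sorted(rng.choice(len(ids), size=n_geno, replace=False)) if n_geno else []
        geno_ids = [ids[k] for k in chosen]
        dos = self.haplotypes.dosages[chosen].astype(float)
        if cfg.missing_rate > 0 and dos.size:
            mask = rng.random(dos.shape) < cfg.missing_rate
            dos[mask] = np.nan
        return GenotypeMatrix(geno_ids, list(self.haplotypes.gmap.marker_id), dos), geno_ids


class DegenerateSelectionError(ValueError):
    pass


def simulate_breeding_program(config: SimConfig, gmap: GeneticMap, arch: TraitArchitecture,
                              founders: tuple[HaplotypeSet, Pedigree] | None = None) -> BreedingProgram:
    """Gene-drop a breeding program through time.

    Before ``cp_year`` parents are drawn at random from the recent candidate
    pool (no selection); from ``cp_year`` onward the pool is truncated to the
    top ``selection_fraction`` by true breeding value of the focal trait
    (trait 0). Every offspring's parents have strictly earlier birth years.
    """
    rng = substream(config.seed, "breeding")
    if founders is None:
        fhaps, fped = simulate_founders(config, gmap)
    else:
        fhaps, fped = founders
    m = gmap.n_markers
    if arch.marker_effects.shape[0] != m:
        raise ValueError("architecture and map disagree on marker count")

    ids: list[str] = list(fhaps.ids)
    sires: list[str] = ["0"] * len(ids)
    dams: list[str] = ["0"] * len(ids)
    years: list[int] = [config.founder_year] * len(ids)
    haps = [fhaps.haplotypes]
    tbv_rows = [fhaps.dosages @ arch.marker_effects]
    founder_freq = fhaps.dosages.mean(axis=0) / 2.0

    counter = 0
    n_migrants = 0
    for year in range(config.founder_year + 1, config.end_year + 1):
        yr = np.asarray(years)
        pool = np.flatnonzero((yr >= year - config.pool_window) & (yr < year))
        if pool.size < 2:
            pool = np.arange(len(ids))[yr < year][-max(2, 2 * config.crosses_per_year):]
        if year >= config.cp_year:
            focal = np.concatenate(tbv_rows)[pool, 0]
            k = max(int(np.ceil(config.selection_fraction * pool.size)), 0)
            if k < 2:
                raise DegenerateSelectionError(
                    f"selection_fraction {config.selection_fraction} leaves {k} parent(s) in {year}")
            pool = pool[np.argsort(focal)[::-1][:k]]
        all_haps = np.concatenate(haps)
        new_haps = []
        new_tbv = []
        for _ in range(config.crosses_per_year):
            p1, p2 = rng.choice(pool, size=2, replace=False)
            h1 = all_haps[p1]
            sire_id = ids[p1]
            if year <= config.migration_end_year and rng.random() < config.migration_rate:
                # exotic introgression: unrelated parent at founder frequencies
                h1 = (rng.random((2, m)) < founder_freq).astype(np.int8)
                sire_id = f"M{year}_{n_migrants:04d}"
                n_migrants += 1
                ids.append(sire_id)
                sires.append("0")
                dams.append("0")
                years.append(year - 1)
                new_haps.append(h1[None])
                new_tbv.append((h1.sum(axis=0) @ arch.marker_effects)[None])
            g1 = gametes(h1, gmap, config.progeny_per_cross, rng)
            g2 = gametes(all_haps[p2], gmap, config.progeny_per_cross, rng)
            kid_haps = np.stack([g1, g2], axis=1)
            new_haps.append(kid_haps)
            new_tbv.append(kid_haps.sum(axis=1) @ arch.marker_effects)
            for _k in range(config.progeny_per_cross):
                ids.append(f"I{year}_{counter:05d}")
                counter += 1
                sires.append(sire_id)
                dams.append(ids[p2])
                years.append(year)
        if new_haps:
            haps.append(np.concatenate(new_haps))
            tbv_rows.append(np.concatenate(new_tbv))

    all_haps = np.concatenate(haps)
    tbv = np.concatenate(tbv_rows)
    ped = Pedigree.from_frame(pd.DataFrame(
        {"id": ids, "sire": sires, "dam": dams, "birth_year": [float(v) for v in years]}))
    hs = HaplotypeSet(ids, all_haps, gmap)
    tbv_df = pd.DataFrame(tbv, index=ids, columns=arch.trait_names)
    gv = tbv_df.copy()
    carrier = hs.dosages[:, arch.pf_locus] >= 1
    gv.iloc[:, arch.pf_trait] += arch.pf_effect * carrier
    # pedigree sorting permutes rows; align data frames to pedigree order
    tbv_df = tbv_df.loc[ped.ids]
    gv = gv.loc[ped.ids]
    hs = hs.subset(ped.ids)
    return BreedingProgram(ped, hs, tbv_df, gv, arch, config)


def simulate_trials(ids: list[str], genetic_values: np.ndarray, design: TrialDesign,
                    seed: int = 0, trait: str = "trait1") -> pd.DataFrame:
    """Balanced randomized-complete-block trial phenotypes.

    observation = intercept + genetic value + block + year (+ location terms)
    + GxY (+ GxL, GxYxL) + residual, all effects from centered normals with
    the design's variances.
    """
    g = np.asarray(genetic_values, dtype=float)
    if len(ids) != g.size:
        raise ValueError("every phenotyped individual needs a genetic value")
    rng = substream(seed, "trials")
    d = design
    h, b, yv, lv = len(ids), d.n_blocks, d.n_years, d.n_locations
    blk = rng.normal(0, np.sqrt(d.var_block), size=b)
    yr = rng.normal(0, np.sqrt(d.var_year), size=yv)
    loc = rng.normal(0, np.sqrt(d.var_location), size=lv)
    gxy = rng.normal(0, np.sqrt(d.var_gxy), size=(h, yv))
    gxl = rng.normal(0, np.sqrt(d.var_gxl), size=(h, lv))
    gxyxl = rng.normal(0, np.sqrt(d.var_gxyxl), size=(h, yv, lv))
    eps = rng.normal(0, np.sqrt(d.var_e), size=(h, yv, lv, b))
    rows = []
    for iy in range(yv):
        for il in range(lv):
            for ib in range(b):
                vals = (d.intercept + g + yr[iy] + loc[il] + blk[ib]
                        + gxy[:, iy] + gxl[:, il] + gxyxl[:, iy, il] + eps[:, iy, il, ib])
                rows.append(pd.DataFrame({
                    "hybrid": ids, "block": f"B{ib + 1}", "year": f"Y{iy + 1}",
                    "location": f"L{il + 1}", "trait": trait, "value": vals,
                }))
    return pd.concat(rows, ignore_index=True)


def classify_pf(geno: GenotypeMatrix, pf_locus) -> pd.Series:
    """Classify individuals at the dominant flowering locus.

    Dosage >= 1 -> "carrier" (day-neutral, PF_); dosage 0 ->
    "non-carrier" (short-day, pfpf); missing dosage -> "unclassified".
    """
    if isinstance(pf_locus, str):
        j = geno.markers.index(pf_locus)
    else:
        j = int(pf_locus)
        if not 0 <= j < len(geno.markers):
            raise ValueError("pf_locus column not present in genotype matrix")
    d = geno.dosages[:, j]
    lab = np.where(np.isnan(d), "unclassified",
                   np.where(d >= 1, "carrier", "non-carrier"))
    return pd.Series(lab, index=geno.ids, name="pf_class")


def pf_segregation(parent1_dosage: float, parent2_dosage: float) -> dict:
    """Expected carrier : non-carrier segregation for a cross at a dominant
    locus. Het x het gives 3:1; het x homozygous-recessive gives 1:1."""
    for dv in (parent1_dosage, parent2_dosage):
        if np.isnan(dv):
            return {"carrier_fraction": float("nan"), "ratio": "unclassified"}
    q1 = (2.0 - parent1_dosage) / 2.0  # P(transmit recessive allele)
    q2 = (2.0 - parent2_dosage) / 2.0
    frac = 1.0 - q1 * q2
    from fractions import Fraction

    fr = Fraction(frac).limit_denominator(16)
    ratio = f"{fr.numerator}:{fr.denominator - fr.numerator}"
    return {"carrier_fraction": frac, "ratio": ratio}
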