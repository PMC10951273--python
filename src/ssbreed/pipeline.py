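"""End-to-end orchestration: simulate -> relationship matrices -> trial
analysis -> single-step BLUP -> change-point analysis -> cross prediction,
with every artifact written to disk and a manifest recording inputs, seeds,
constants and content hashes so identical configurations reproduce identical
bundles."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from ._rng import substream
from .crosspred import compare_eras, crosses_from_program, estimate_marker_effects
from .relmat import amatrix, gmatrix, hmatrix, qc_genotypes
from .simulate import SimConfig, TraitArchitecture, TrialDesign, simulate_breeding_program, simulate_trials
from .ssblup import SingleStepBLUP
from .timeseries import ChangePointModel, percent_change_summary, variance_trend
from .trial import TrialModel

log = logging.getLogger("ssbreed")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-program pipeline run."""

    seed: int = 0
    out_dir: str = "ssbreed_run"
    sim: SimConfig = field(default_factory=SimConfig)
    design: TrialDesign = field(default_factory=TrialDesign)
    n_traits: int = 2
    trait_corr: float = 0.4
    target_va: float = 1.0
    pf_effect: float = 0.5
    phenotyped_fraction: float = 0.35
    maf_min: float = 0.05
    miss_max: float = 0.10
    blend_weight: float = 0.05
    tune: bool = True
    guard: int = 5
    era_threshold: int = 1953
    n_crosses_per_era: int = 40
    n_progeny: int = 200

    def __post_init__(self):
        if not 0.0 < self.phenotyped_fraction <= 1.0:
            raise ValueError("phenotyped_fraction must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dictionary.

    Stage failures raise with a stage-tagged message; artifacts written before
    the failure are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    sim_cfg = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
    stage = "simulate"
    try:
        from .genmap import GeneticMap

        gmap = GeneticMap.uniform(sim_cfg.n_markers)
        lo, hi = sim_cfg.founder_freq_range
        founder_freq = substream(cfg.seed, "founder-freqs").uniform(lo, hi, gmap.n_markers)
        arch = TraitArchitecture.random(gmap, n_traits=cfg.n_traits, trait_corr=cfg.trait_corr,
                                        target_va=cfg.target_va, pf_effect=cfg.pf_effect,
                                        rng=substream(cfg.seed, "architecture"),
                                        allele_freq=founder_freq)
        from .simulate import simulate_founders

        founders = simulate_founders(sim_cfg, gmap, allele_freq=founder_freq)
        program = simulate_breeding_program(sim_cfg, gmap, arch, founders=founders)
        geno_raw, geno_ids = program.genotype_matrix()
        rng = substream(cfg.seed, "phenotyping")
        ids = program.pedigree.ids
        n_ph = max(2, int(round(cfg.phenotyped_fraction * len(ids))))
        ph_ids = sorted(str(ids[k]) for k in rng.choice(len(ids), size=n_ph, replace=False))
        pheno = simulate_trials(ph_ids, program.genetic_values.loc[ph_ids, "trait1"].to_numpy(),
                                cfg.design, seed=cfg.seed)
        sio.write_pedigree(program.pedigree, out / "pedigree.csv")
        sio.write_map(gmap, out / "map.tsv")
        sio.write_genotypes(geno_raw, out / "genotypes.tsv")
        sio.write_phenotypes(pheno, out / "phenotypes.csv")
        program.true_bv.to_csv(out / "true_bv.csv", index_label="id")

        stage = "qc"
        geno = qc_genotypes(geno_raw, cfg.maf_min, cfg.miss_max) if len(geno_ids) else geno_raw

        stage = "relmat"
        A = amatrix(program.pedigree)
        if len(geno_ids) >= 2:
            G = gmatrix(geno)
            H = hmatrix(A, G, blend_weight=cfg.blend_weight, tune=cfg.tune)
        else:  # ungenotyped program: single-step degenerates to pedigree BLUP
            from .relmat import RelationshipMatrix

            H = RelationshipMatrix("H", list(A.ids), A.values.copy(), meta={"source": "A"})
        sio.write_relmatrix(H, out / "hmatrix.tsv")

        stage = "trial"
        tri = TrialModel(pheno, trait="trait1").fit()
        tri.emm_table.to_csv(out / "emms.csv")
        pd.Series({
            "sigma2_g": tri.varcomps.sigma2_g, "sigma2_gxy": tri.varcomps.sigma2_gxy,
            "sigma2_e": tri.varcomps.sigma2_e, "H2_clone_mean": tri.heritability,
            "harmonic_mean_r": tri.varcomps.r,
        }).to_csv(out / "varcomps.csv", header=["value"])

        stage = "ssblup"
        birth = program.birth_year
        ss = SingleStepBLUP(tri.emm_table["emm"], H, birth_year=birth, genotyped=geno_ids).fit()
        sio.write_gebvs(ss.gebv_table, out / "gebvs.csv")

        stage = "changepoint"
        tbl = ss.gebv_table.dropna(subset=["birth_year"])
        cp = ChangePointModel(tbl["birth_year"].to_numpy(), tbl["gebv"].to_numpy(),
                              guard=cfg.guard).fit()
        pc = percent_change_summary(cp, sim_cfg.founder_year, sim_cfg.end_year)
        vt = variance_trend(cp)
        cp_json = {
            "cp_year": cp.cp_year, "pre_slope": cp.pre_slope, "post_slope": cp.post_slope,
            "sse": cp.sse, "percent_change": pc,
            "variance_trend": {"cp_year": vt.cp_year, "post_slope": vt.post_slope},
        }
        (out / "changepoint.json").write_text(json.dumps(cp_json, indent=2, default=float))

        stage = "crosspredict"
        train = tri.emm_table.loc[[i for i in tri.emm_table.index if i in set(geno_ids)], "emm"]
        era_summary = None
        if len(train) < 20:
            log.info("skipping cross prediction: only %d genotyped+phenotyped hybrids", len(train))
        if len(train) >= 20:
            from .crosspred import expand_to_panel

            eff = expand_to_panel(estimate_marker_effects(geno, train),
                                  list(gmap.marker_id))
            pairs = _era_pairs(program, cfg, rng=substream(cfg.seed, "era-pairs"))
            crosses = crosses_from_program(program.haplotypes, pairs, eff,
                                           n_progeny=cfg.n_progeny, seed=cfg.seed)
            era_summary = compare_eras(crosses, birth, cfg.era_threshold)
            era_summary.to_csv(out / "era_summary.csv")
            pd.DataFrame([{"parent1": c.parent1, "parent2": c.parent2, "mu_hat": c.mu_hat,
                           "va_hat": c.va_hat, "era": c.era} for c in crosses]
                         ).to_csv(out / "cross_predictions.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": _pkg_version("ssbreed"),
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "artifacts": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.suffix in (".csv", ".tsv", ".json") and p.name != "manifest.json"},
        "summary": {
            "n_individuals": len(program.pedigree),
            "n_genotyped": len(geno_ids),
            "n_phenotyped": len(ph_ids),
            "n_markers_post_qc": len(geno.markers) if len(geno_ids) else 0,
            "heritability_clone_mean": tri.heritability,
            "cp_year": cp.cp_year,
            "era_va": (era_summary["mean_va"].to_dict() if era_summary is not None else None),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest


def _era_pairs(program, cfg: PipelineConfig, rng) -> list[tuple[str, str]]:
    by = program.birth_year
    pre = [i for i in by.index if by[i] <= cfg.era_threshold]
    post = [i for i in by.index if by[i] > cfg.era_threshold]
    pairs = []
    for group in (pre, post):
        if len(group) < 2:
            continue
        for _ in range(cfg.n_crosses_per_era):
            a, b = rng.choice(len(group), size=2, replace=False)
            pairs.append((group[a], group[b]))
    return pairs
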