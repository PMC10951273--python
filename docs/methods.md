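# Methods

`ssbreed` implements the quantitative-genetics analysis chain used to
reconstruct long-run genetic change in a clonally propagated crop from
pedigree records, SNP genotypes and replicated trial phenotypes. This note
documents the models, the numerical choices, what the synthetic generator
does and does not emulate, and the known limitations.

## Relationship matrices

**Pedigree (A).** The numerator relationship matrix is built with the tabular
method on a topologically sorted pedigree: `a(i,i) = 1 + a(s,d)/2` (zero
contribution from unknown parents) and `a(i,j) = (a(j,s) + a(j,d))/2` for
previously processed `j`. Inbreeding is `F_i = a(i,i) − 1`. Cycles and
duplicate ids are rejected at load time; "0" and the empty string both code an
unknown parent. The dense implementation is intended for pedigrees up to a
few thousand individuals.

**Genomic (G).** VanRaden's first method: with dosages `M` (missing entries
mean-imputed at `2p_j`; the raw matrix is retained), `W = M − 2p` and
`G = WWᵀ / (2 Σ p_j(1 − p_j))`. Allele frequencies come from the genotyped
panel itself — no base-population frequencies are available — so relationships
are expressed relative to the current panel, which slightly shrinks
relationships of families that contribute to the frequency estimates (one
unit test quantifies this). QC removes markers with MAF < 0.05 or
missingness > 0.10 by default; both thresholds are exposed.

**Unified (H).** Single-step construction: (i) optionally tune G to the
genotyped pedigree block A22 by matching mean diagonal and mean off-diagonal
(`G* = α + βG`); (ii) blend `G_b = (1 − w)G* + wA22` with `w = 0.05` by
default; (iii) update the genotyped block and its pedigree cross-terms via
`A12 A22⁻¹ (G_b − A22) A22⁻¹ A21`. Tuning on and `w = 0.05` follow common
single-step practice; both constants are recorded in the matrix metadata.
With no genotyped individuals H reduces to A exactly; with everyone genotyped,
`w = 0` and tuning off, H equals G exactly.

## REML engine

Variance components are estimated by restricted maximum likelihood with
average-information updates, step halving, and an EM-REML fallback, so the
restricted log-likelihood is non-decreasing across accepted iterations
(convergence: relative change < 1e−8, cap 200 iterations; variances floored
at effectively zero and reported as 0 at the boundary). Two code paths share
this ascent:

* a **factor path** for crossed i.i.d. random factors (block, year,
  hybrid×year, …) that works in the q-dimensional random-effect space via the
  Woodbury identity — a 300-hybrid, 4-block, 2-year trial fits in seconds;
* a **dense path** for components with an arbitrary covariance kernel
  (the H-matrix genetic effect in single-step BLUP; the `WWᵀ` kernel behind
  ridge shrinkage), operating on the n×n marginal covariance of the
  phenotyped records.

The factor path was checked against `lme4` on crossed designs during
development (variance components agree to ~6 decimals) and is tested against
the closed-form balanced one-way ANOVA estimator.

## Trial analysis

The trial model is `value ~ hybrid + (block) + (year) + (hybrid×year) [+
location terms] + residual`. Fitting it twice — hybrid random for variance
components, hybrid fixed (cell-means coding) for estimated marginal means —
mirrors standard practice for clone trials. Because all non-hybrid terms are
centered random effects, the GLS hybrid estimates are least-squares means
over the factor margins; in balanced data they equal arithmetic means.
Contrast and EMM degrees of freedom use the Satterthwaite approximation with
the variance of the variance components taken from the inverse
average-information matrix. Genetic gain contrasts report
`ΔG = EMM₁ − EMM₂`, `ΔG% = ΔG/EMM₂ × 100`, a t statistic, and a Bonferroni
adjustment (default two tests per trait). Clone-mean broad-sense heritability
is `H² = σ²_G / (σ²_G + σ²_GY/y + σ²_GL/l + σ²_GYL/(ly) + σ²_E/(rly))` with
`r` the harmonic mean of realized replicate counts per hybrid per
year-location; location terms drop out of single-location designs. AUDPS
scores are the trapezoid area under the ratings plus the endpoint term
`(y₁ + yₙ)/2 · D/(n−1)`.

## Single-step BLUP

`y = 1μ + Zg + ε` with `g ~ N(0, H σ²_g)` over every individual in H and one
EMM record per phenotyped individual, unweighted by its standard error
(SE-weighting is deliberately not the default; EMMs from balanced clone
trials have near-homogeneous precision). REML on the phenotyped block of H
estimates `(σ²_g, σ²_ε)`; the mixed-model equations then give breeding values
for all individuals, prediction error variances from the inverse coefficient
matrix, and accuracy `1 − sqrt(PEV/σ²_g)` clipped to [0, 1] with a clip flag.
The dense solve refuses more than 5,000 individuals rather than approximate
silently. When the REML residual variance hits zero the MME shrinkage ratio
is floored at 1e−8 to keep the equations solvable for unphenotyped
individuals. Genetic correlations between traits are Pearson correlations of
per-trait GEBVs on the id intersection.

## Change-point and trend analysis

The change-point model regresses values (GEBVs, or their transformed
residuals) on year with two linear segments. The default is continuous at the
knot with free slopes; the change point is chosen by exhaustive least-squares
search over observed years with at least `guard = 5` observations and two
distinct years on each side, ties broken toward the earliest year. A
discontinuous variant (independent lines per segment) is available and is the
right tool when the underlying process shifts its mean abruptly: yearly
truncation selection moves the cohort mean by a full selection differential in
the first selected cohort, and on such step-plus-ramp signals the continuous
knot lands systematically early (about 5–15 years in our studies) while the
discontinuous variant is unbiased. Change-point uncertainty can be reported
by a seeded 200-resample percentile bootstrap. Dispersion trends re-run the
same search on `sqrt((y − ŷ)²) = |y − ŷ|`; a positive post-change-point slope
indicates growing additive variation. Production series use ordinary least
squares (`y = β₀ + β₁·year`) with percent change evaluated on the fitted
line between two years.

## Cross prediction

Marker effects are ridge-regression BLUP,
`β̂ = (WᵀW + λI)⁻¹Wᵀ(y − μ̂)` with training dosages centered at `2p` and
`λ = σ̂²_ε/σ̂²_β` from a REML fit of the equivalent genomic model (an explicit
λ can be supplied). Progeny are simulated as one recombinant gamete per
parent, with crossovers drawn independently per marker interval from
Haldane's mapping function `c = (1 − e^(−2d/100))/2` — no interference, no
selfing, no double reduction: the octoploid is treated diploid-wise on the
diploidized SNP panel. Per cross, the predicted mean and additive variance
(n−1 denominator) are computed over `n = 200` simulated progeny GEBVs. Eras
are assigned by parent birth year relative to 1953 (both parents at or before
the threshold → "pre"); crosses with missing birth years are excluded and
counted. In the synthetic pipeline phase is simulation truth; for real
unphased dosages a disclosed random-phase heuristic is applied and flagged —
it destroys within-parent linkage phase and is only acceptable when linkage
contributes little.

## Synthetic breeding program

The generator emulates the statistical structure the analysis chain assumes:

* **Founders** with allele frequencies uniform on [0.05, 0.95], haplotypes
  drawn site-wise independently (no founder LD; LD subsequently arises from
  the pedigree).
* **Trait architecture**: additive effects per marker drawn from a
  multivariate normal across traits (controllable genetic correlations),
  scaled to a target founder additive variance; one designated marker acts as
  a dominant flowering locus whose carriers gain a fixed deviation. When
  founder frequencies are supplied, 70–80% of markers are oriented so the
  allele that raises the focal trait is the rarer founder allele — initially
  rare favorable alleles whose accumulation under selection sustains and can
  increase segregation variance, the structure long-running breeding
  populations show.
* **Mating**: each year a fixed number of crosses among a pool of
  recently born individuals (window 10 years); before the change-point year
  parents are drawn at random, from it onward the pool is truncated to the
  top fraction (default 0.5) by true breeding value of the focal trait.
  Truncation on true rather than estimated values isolates the trend signal
  the change-point module must recover. A small migration stream (5% of
  crosses until 1990) introduces unrelated individuals at founder
  frequencies, emulating exotic introgression before the population closes.
* **Trials**: balanced randomized complete blocks with centered-normal
  block, year, hybrid×year and residual effects at configured variances.

All stochastic operations consume named substreams derived from one global
integer seed, so identical configurations are byte-identical on rerun.

What the generator does **not** emulate: founder linkage disequilibrium,
population structure and subpopulations, non-additive architectures beyond
the single dominant locus, genotyping error, unbalanced or spatially
structured field designs, and selection on phenotypes rather than true
values. Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to these departures.

## Study conditions used by the recovery harnesses

* **Variance components**: 300 hybrids, 4 blocks, 2 years, true components
  σ²_G = 8, σ²_G×Y = 2, σ²_E = 12; medians over 20 seeds are required within
  15% of truth.
* **Change-point recovery**: program spanning 1850–2015 with selection onset
  1950 (50 founders, 12 offspring/year, 300 markers); 35% of individuals
  across the whole timeline receive EMM-level phenotypes (genetic value +
  N(0, 0.35²) noise); pedigree single-step BLUP predicts everyone;
  the discontinuous change-point fit detects onset. Median absolute error
  over 20 seeds is required ≤ 5 years (observed ≈ 0–2).
* **Era comparison**: program with 16 parent slots/year and migration;
  ridge effects estimated from ≤400 hybrids born 1985+; 30 crosses per era at
  200 progeny. The post-era median predicted additive variance must exceed
  the pre-era median. Notably this holds with *estimated* effects but not
  with the true simulated effects: effect estimates concentrate on loci still
  segregating in the modern training material, which is exactly how the
  analysis sees real data.
* **Demo pipeline**: ~1,500 individuals spanning 1775–2015, 1,000 markers,
  half genotyped, 35% phenotyped; completes in well under a minute per run on
  one CPU and reruns byte-identically.

These problem sizes were chosen so each study carries clear statistical
signal while a full run of the suite stays interactive.

## Numerical details and degenerate inputs

* Variances are floored at `max(1e−8·var(y), 1e−12)` during ascent and
  snapped to zero at the boundary on output.
* H matrices failing a Cholesky factorization get one diagonal jitter of
  1e−8 × mean diagonal; anything worse raises with an eigenvalue report.
* A single marker per chromosome, monomorphic panels after QC, pedigrees with
  cycles or self-parents, unreplicated trials, zero-variance responses, and
  zero-baseline percent changes all raise explicit errors (or return flagged
  NaN where the surrounding table remains valid).
* Change-point ties in SSE are broken toward the earliest candidate year;
  the candidate grid is restricted by the guard so segments are always
  identifiable.

## Limitations

* The continuous change-point default underestimates onset on step-like
  signals (see above); use the discontinuous variant when an abrupt regime
  shift is plausible.
* Dense A/H algebra limits analyses to a few thousand individuals; large
  genealogies need sparse inverse methods that are out of scope here.
* Single-trait ss-BLUP only; genetic correlations are computed from GEBVs,
  which understates uncertainty relative to multi-trait REML.
* EMMs enter ss-BLUP unweighted; strongly unbalanced trials would justify
  SE weighting (available behind a flag at the model level via explicit
  variance components).
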