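# Methods

`flaxnue` re-implements, as a tested and reusable pipeline, the genetic
dissection of nitrogen-use-efficiency (NUE) seedling traits in a flax
diversity panel: trait derivation under two nitrogen treatments, multi-locus
mixed-model GWAS with allele-effect validation and LD-based QTL construction,
differential-expression colocalization within QTL windows, and GWAS-assisted
GBLUP genomic selection.  Every stage runs on a bundled synthetic-data
generator, so the whole analysis is exercisable without any downloads.

## The synthetic cohort

The generator emulates an association panel of ~123 mostly-inbred flax
accessions genotyped genome-wide and phenotyped at the seedling stage under
optimum nitrate (N+) and nitrogen deficiency (N−).

**Genotypes.** Each gamete carries a latent Gaussian field that is
first-order autoregressive along the chromosome, with correlation
`exp(-gap / ld_block_len_bp)` between adjacent markers, thresholded at the
subpopulation allele frequency.  Nearby markers therefore sit on shared
latent blocks and pairwise r² decays roughly as `exp(-2 d / L)`; the decay
length is the single parameter `ld_block_len_bp` (default 100 kb, the
genome-wide scale reported for flax panels).  We chose this latent-field
construction over copying along a founder-haplotype pool because i.i.d.
founders carry no internal LD: with a pool of K founders the copying process
produces only O(1/K) background association and no controllable decay length,
whereas the autoregressive field gives the decay profile directly.
Population structure follows the Balding–Nichols model (default two
subpopulations, Fst = 0.10); accessions are fully inbred by default
(dosages {0, 2}), with an `inbreeding` knob for residual heterozygosity.
Missing calls can be injected before the call-rate (> 0.95) and MAF
(> 0.05) filters, mirroring a real variant-filtering path; missing dosages
are mean-imputed per marker everywhere downstream (one rule, applied once).

**Phenotypes.** The genetic model carries six base traits — total root
length (TRL, cm), root volume (RV, cm³), root tip number (RT), shoot and
root dry weight (SDW, RDW, mg) and a latent NUE (mg dry weight per mg plant
N).  Replicate-level values are

    value = mu(trait, treatment)
            + sum_q beta_q * dosage_q        (planted QTLs, trait units/dosage)
            + polygenic * s                  (marker-derived, correlated across traits)
            + residual                       (correlated across traits within a plant)

The polygenic score is built from genome-wide markers (so GRM-based REML can
recover heritability), correlated across traits through the Cholesky factor
of a configurable genetic correlation matrix; replicate residuals share the
same correlation because the compartments of one plant are measured together.
The residual scale is set so the heritability of *accession means* over
`n_reps` replicates equals the planned h² — with h² = 1 the residual is
exactly zero, which makes the additive-coding contract (`effect +1` ⇒
dosage-2 vs dosage-0 difference of exactly 2) hold to machine precision.
Default means and SDs per treatment reproduce the magnitudes of the
published panel (TRL 469→407 cm, SDW 77→60 mg, NUE 25.6→28.3, etc.), so
size traits shrink under deficiency while NUE and root/shoot ratio rise.
Emitted raw traits are TRL, RV, RT, PDW (= SDW + RDW), SDW, RDW and the two
nitrogen contents, derived as `plantN = PDW / NUE` split ~75:25 between
shoot and root with small per-plant noise.  Modelling NUE as the latent
trait (rather than simulating N content independently) keeps the ratio
distribution realistic — independent denominators produced physiologically
impossible NUE outliers — and gives planted NUE QTLs a directly additive
effect.  Values are floored at 8% of the treatment mean (measurements are
positive).

The default planted architecture is oligogenic for NUE: 16 QTLs under both
treatments with per-QTL variance explained between ~1% and ~12% (~55% in
total), plus a handful of QTLs per root/biomass trait, partly shared to
create pleiotropic loci.

**Counts.** RNA-seq counts for a 2-genotype (high-NUE HN, low-NUE LN) ×
2-treatment × 4-replicate design are negative binomial with log-normal
per-gene baselines, uniform library-size factors and Var = μ + αμ²
(α default 0.1).  Planted fold changes multiply the N− samples of one
genotype by `2^log2FC`; the default plan places DEGs inside ±100 kb windows
of planted QTL positions (plus scattered background DEGs, ~80% on LN).

**What the generator does not emulate:** sequence-level reads, epistasis or
dominance, selection/demographic realism, genotype-by-environment structure
beyond the two fixed treatments, and skewed/over-dispersed phenotype
distributions beyond the rectified Gaussian.  Passing tests therefore show
correctness of the statistical machinery under its stated model, not
performance guarantees on real panels.

## Trait derivation

Best linear unbiased estimates per accession × treatment are replicate means
for the balanced completely randomized design; unbalanced designs fall back
to a two-factor (accession + replicate) least-squares fit averaged over
replicate levels — identical to cell means when balanced.  The 21-trait
table comprises six traits per treatment (TRL, RV, RT, PDW, SDW, R/S =
RDW/SDW), five stability indices `100 × trait_N− / trait_N+` (TRL, RV, RT,
PDW, SDW), NUE per treatment (`PDW / (shootN + rootN)`), the NUE index, and
the Fernandez stress tolerance index `NUE_STI = (Yp·Ys)/Ȳp²` with
Yp = NUE_N+ and Ys = NUE_N− (the canonical Fernandez 1992 form).  Effect
tests use fixed-effects two-way ANOVA (classical decomposition when
balanced, type-II via statsmodels otherwise); for balanced data this
coincides with the REML analysis it stands in for, and the
variance-component route is available through `mlgwas.fit_null_vc` for a
genotype-as-random analysis.  Note one published subtlety the code makes
explicit: the mean stability index in a trait table is the mean of
per-accession ratios, which differs from the ratio of treatment means
(86.8% vs 87.3% for TRL).

## LD and relatedness

r² is the squared Pearson correlation of unphased dosage vectors against the
next 50 markers (a marker window, the convention of the standard tooling);
for inbred lines this equals haplotype-frequency r², a documented limitation
for heterozygous panels.  Decay profiles fit the Hill & Weir (1988)
drift-recombination expectation of r² with the finite-sample term by
nonlinear least squares; `decay_distance(t)` inverts the fitted curve and is
right-censored (∞) when the curve never reaches the threshold within the
observed range.  A binned-median interpolation fallback (monotone-rectified)
is selectable and is used automatically on non-convergence, flagged in the
profile's `method` field.  Kinship: IBS sharing `mean(1 − |dᵢ − dⱼ|/2)` and
the VanRaden GRM `ZZᵀ / 2Σp(1−p)`.  For a fully inbred panel the GRM mean
diagonal is ≈ 2 (dosage variance 4p(1−p)), so heritability is reported as
`σ²_g·tr(G)/n / (σ²_g·tr(G)/n + σ²_e)` — without this scaling, h² on inbred
panels is biased down by a third.

## Multi-locus GWAS

One configurable two-stage algorithm replaces the six published multi-locus
models, which are used in practice as an ensemble whose union is
post-filtered:

1. **Null fit.** REML variance components of `y = Xβ + g + e`,
   `g ~ (0, σ²_g G)`, via spectral decomposition of G and bounded 1-D
   optimization of the variance ratio (grid seed + Brent refinement);
   deterministic.  A G proportional to the identity is flagged
   unidentifiable and reported as pure residual variance.
2. **Screen.** The null components are reused for every marker (P3D): a
   generalized-least-squares Wald test on the rotated, whitened data,
   vectorized over markers.  Monomorphic or covariate-collinear markers get
   missing p-values.
3. **Refinement.** Markers passing the screening threshold enter forward
   selection under the extended BIC,
   `n·log(RSS/n) + k·log n + 2γ·k·log m`; each selected marker is scored by
   single-term-deletion likelihood ratio, `LOD = LRT / (2 ln 10)`, p from
   χ²₁, effect = joint per-dosage coefficient, R² = 100·Var(xβ)/Var(y).
   Only LOD > 3.0 is retained — no Bonferroni correction, since the joint
   model already tests effects simultaneously.

Config variants (screening p ∈ {0.01, 0.005, 0.05} × EBIC γ ∈ {0.5, 1})
play the ensemble's role; per-variant QTN sets are unioned, keeping the
max-LOD record per marker × trait with all finding variants listed as
provenance.  Covariates default to intercept-only; principal components of G
can be supplied.  Effects are per-dosage additive coefficients.

## QTN validation and QTL construction

Each QTN is validated by a two-sided Mann–Whitney U test on the two
homozygous allele classes (exact when the smaller class has ≤ 8 members and
there are no ties; normal approximation with tie and continuity corrections
otherwise).  Heterozygotes are excluded under the inbred-panel assumption
(a flag pools them with the minor class instead); classes under 2 members
make a QTN untestable and it is removed with a reason code.  QTNs failing
p < 0.05 are removed as false positives.

Validated QTNs are merged per chromosome by single-linkage clustering with
link distance `0.75 ×` the chromosome-specific distance at which fitted r²
falls to 0.3 (genome-wide profile as fallback; both the factor and the r²
threshold are config keys, since the published "75% of the maximum LD decay"
admits an r² = 0.1 reading).  Clustering runs across traits; a block's trait
set defines pleiotropy (≥ 2 traits), its representative is the maximum-R²
member with ties broken by smallest position (deterministic IDs of the form
`Lu{chrom}_{position}`), and a block is "major" when the representative R²
strictly exceeds 10%.  Simple OLS of each trait on its representative-QTN
dosages yields R² and `adjR² = 1 − (1−R²)(n−1)/(n−p−1)`.  Favorable-allele
counts score, per accession and trait, the QTLs at which it is homozygous
for the class with the larger trait mean; heterozygous calls count as
non-favorable (logged), and decile groups use `round(0.1·n)` accessions
(12 of 123).

## Differential expression and colocalization

Size factors are DESeq-style median-of-ratios (cross-checked against the
pydeseq2 reference implementation in the tests).  Per gene, a negative
binomial GLM (log link, treatment indicator, log size factor offset) with a
method-of-moments dispersion pooled across groups (floor 1e-8) is fitted on
raw counts; the treatment coefficient is Wald-tested and
Benjamini–Hochberg-adjusted across tested genes.  No empirical-Bayes
dispersion shrinkage is applied — a deliberate simplification that is
adequate at four replicates for the |log2FC| ≥ 1 effect sizes the calls are
gated on (significance requires |log2FC| ≥ 1 AND FDR < 0.05).  The contrast
is N+ relative to the N− baseline within each genotype (positive log2FC =
up under optimum nitrate); the two genotypes are tested independently and
stacked.  Colocalization intersects gene intervals (1-based, closed) with
±100 kb windows anchored on each QTL's representative position, clipped at
the chromosome start, and reports per-QTL DEG lists plus a summary (QTLs
with ≥ 1 DEG, fraction of DEGs inside any window, mean ± SD DEGs per hit
QTL; the sum over QTLs can exceed the distinct count because a DEG may hit
two windows).

## GWAS-assisted genomic selection

Five marker sets predict NUE_STI: M1 a seeded random genome-wide sample;
M2 representatives of QTLs for any trait measured under N−; M3
representatives of QTLs for NUE_STI itself; M4 for traits significantly
positively correlated with NUE_STI (Pearson r > 0, p < 0.05 — the gate is a
config key, and the target belongs to its own group, so M3 ⊆ M4); M5 = M4
restricted to QTLs whose window harbors ≥ 1 DEG.  Markers are coded +1 for
the favorable homozygote and −1 for the alternative (0 for heterozygotes, an
extension); markers without an allele test fall back to alternate-allele
coding for M1 only — GBLUP is invariant to per-column sign flips, which the
tests assert.  GBLUP uses `G = WWᵀ/m`, REML variance components on each
training fold and `ĝ_test = G_ts (G_tt + δ̂I)⁻¹ (y_train − μ̂)` with the GLS
intercept; this REML formulation replaces the Bayesian engine of the
original workflow — deterministic, testable, and equivalent in expectation
for a single random effect (and exactly a ridge regression on marker effects
with penalty m·δ, asserted to 1e-6).  Cross-validation is unstratified
repeated 5-fold; accuracy is the Pearson correlation between predicted
genetic values and observed phenotypes in the held-out fold, aggregated as
the mean over all fold results.  Sets are compared by one-way ANOVA with
Tukey HSD and a greedy compact letter display.

## Numerical choices and degenerate inputs

* REML: eigenvalues clipped at 0; log-δ grid [−12, 12] then bounded Brent;
  boundary solutions collapse to σ²_g = 0.  Singular GBLUP training systems
  get a 1e-8 ridge jitter (logged).
* Forward selection refuses rank-deficient additions (collinear candidates
  dropped, logged); empty candidate sets are a valid empty result.
* Zero-variance traits are skipped with a log entry; zero-denominator
  accessions in trait derivation are excluded with a logged count; constant
  held-out folds yield no accuracy and are excluded from means with a count.
* All coordinates are 1-based inclusive (VCF/GFF3 convention).  Every
  stage's outputs carry the config hash; reruns under the same seed are
  byte-identical (asserted in the tests).

## Problem sizes

The bundled study conditions used by the tests and the acceptance script are
a desk-scale panel: 150 accessions, 3 chromosomes × 1000 simulated markers
(~2700 after filtering), 1500 genes, 20 CV repeats.  Calibration runs use
2000 null replicates for the rank tests and ANOVA, 2000 null genes for the
DE pipeline, and 10–20 seeds for recovery checks.  These sizes keep the full
suite around a minute on one CPU while leaving every statistical conclusion
(calibration bands, recovery power, marker-set ordering) stable across
seeds.

## Known limitations

Dosage-based r² understates haplotype LD for outbred heterozygous panels;
the NB dispersion is unshrunk; the two-stage GWAS is one algorithm with
variant configs, not a reimplementation of the six published multi-locus
models; BLUEs adjust for replicate only; prediction accuracies from
repeated partitions of one panel are optimistic relative to validation in an
independent population.
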