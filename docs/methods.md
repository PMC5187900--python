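# Methods

`pigbv` compares three routes to predicting breeding values for
intramuscular fat (IMF) and fatty-acid composition in a Duroc-style pig
population: whole-chip Bayesian genomic prediction (Bayes B), classical
pedigree BLUP, and marker-assisted BLUP built around two validated major
loci, the *SCD* promoter polymorphism and a *LEPR* missense variant.
Because the motivating field data (a proprietary nucleus population) are
not public, the package pairs the estimation machinery with a synthetic
population generator that reproduces the study *design* — cohort
structure, record counts, partial genotyping — so that every stage can
be verified against known truth at desk scale.

## Synthetic populations

**Pedigree.** Founders form a base population; each yearly cohort
consists of full-sib litters (one sire, one dam per litter; sires serve
several litters, creating half-sib families). The default scale is 80
founders and nine cohorts of 40 litters × 6 piglets (2,240 animals) —
a deliberate reduction of a six-figure field pedigree chosen so a full
replicate of the method comparison solves in seconds on one CPU while
retaining littermate and half-sib structure.

**Genotypes.** Markers are unlinked and biallelic. Founder alleles are
drawn Bernoulli(p) per locus; offspring receive one random allele from
each parent. The default chip has 120 markers with frequencies uniform
on (0.1, 0.9), plus SCD (p = 0.5) and LEPR (p = 0.3) appended and
flagged. Because loci are unlinked, the "rest of chip" carries no LD
with the major loci beyond pedigree co-segregation — this is what makes
the rest-of-chip contrast clean: any predictive ability it has comes
from family relationships captured by markers, not from tagging the
major genes.

**Traits.** Nine traits: IMF, SFA, MUFA, 18:1, PUFA, 18:1/18:0,
SFA/PUFA (the reported quality traits) plus body weight (BW) and
backfat thickness (BF), the routinely recorded performance traits.
For animal i and trait t,

    y_it = mu_t + cohort_c(i),t + batch_b(i),t + g_it + e_it
    g_it = sum_m (x_im - 2 p_m) beta_tm + u_it

* Major-locus effects are purely additive; `beta_tm` is scaled so that
  `2 p (1-p) beta^2 = q_t * sigma2_a,t`, making the variance fraction
  `q_t` exact in expectation. Defaults: SCD explains 27% of the additive
  variance of MUFA, 14.7% of 18:1, 25% of 18:1/18:0 and 10% of SFA
  (signs: raises the unsaturated traits, lowers SFA); LEPR adds 5–10%
  fractions on the same traits. IMF, PUFA and SFA/PUFA carry no
  major-locus variance, which is what lets the package reproduce the
  observation that the markers help some traits and not others.
* The polygenic values `u` follow the multivariate animal model:
  founders ~ N(0, Sigma_poly); non-founders are the parent average plus
  a Mendelian-sampling deviate with covariance
  (1/2 − 1/4 (F_s + F_d)) Sigma_poly, using pedigree inbreeding
  coefficients F. `genetic_corr` parameterises the *polygenic*
  correlation matrix; trait pairs sharing a major locus acquire
  additional genetic covariance from it. Of the four correlation
  anchors (IMF–BW 0.29, IMF–BF 0.44, 18:1/18:0–BW −0.07,
  18:1/18:0–BF 0.00) only 18:1/18:0 carries marker variance, so the
  realized totals differ from the anchors by at most √(1−0.30) dilution
  (≈ 0.01 on the −0.07 anchor) — inside every tolerance used.
* Heritability defaults: 0.55 for the quality traits (middle of the
  0.4–0.7 range reported for IMF/MUFA in this breed), 0.35 for BW/BF
  (an assumption; performance traits are typically moderately
  heritable). Trait means use the gluteus medius fatty-acid profile of
  the reference line (MUFA 49.51, SFA 39.84, 18:1 45.41, PUFA 10.61,
  18:1/18:0 3.31, % of total fatty acids); IMF defaults to 3.5%
  (mid-range for the breed) and SFA/PUFA to 3.76 (ratio of the SFA and
  PUFA means), since neither is tabulated directly. Phenotypic SDs are
  plausible per-trait values on each trait's own scale.
* The remaining polygenic correlations (compositional trade-offs among
  the fatty-acid traits, mild positive correlations of fat traits with
  BW/BF) were chosen once as a realistic, positive-semi-definite set and
  are part of the default architecture, all overridable.
* Residual correlations are unreported in the field data; the default is
  half the polygenic ones (a convex blend with the identity, hence PSD).
* Fixed effects: a cohort effect (SD = 0.25 phenotypic SD) and a
  slaughter-batch effect nested in cohort (two batches per cohort,
  SD = 0.15 phenotypic SD), drawn once per level.

**Field design.** Role tags reproduce the study layout: 65 chip-genotyped
training pigs from the two earliest cohorts; 70 chip-genotyped testing
pigs, one per litter, from the last two cohorts; 196 littermates of the
testing pigs with quality records; 936 low-relationship background
records from the first six cohorts; BW/BF recorded on all non-founders.
Testing-set quality phenotypes exist (evaluation needs them) but are
excluded from every training fit by construction. SCD and LEPR are
additionally genotyped on random subsets of record-bearing animals
(45%/40% by default), emulating partial single-marker assays; chip
genotyped animals always have their major-locus calls.

What the generator does **not** emulate: linkage and LD structure,
selection across cohorts, genotyping error, maternal and litter
environmental effects, non-additive gene action at the major loci.
Passing tests therefore demonstrate internal correctness and the
qualitative information-content ordering of the methods, not field-data
performance levels.

## Relationship machinery

A is built by the tabular method; inbreeding is its diagonal minus one;
A⁻¹ is assembled directly by Henderson's rules with Mendelian-sampling
variances adjusted for parental inbreeding. Unknown parents are treated
as unique unrelated non-inbred founders. An independent gene-dropping
estimator (10⁵ allele drops, a_ij = 2 × IBD probability) cross-checks
the tabular recursion in the test suite. The dense tabular pass is
O(n²) memory; fine to a few thousand animals, which is the intended
desk scale (founder-only populations skip it).

## BLUP

Henderson's mixed-model equations with fixed effects
intercept + cohort + batch. Identifiability: the first level of each
factor is zeroed; remaining dependent columns (batch is nested within
cohort) are detected by a deterministic greedy rank filter, zeroed, and
reported. The multitrait solver uses the G0⁻¹ ⊗ A⁻¹ structure; each
animal contributes the inverse of the residual covariance restricted to
its observed traits, so animals with BW/BF but no fatty-acid records
still inform quality-trait EBVs through the genetic correlations.
Systems are solved by sparse LU in SuperLU symmetric mode
(MMD on AᵀA + A ordering), which keeps fill-in low on the
animal-model structure. Variance components are inputs (from the
generator's architecture by default), not estimated — REML is out of
scope. For Method B the animal-effect covariance is the *total* genetic
covariance (an un-genotyped model absorbs the major loci into the
polygene); for Method C it is the polygenic remainder, since the marker
effects are fitted explicitly.

## Bayes B

The classic mixture prior: each SNP has zero effect with probability π,
otherwise an effect with its own variance drawn from a scaled inverse
chi-square(ν, S). The sampler proposes (δ_j, σ²_j) jointly from the
prior and accepts by Metropolis–Hastings on the marginal likelihood with
the effect integrated out; conditional on inclusion, the effect and its
variance are Gibbs-updated, as are the intercept and residual variance.
Defaults: π = 0.95 for chip fits and π = 0 for the two-marker subset;
chain 20,000, burn-in 5,000, thinning 10; ν = 4.2; S set so the prior
mean effect variance spreads an assumed h² = 0.5 of the phenotypic
variance over the expected number of included SNPs. Training phenotypes
are pre-adjusted for fixed effects (the intercept is re-fit in the
sampler), dosages are centered on training means and the same centering
is used at prediction. The kernel is numba-compiled with an internal
seeded RNG, so identical configurations give identical chains. With π=0,
ν large and the scale pinned, the posterior means converge to ridge
regression — a property the test suite checks against the closed form.

QC before fitting: call rate ≥ 0.95, MAF ≥ 0.05, monomorphic removal
(in that order, each marker counted once), then mean imputation. The
marker subsets of the comparison (whole chip / SCD+LEPR / rest of chip)
are each *re-fitted*, not masked from a full fit.

## Marker-assisted BLUP

Each major marker enters the MME as a fixed three-level genotype-class
factor (captures additive + dominance); the breeding value is the
centered class value plus the polygenic EBV, an exact decomposition.
Centering uses class frequencies of the genotyped animals among the
training records. Ungenotyped animals carry the class-frequency design
row — mean imputation that contributes no class-contrast information —
and receive the expected (zero after centering) genotypic value. A
marker with only two observed classes collapses to additive dosage
regression; a monomorphic or uncalled marker is excluded, which makes
Method C reduce exactly to Method B. Partial genotyping attenuates the
fitted class effects somewhat (relatives' records enter through the
polygenic term); with full genotyping the class effects recover the
simulated values, as the tests show.

## Evaluation

Predictive quality is the Pearson correlation between predicted breeding
values and adjusted phenotypes over the 70 testing animals. "Adjusted"
means raw minus the fixed-effect solutions of a base fit — a single-trait
animal model on the full training record set. Because the testing
cohorts have no quality-trait training records, their cohort/batch
levels are unestimable from the base fit; such records are centered
within the level among testing animals instead of being dropped (which
would empty the evaluation set). Correlations divide by √h² to give
accuracies. Replicates aggregate by the arithmetic mean of r (Fisher-z
averaging was considered and rejected to stay closest to how such
tables are conventionally reported; the option is trivial to add).

## Numerical and design choices

* All randomness flows from `numpy` SeedSequence spawning; one seed
  reproduces a bundle bit-for-bit. Seeds derived for the numba kernel
  stay below 2³¹.
* MME solves target 1e-8 agreement with dense GLS oracles; the
  acceptance suite verifies this on every run.
* Sparse systems are symmetric positive definite by construction
  (positive-definite G0/R0 are validated on input; non-PD input is
  rejected).
* Ties in marker ranking break by marker id (stable sort).
* The `evaluate_bundle` replicate (2,240 animals, 122 markers, eleven
  method rows × seven traits) runs in ~12 s on one CPU; the 20-replicate
  comparison used by the tests and the acceptance script was sized to
  that budget.

## Known limitations

* O(n²) dense pass for A and inbreeding limits pedigrees to a few
  thousand animals; a Meuwissen–Luo style O(n·depth) inbreeding
  algorithm would lift this.
* Variance components are assumed known; with misspecified components
  the BLUP rows change quantitatively (the qualitative ordering is
  robust in the replicate tests).
* The Bayes B prior scale ties to an assumed h²; for very small training
  sets (n = 65) posterior summaries are prior-sensitive, which mirrors
  the instability the small field training set showed.
* Mean imputation for ungenotyped animals in Method C is unbiased but
  not information-optimal; gene-content imputation from the pedigree is
  a natural extension and explicitly out of scope.
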