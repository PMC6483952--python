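# Methods

This note documents the models and procedures implemented in `haploblup`,
the assumptions behind them, and the design choices made where several
reasonable options existed.

## Pipeline overview

The analysis proceeds in three stages: (1) SNP selection — a call-rate
filter and a minor-allele-frequency filter, then assembly of blocks of
linked markers from pairwise r²; (2) haplotype construction — EM phasing of
each block and selection of high-frequency haplotypes; (3) prediction — a
random-haplotype-effect linear model fitted to deregressed proofs of the
oldest bulls and validated on the youngest.

## Synthetic populations

Real bull genotypes and national-evaluation proofs are proprietary, so the
package generates populations with the structure the analysis assumes.

* **Genome.** `n_blocks` independent LD blocks (default 50), each 2–8 SNPs,
  each segregating `alleles_per_block` distinct binary haplotype alleles
  (default 4) whose gametic frequencies follow a symmetric Dirichlet with
  concentration 1 — yielding both common and rare haplotypes.  Every SNP is
  made to segregate within its block's allele pool.  Blocks are assigned
  round-robin to the 29 bovine autosomes plus X and laid out with 5 kb SNP
  spacing and 1 Mb gaps.  Blocks are simulated without between-block LD:
  the prediction model treats haplotype effects as independent, and
  within-block LD is implicit in the finite allele set.  The Dirichlet
  design is a stand-in for an unobserved allele-frequency spectrum, not a
  claim about any real population.
* **Diplotypes** are drawn per animal under Hardy–Weinberg equilibrium,
  stored ordered but compared unordered (phase of origin is unobservable).
* **Effects and TBV.** Per-copy haplotype effects are drawn from the
  equal-partition prior N(0, σ²_g/H), centred at the frequency-weighted
  mean of their block (breeding values are deviations from the population
  mean; the mean belongs to μ), and rescaled once so that the analytic
  additive variance given the drawn frequencies, Σ_b 2·Var_f(h), equals
  σ²_g exactly.  Without this calibration the realised genetic variance
  would be an uncontrolled fraction of σ²_g that depends on the drawn
  frequency spectrum, and downstream variance ratios would be
  misspecified by construction.  Effects are simulated under the equal
  partition, so the size-weighted variants (3/4) are evaluated under prior
  misspecification — mirroring how the variants compete on one dataset.
* **Proofs.** EBV_i = TBV_i + e_i with e_i ~ N(0, σ²_g(1−REL_i)/REL_i), the
  standard prediction-error-variance relation, and REL_i uniform on
  (0.60, 0.98) — reliabilities typical of progeny-tested sires.  Birth
  years are uniform on 1987–2003.  Genotype calls are set missing
  independently at 2% by default.

What the generator does *not* emulate: pedigree structure and genetic
trend across birth years, selection, LD decay with distance,
ascertainment bias of SNP chips, and heritability-dependent reliabilities.
Consequently, passing tests demonstrate correctness of the machinery and
reproduction of the qualitative phenomena, not calibrated accuracy on real
cattle data.

## SNP quality control

Call rate is the fraction of non-missing calls per SNP; SNPs with more than
`max_missing` (default 10%) missing are removed first, then SNPs with
MAF ≤ `min_maf` (default 1%; strict inequality, computed over non-missing
calls only).  The two filters are conjunctive, so the kept set is
order-independent; the report counts both stages.  The X chromosome passes
through QC like an autosome; heterogametic dosage is not modelled.

## Pairwise r² and blocks

r² = D²/(p_A p_a p_B p_b) is computed from two-locus haplotype frequencies
estimated by EM from unphased genotypes: all genotype pairs except the
double heterozygote resolve into known gametes; double heterozygotes are
split between cis and trans in proportion to the current frequency
estimates (the estimator PLINK reports).  Monomorphic pairs return 0;
pairs observed in fewer than two animals are undefined.

Blocks are connected components of the graph joining same-chromosome SNP
pairs with r² ≥ threshold (default 0.8) within a sliding window (default
50 SNPs; set it to the chromosome's SNP count to cover all pairs).
Single-linkage components are simple, deterministic, and match PLINK-era
clumping practice; they may be non-contiguous in map order, so a
`contiguous` mode (chaining adjacent pairs only) is provided for
sensitivity analysis.  Components of one SNP form no block.

## EM phasing and haplotype selection

Each block is phased by multi-locus EM: the E-step weights each animal's
compatible unordered haplotype pairs by their Hardy–Weinberg diplotype
probabilities f_j f_k (2 f_j f_k for j≠k); the M-step re-estimates
frequencies from expected gamete counts.  Initialisation is uniform over
observation-compatible haplotypes, making the run deterministic; the
log-likelihood is asserted non-decreasing each iteration and iteration
stops when its change falls below 1e-8 (default) or at 1000 iterations.
Missing calls are marginalised by enumerating compatible alleles; an
all-missing animal receives the population prior as posterior.  Alleles
below 1e-9 frequency are pruned after convergence.  Blocks whose
enumeration exceeds a cap (default 2²⁰ candidates) are reported and
skipped.  EM replaces coalescent-informed Bayesian phasing; for the short,
high-LD blocks used here the two approaches agree closely, and EM is
deterministic at desk scale — a documented fidelity trade-off.

Haplotypes are selected when their frequency strictly exceeds 25%.  Both
frequency notions are computed: the gametic (population) frequency and the
carrier frequency (fraction of individuals whose posterior probability of
carrying ≥ 1 copy exceeds 0.5).  The selector's default basis is carrier
frequency — "appears in at least a quarter of individuals" — with a config
switch to the population basis; the two differ (under HW, carrier ≈ 2p−p²)
and the choice is genuinely ambiguous, so neither is asserted as canonical.

## Deregression

Full mixed-model-equation deregression of national proofs requires the
evaluation's own system matrices.  The package uses a transparent
reliability-scaled deviation rule, drp_i = m + (ebv_i − m)/REL_i with m the
mean EBV, attaching weights w_i = REL_i/(1−REL_i); it expands deviations by
exactly the factor reliability shrank them and is the identity at REL = 1.
The rule is pluggable, deregression is global (not within birth year), and
the model fit is unweighted by default (homogeneous residual variance) with
a switch to use the DRP weights — both conventions are configurable because
neither is uniquely standard.

## The prediction model

σ²_e defaults to σ²_g(1−h²)/h², the residual variance implied by the
heritability on the phenotypic scale, with an explicit override.  The
"probability" Z is the transmission probability (expected dosage/2,
entries in [0,1]); an expected-dosage (0–2) mode exists for sensitivity.
The "indicator" Z uses the most probable diplotype (ties broken by listed
order, which is deterministic).  The size-weighted partition normalises by
the total SNP count over selected haplotypes, Σ_k L_k, so that both schemes
sum exactly to σ²_g; a per-block-allele-count reading of the normaliser
would not conserve σ²_g across blocks of unequal allele numbers, which is
why the total-SNP reading is the default.  μ is fitted as a fixed effect
inside the MME (standard BLUP practice).  The MME are formed densely —
after the 25% frequency filter the haplotype count is at most a few
thousand — and solved by a symmetric positive-definite factorisation;
numerically singular systems (possible only with vanishing ridge terms)
fall back to the minimum-norm least-squares solution with a warning naming
zero columns.  DGV excludes μ̂, which leaves correlations unchanged and
affects only the regression intercept; the intercept is reported but is
not a headline statistic.

## Validation

The split is generational: animals ordered by birth year (ties by id), the
oldest ⌊n·0.875⌋ train, the rest validate — 1064/152 at n = 1216.  Train
statistics are in-sample refits and labelled as such.  The comparison
target is EBV by default; TBV is available in simulation as the cleaner
accuracy measure.

## Replicate experiments

`haploblup.experiments` fixes the desk-scale study conditions once: 600
animals, 40 blocks of 2–6 SNPs with 3 alleles, σ²_g = 1, reliabilities
0.60–0.98, 2% missingness, ten seeded replicates.  Three findings are
scored by majority vote: (a) haplotype variances at 1% of their partition
(over-shrinkage) push the validation EBV-on-DGV slope above 1; (b)
in-sample correlation exceeds validation correlation; (c) a h² = 0.30
model setting validates better than h² = 0.02 on the *same* simulated
data — a matched-pairs contrast in which only the model's residual
variance changes, the single channel through which heritability acts when
reliabilities are drawn independently of h².

## Numerical conventions

Tolerances: EM convergence 1e-8 (two-locus r²: 1e-12), frequency pruning
1e-9, posterior normalisation asserted to 1e-10.  Ties: selection orders by
descending frequency then lexicographic allele string; modal diplotypes
take the first-listed maximum; the generational split breaks year ties by
animal id.  Degenerate inputs: monomorphic loci give r² = 0; all-missing
SNPs fail QC; constant vectors give undefined (NaN) correlation/slope; an
empty selected-haplotype set aborts the pipeline with an explicit error.
All pipeline randomness derives from one seed through named substreams, so
artifacts are byte-identical across re-runs.
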