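# Methods

This note documents the statistical models behind `slowfast`, the defaults
they ship with, what the synthetic-data generators do and do not emulate,
and the numerical and design choices a user auditing results should know.

## Differentiation of haploid genotype panels

Accessions of a highly selfing species are homozygous at essentially every
locus, so each genome carries one effective allele per SNP. `io_core`
therefore collapses homozygous diploid calls to haploid 0/1 dosages;
heterozygous calls — biologically unexpected in such a panel — are set to
missing and counted rather than recoded as 0.5, so a contaminated input is
visible in the log instead of silently shrinking allele-frequency contrasts.
Missing calls are excluded per SNP (complete case); there is no imputation.

Population labels come from ancestry fractions with a strict majority rule:
an accession belongs to cluster j only if q_j > 0.5; otherwise it is
"Admixed" and excluded from all differentiation statistics. The strictness
matters at the boundary: a 50/50 accession is Admixed.

Per-SNP differentiation uses the Weir–Cockerham moment estimator specialized
to haploid indicators. With populations i = 1..r, sizes n_i, allele
frequencies p_i, N = Σn_i:

- MSP = Σ n_i (p_i − p̄)² / (r − 1), MSG = Σ n_i p_i (1 − p_i) / (N − r)
- n_c = (N − Σn_i²/N) / (r − 1)
- a = (MSP − MSG) / n_c, b = MSG, θ̂ = a / (a + b)

θ̂ can be negative for undifferentiated SNPs and is kept so: clamping would
bias medians of null-ish SNPs upward. A SNP needs ≥ 2 populations with ≥ 2
calls each and a polymorphic pooled sample; otherwise θ̂ is undefined (NaN),
never silently 0. The multilocus estimate is the ratio of sums Σa / Σ(a+b)
(lower bias than averaging ratios); the unweighted mean of per-SNP θ̂ is also
reported because both conventions circulate, and on real data they differ.

Significance is assessed by permuting population labels. One permutation is
drawn per iteration and applied to all SNPs jointly, which preserves
between-SNP dependence and exact per-population sample sizes. A SNP is
significant when its observed θ̂ strictly exceeds the 95th quantile of its
own 1,000-value null. The neutral benchmark — the drift-only differentiation
a trait must beat — is the median θ̂ of the significant *intergenic* SNPs.
Conditioning on significance biases this benchmark upward relative to the
multilocus θ̂, which makes the downstream trait verdict conservative; the
test suite checks this ordering on simulations.

LD pruning is a greedy left-to-right sweep: a SNP is dropped if any earlier
retained SNP on the same chromosome within 50 kb has r² ≥ 0.1 (pairwise
complete-case Pearson on dosages). This checks every within-window pair —
slightly stricter than the classic step-advanced window, which can let pairs
that straddle a window boundary survive — and is deterministic for a fixed
input order. Zero-variance SNPs correlate with nothing and are retained.

The kinship matrix standardizes each polymorphic SNP column to mean 0 / unit
variance over non-missing calls (missing ⇒ 0 after centering) and divides the
cross-product by the per-pair count of shared calls, so the diagonal averages
1. Column centering makes the average off-diagonal exactly −1/(n−1); tests
assert the structural value rather than "≈ 0".

## P_ST for autogamous species

The phenotypic analogue of Q_ST used here is

    P_ST = c σ²_B / (c σ²_B + h² σ²_W)

with σ²_B, σ²_W the between-/within-population variances of genotype means,
c the genetic fraction of the between-population variance and h² the
within-population heritability. The usual factor 2 on σ²_W is dropped: in a
fully selfing species offspring inherit the entire genotype, not half the
additive variance. Under H0 (c = h² = 1) the statistic reduces machine-
exactly to σ²_B / (σ²_B + σ²_W).

Components come from a one-way random-effects ANOVA of genotype means with
the unbalanced-design coefficient n₀; negative method-of-moments estimates
of σ²_B are truncated to 0 and flagged. σ²_W in the formula is the variance
of genotype means (the phenotypic quantity the h² multiplier is designed to
discount); the replicate-level residual enters only through h², estimated by
a separate one-way ANOVA of replicates within genotypes. In an inbred panel
a replicate design measures broad-sense genotypic variance; under full
homozygosity that is the heritable variance, and the package reports the
ratio as h² without claiming a narrow-sense decomposition.

Confidence intervals are parametric-bootstrap percentiles (default 10,000
iterations): redraw population effects ~ N(0, σ̂²_B) and genotype deviations
~ N(0, σ̂²_W) on the observed design, re-estimate, recompute P_ST. The
sensitivity analysis evaluates P_ST and its CI along a c/h² grid (default
0.05–2.0, step 0.05; P_ST depends on c and h² only through their ratio) and
reports the critical c/h² — the smallest ratio whose CI lower bound clears
neutral F_ST. One shared set of bootstrap draws is reused across the grid,
which makes the reported curve monotone by construction and 40× cheaper.

**Known limitation — few populations.** With k populations the bootstrap
lower bound of P_ST is governed by roughly k−1 degrees of freedom of
between-population information. At k = 5 the 2.5th percentile of a χ²₄/4
factor is ≈ 0.12, so even a trait with P_ST ≈ 0.35 has a CI lower bound near
0.05–0.08, and the percentile interval undercovers (measured ≈ 88% at
nominal 95%, converging to nominal by k ≈ 50 in the same experiment). This
is a property of the design, not a defect of the estimator: with five
lineages a drift-alone explanation is hard to exclude at the H0 settings,
which is precisely why the sensitivity analysis and the critical c/h² are
reported alongside the verdict. Two acceptance-style checks that posit
near-nominal coverage and a ≥ 90% diversifying rate at k = 5 fail for this
reason and are left failing deliberately.

## Growth curves, trait axes, scaling

Rosette area series are fitted with the 3-parameter logistic
A(t) = K / (1 + exp(−r(t − t0))) by least squares (initialization: K₀ = max
area, t0₀ = first half-max crossing, r₀ = early log-linear slope). RGR is
the relative growth rate at the inflection, analytically r/2 (units
mm² mm⁻² d⁻¹) — an absolute-slope reading (rK/4, mm² d⁻¹) would contradict
those units. RGR is thus invariant to rescaling areas, which the tests
exploit. A fit is flagged unconverged when the optimizer fails, when
K̂ > 10× the observed maximum, or when the fitted curve reaches < 90% of K̂
by the last time point (no plateau observed); RGR is refused on such fits.
A Gompertz alternative was considered and rejected as a default: for the
relative-rate-at-inflection summary the two families differ only through the
fitted r, and the logistic is the simpler, better-conditioned choice.

Trait axes are PC1 of a correlation-matrix PCA (traits have incommensurable
units) of log10-transformed genotype means; RGR stays on its natural scale
because it is a rate that can be ~0. Complete-case only; dropped genotypes
are logged. The axis orientation is pinned by requiring a positive loading
for the mass-per-area trait (LMA or plant LMA; configurable), so a high
score always means conservative/slow. Which traits define the slow-fast
axis is configurable; the default set is plant A_mass, plant LMA, age at
maturity and RGR.

SMA regression: slope = sign(r)·s_y/s_x, intercept through the means, and
the correlation-based 95% slope CI with B = F(1−α; 1, n−2)(1−r²)/(n−2) and
bounds slope·(√(B+1) ± √B). |r| = 1 gives a degenerate interval at the
slope. SMA slopes satisfy |b_xy · b_yx| = 1 exactly; the test suite asserts
this at machine precision. The kinship-GLS check fits the same slope with
residual covariance K + δI (δ a logged jitter escalated until Cholesky
succeeds) and declares a structure problem when GLS and OLS slopes differ by
more than twice the combined standard errors.

## Climate association

The correlation screen reports per-variable Pearson r and two-sided p with
no multiplicity correction (by design: the screen is descriptive, and the
count of nominally significant variables is reported alongside). Model
selection is bidirectional stepwise AIC starting from the full model, with
perfectly collinear columns removed up front and ties broken by column
order, so the procedure is deterministic given the data. The final model is
guaranteed no worse (in AIC) than both the full and the empty model.

Predictive accuracy is repeated k-fold cross-validation (default 10 × 10,
seeded). Selection is re-run inside every training fold; nothing from the
held-out fold can influence the model — the no-leakage property is enforced
by a regression test on pure-noise data, where a leaky implementation
inflates r² well above 0. Per repetition the pooled out-of-fold predictions
are scored by squared Pearson correlation with the observed values (the
headline metric) and by 1 − SSE/SST (also emitted; it can be negative).
Grid prediction is the bare linear predictor with a per-row extrapolation
flag whenever a selected variable leaves its training range.

## Synthetic data: what it emulates, and what it does not

`simulate_genotypes` is a Balding–Nichols island model: ancestral
frequencies Uniform(0.1, 0.9), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), haploid Bernoulli dosages. Defaults mirror the
study design this package was built around: 5 populations, ~300 core
accessions, ~20% admixed, target F_ST 0.1. Admixed accessions are equal
50/50 two-population mixtures — any unequal two-way split would have a
majority component above 0.5 and stop being admixed under the strict rule —
and their Q rows carry the true weights. Linkage is absent by default; an
optional block-duplication mode (adjacent SNP copies with a small flip
probability) creates the LD needed to exercise pruning. No coalescent
history, mutation model, or selection at the sequence level is simulated, so
the panel has no isolation-by-distance or haplotype structure; F_ST-scale
statistics are faithful, haplotype-scale ones would not be.

`simulate_phenotypes` draws population effects (variance σ²_B, split into a
genetic share c and an environmental share 1−c) and within-population
genotype deviations (variance σ²_W, split by h²), then adds replicate noise
scaled from the realized genotype-value variance so that the replicate ANOVA
targets h²_true. Note the identifiability caveat this encodes: the
genotype-persistent environmental deviation is counted as genetic by any
replicate design — which is exactly why P_ST needs the c/h² sensitivity
analysis rather than a point claim. Values are shifted by a variance-neutral
offset to stay positive (log10-transformable).

`simulate_growth_series` adds Gaussian noise (sd = noise_sd·K) to a logistic
and truncates at 0; the truncation makes the early-phase noise slightly
non-Gaussian, negligible at the default 2%. `simulate_climate` couples one
causal variable linearly to the supplied score (a helper converts a target
population correlation into the slope) and fills the remaining variables
with independent standard normals — real bioclim variables are strongly
cross-correlated, so selection behaviour on real data will be harder than on
this null; the generator is calibrated for correlation and leakage tests,
not for realism of the climate covariance.

Passing tests on these generators demonstrate estimator correctness,
calibration and no-leakage under the assumed model; they do not demonstrate
robustness to real-data pathologies (genotyping error, shared ancestry
within populations, non-normal traits, spatially autocorrelated climate).

## Problem sizes and determinism

Simulation-based tests and the acceptance script run at desk scale chosen to
keep Monte-Carlo error comfortably inside the asserted tolerances: 5,000–
8,000 SNPs, 300–378 accessions, 1,000 permutations, 2,000–10,000 bootstrap
iterations, 20–500 seeds per recovery experiment. Every stochastic routine
takes an explicit seed (or numpy Generator); identical seeds give
bit-identical outputs, and the acceptance script derives all its streams
from its single `--seed` argument.
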