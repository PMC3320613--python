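# Methods

This note documents the statistical models implemented in `fecmap`, the
assumptions behind them, the synthetic-data generator that drives the test
suite, and the numerical and design choices that were genuinely open.

## The fecundity curve

Daily egg counts of individual females are treated as a function-valued
trait.  The mean trajectory rises to a single interior peak and declines —
a "triangular" fecundity trajectory in the classical sense — and is fitted
in a form linear in its parameters after a log transform:

    y = ln(eggs + 1) = b0 + b1·ln(age) + b2·age + Z u + ε,

with `b1 > 0 > b2`.  On the back-transformed scale the mean curve is
`exp(b0)·age^b1·exp(b2·age) − 1`, which peaks at `age = −b1/b2`.  The `+1`
offset keeps zero-egg days finite; its inverse `exp(·) − 1` is the
back-transform.  This family was adopted because it has exactly three
parameters per stratum, is linear in them (so least-squares and
mixed-model machinery apply directly), and has the right qualitative
shape; alternative curve families are deliberately out of scope, and all
downstream statistics (totals, contrasts, scans) are defined relative to
this form.

`Z u` collects random intercepts: by default a vial effect, plus a fly
effect nested in vial when vials hold several flies.  With a random
structure declared, variance components are estimated by REML (ML where a
likelihood-ratio test on fixed effects follows) through `statsmodels`
MixedLM; with none, the fit is per-stratum ordinary least squares.  On
balanced designs the OLS fixed-effect estimates coincide with the
mixed-model ones, which is why the fast OLS path is used inside bootstrap
loops and replicated simulation studies.

**Total fecundity** for a stratum is the integral of the back-transformed
fitted mean over days 1–14, with the integrand floored at zero.
Quadrature is composite Simpson on a fixed 1301-point grid; because the
floor introduces kinks where the transformed curve crosses zero (the
curve has at most one interior extremum, hence at most two roots), the
roots are located by bisection and the rule applied piecewise, giving
~1e-9 relative accuracy deterministically.

**Confidence intervals** are nonparametric bootstrap percentiles
(default 5000 replicates) with the *fly* as resampling unit: all daily
records of a fly move together, and flies are resampled with replacement
within stratum.  Refits inside the bootstrap use per-fly sufficient
statistics (X'X, X'y), so each replicate is a 3×3 solve and 5000
replicates take well under a second.  The bootstrap targets the
estimator's population value.  Note that this value sits slightly below
the generator's nominal total (a few percent) because `E[ln(X+1)]` is
below `ln(E[X]+1)` for noisy counts; the bias is common to compared
groups and cancels in ratios, and coverage checks in the test suite
define truth as the large-sample value of the estimator itself.

## Synthetic data

The generator emulates the data structure of a fecundity study in a
two-way recombinant inbred line (RIL) panel of *Drosophila melanogaster*:
12 lines genotyped at ~102 SNPs on the X, 2nd and 3rd chromosomes
(approximate map lengths 66, 108 and 106 cM), two larval diets, daily egg
counts over a 14-day assay, four-genotype complementation crosses, and
qPCR Ct plates with a reference gene.

**Genotypes.**  Each line's chromosome starts on parent A or B with
probability ½ and switches between adjacent markers with probability
`r* = 2r/(1+2r)`, the standard RIL map expansion of the Haldane fraction
`r = (1 − e^(−2d))/2` (Kosambi optional).  Lines are fully inbred — no
residual heterozygosity — and the X is treated like an autosome, which is
immaterial for a female-only phenotype and an autosomal planted QTL.

**Egg counts.**  The mean trajectory per environment is parameterized by
peak height (default 28 and 45 eggs/day for the low- and high-yeast
diets), peak day (4) and decline rate (−0.35).  Line, vial and fly
effects are Gaussian on the transformed scale (defaults 0.30, 0.15, 0.15)
and drawn with mean `−σ²/2` so that multiplicative noise is mean-one and
the configured curve is exactly the population mean.  Daily counts are
negative-binomial around the back-transformed mean (dispersion 20;
Poisson and noise-free as limiting cases), giving the overdispersion real
egg counts show.

**The planted QTL** shifts the transformed line intercept by `±δ_e/2` by
allele, with `δ = 2·line_sd·sqrt(v/(1−v))` so that the expected fraction
of among-line variance attributable to the QTL is exactly `v` on the
transformed scale (and to first order on the raw-total scale); the
per-environment weights (normalized to rms 1) create
genotype-by-environment structure without changing `v`.  A requested
`v > 0` with `line_sd = 0` is rejected as infeasible.  The test suite
verifies the calibration empirically: regressing noise-free line totals
on the planted allele recovers `v` within Monte-Carlo error.

**Complementation and RNAi designs** specify target mean totals per
genotype class; the intercept for each class is solved from the target by
bisection on the day-1–14 integral.  Four-class designs
(`A/Bal, B/Bal, A/Def, B/Def`) share a pool of six RILs per allele whose
random effects are common to both crosses of that allele (sd 0.15);
two-class control/RNAi designs are one genetically uniform cross per arm
(no stock-level variance), with 30 vials of one female each as the
default replication — the scale a fly fecundity RNAi assay typically has.

**qPCR plates** assume perfect doubling efficiency: the target gene's Ct
in the second group is shifted by −(true log2 fold change) cycles, the
reference gene is unaffected by group.  Noise is nested: a loading shift
per biological replicate shared by both genes (cancels in ΔCt),
gene-specific biological noise (sd 0.2 by default), and technical noise
at half that sd within biological replicates.

What the generator does **not** emulate: day-to-day environmental trends,
mortality during the assay (all flies lay for 14 days), non-Gaussian line
effects, segregation distortion, genotyping error, and qPCR efficiency
below 2.  Passing tests therefore demonstrate correctness of the
machinery and calibration under the assumed structure, not robustness to
these real-data features.

## The genome scan

The scan operates on line-level totals (one per line × environment,
estimated upstream by the fecundity model) and compares, at every marker
and pseudomarker,

    full:     y = M_i + E + M_i:E + ε
    reduced:  y = E + ε

by ordinary least squares, `LOD_i = (n/2)·log10(RSS_reduced/RSS_full)`.
Random effects live upstream in the curve fits; the scan models exactly
the terms above.

**Pseudomarkers** are inserted so adjacent evaluation points are ≤ 3 cM
apart.  Genotypes at pseudomarkers (and untyped or missing markers) are
drawn jointly along each chromosome by forward-filter backward-sampling
from the two-state Markov chain with RIL-expanded Haldane transitions —
50 imputations by default.  At typed markers all imputations agree with
the observations, so the LOD there is exact regardless of the imputation
count.  Per-position LODs are combined across imputations as
`log10(mean_i 10^LOD_i)` (likelihood averaging); a mean-of-LODs
alternative is available behind a flag.  Positions where an observed
genotype class has fewer than two lines are skipped with a logged
warning; positions monomorphic within an imputation contribute LOD 0 for
that imputation.

**Significance** is by permutation: line identities of the phenotype are
permuted with each line's environment pair kept intact (preserving the E
main effect under the null of no marker effect and no interaction), the
genome is rescanned, and the threshold is the empirical 95th percentile
of the null maximum LOD.  The implementation precomputes an orthonormal
basis of each (position × imputation) design once, so a 200-permutation
threshold on the full panel costs well under a second.

**Variance explained** at a position is `1 − RSS_full/RSS_reduced` on the
line-level totals, averaged over imputations, in percent.  At a *fixed*
locus this estimator is approximately unbiased: with a QTL planted at a
35% variance fraction, its mean at the planted marker is ~34% across
replicates.  At the *genome-wide peak* it is strongly inflated at this
panel size (~50% mean under the same conditions): selecting the maximum
of ~190 correlated positions in 12 lines captures polygenic and sampling
variance along with the QTL — the well-known winner's-curse inflation of
detected-QTL effect sizes.  By affine invariance of the LOD, this
inflation depends only on the design (lines, environments, grid) and the
true fraction, not on any generator scale, so reported
variance-explained figures at a selected peak should be read as upper
estimates.  `variance_explained` reports the peak value as defined; the
replay report compares it against generator truth with a wide tolerance
for exactly this reason.

**Support intervals** are LOD-drop intervals (default 3): the maximal
contiguous region around the peak with LOD ≥ peak − drop, reported in cM
with the flanking typed markers.

## Complementation and RNAi contrasts

Quantitative complementation asks whether fecundity satisfies
`(A/Bal) = (B/Bal) = (A/Def) > (B/Def)`.  The model is the fecundity
curve with contrast terms shifting the transformed intercept — A = the
indicator of `A/Def`, B = the indicator of `B/Def` (both configurable) —
plus random intercepts for RIL and vial nested within RIL, fitted by ML.
Sequential likelihood-ratio tests remove the contrasts last-to-first
(B first, then A); each statistic is referred to a χ² distribution with
**two** degrees of freedom although a single parameter is removed.
Fixed-effect LRTs in mixed models are anticonservative against χ²(1);
the 2-df reference makes the test deliberately conservative, and the
test suite verifies a null failure-to-complement call rate ≤ 5% at
α = 0.05 over 500 replicates.  A deficiency *fails to complement* iff
some sequential LRT is significant **and** that contrast's estimate is
negative.  RNAi designs run the same engine with a single treatment
contrast (`[0,1] = [control, RNAi]`), vial as the random grouping, and
the same conservative reference.

Contrasts act on the intercept only by default (a flag extends them to
the shape coefficients for sensitivity analysis).  When a variance
component is estimated on the zero boundary the optimizer's Hessian can
be singular; the fit falls back to the boundary solution (OLS), whose
Gaussian loglik is the constrained ML optimum, and sequential LRTs are
clamped at zero.  With zero-residual degenerate data the ML variance is
floored at 1e-10 so nested logliks coincide instead of amplifying float
noise.

## qPCR fold changes

Technical replicates are averaged per biological replicate; each
biological replicate's target Ct is normalized by the reference gene
(ΔCt); the estimate is `log2FC = mean ΔCt(group1) − mean ΔCt(group2)`
(negative = lower in group 2), i.e. −ΔΔCt under efficiency 2.0 — the
efficiency is a configuration hook, not estimated.  Inference permutes
*biological* replicates between groups (technical replicates are not
exchangeable across samples): exact enumeration whenever the assignment
count is small (3v3 → all 20 assignments), Monte-Carlo with add-one
smoothing otherwise.  A pure permutation CI is ill-defined for a point
estimate, so the reported interval is a percentile bootstrap over
biological replicates (5000 draws), labelled as such alongside the
permutation p.

## Life-history statistics

Standard correlations are pairwise-complete Pearson; partial correlations
come from the inverse correlation matrix,
`r_ij = −P_ij/√(P_ii·P_jj)` (equivalently residual regressions — the test
suite checks agreement to 1e-10).  P values are permutation-based (trait
columns permuted independently), matching the package's permutation-first
style.  Genetic-level analyses use line(-by-environment) means.  Variance
components follow environment (fixed) + line + line×environment + vial
(random) by REML, with conservative χ²(2) LRT p values for dropping each
random term; the broad-sense fraction is the line component over the sum
of all components.  Pairwise-complete handling of missing data is used
for standard correlations and complete-case for partials.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds (numpy `default_rng`);
identical seeds give bit-identical outputs, including the end-to-end
replay.  The replicated studies in the test suite and the acceptance
script use the study's own design dimensions (12 RILs, ~102 markers,
2 diets, 50 imputations, 3 cM grid) with 100–500 replicates per check and
200 permutations per null scan; bootstrap checks use 1000 replicates
rather than the 5000 used for final reported intervals.  These sizes keep
each check's Monte-Carlo error comfortably inside its assertion band.

## Known limitations

- The linearized trajectory is a stand-in for the exact historical curve
  form; totals and contrasts are internally consistent but not
  form-agnostic.
- Variance explained at a selected genome-wide peak is inflated at small
  panel sizes (see above); only fixed-locus values are calibrated.
- The scan assumes one phenotype value per line × environment; designs
  with unequal replication feed in through the upstream curve fits only.
- Percentile bootstrap CIs under-cover slightly for < ~20 flies per
  stratum; the coverage check runs at 30 flies.
- MixedLM occasionally lands on variance boundaries; the OLS fallback is
  exact there but the sequential LRT can be conservative in those rare
  fits.
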