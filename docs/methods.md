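# Methods

## Model

Let a_ij be the absolute abundance (load per unit sample mass) of taxon i
in sample j, Psi_j = sum_i a_ij the sample's total microbial load, and
o_ij = a_ij / Psi_j the relative abundance that sequencing observes. Under
the standard assumption that within one sample the sampling fraction (the
ratio of a taxon's expected sequenced count to its absolute abundance) is
constant across taxa, proportions computed from raw counts equal o_ij, so
a_ij = Psi_j * o_ij with Psi_j unobserved.

Group-level changes are defined as differences of expectations of logged
abundance, all in base 2 (so every change is a fold change). With
M_i^K = E[log2 a_i] over group K and
delta_psi = E[log2 Psi]^T − E[log2 Psi]^C,

    delta_M_i = M_i^T − M_i^C = delta_psi + d_i,
    d_i = mean(log2 o_i)^T − mean(log2 o_i)^C.

The d_i are estimable from relative data; delta_psi is the single shared
unknown. It is identified by the sparsity-of-change assumption — most taxa
undergo small absolute changes — as the minimizer of the weighted L1
objective

    f(x) = sum_i w_i |x + d_i|,   w_i = (D_i^T + D_i^C)/2,

with detection rates D_i^K (fraction of the group's samples where the
taxon's count is nonzero) as weights, down-weighting sporadically observed
taxa whose d_i are noisy. f is convex and piecewise linear with kinks at
{−d_i}; its minimizer is a weighted median of {−d_i}. The implementation
evaluates f on the inclusive grid −10, −9.99, …, 10 and returns the
minimizing grid point (ties broken toward the smallest |delta_psi|, then
the smaller value — the conservative "least total change" report); a
property test checks the grid answer against an independent sort-and-
accumulate weighted median. The ±10 scope covers ~1000-fold total-load
changes; a warning flags a minimizer on the boundary.

## Zeros

Zero counts are removed, never pseudocounted: group means of log2
abundance run over detected samples only. A taxon undetected in one whole
group has undefined d_i, is excluded from the objective, and is marked
untestable in the output rather than being assigned an infinite change.
Low-detection taxa (< 5 samples over both groups by default) are either
excluded or aggregated into a single "filtered-out-taxa" row that
preserves per-sample totals; detection-rate weights are computed after
filtering, on the taxa actually analyzed.

## Testing

Each taxon is tested against H0: delta_M_i = 0, i.e. the treatment log2
relative abundances shifted by the estimated delta_psi against the control
log2 relative abundances, with a two-sided Mann–Whitney U test. p-values
come from the permutation null that relabels the pooled shifted values:
exhaustive enumeration of all C(n_T+n_C, n_T) label assignments when that
count is within the permutation budget (an exact test), otherwise 500
Monte Carlo permutations with the add-one estimator
p = (1 + #{|U* − E[U]| ≥ |U − E[U]|}) / (1 + B), so p > 0 and seeded runs
are bit-reproducible (per-taxon RNG streams are spawned from the run
seed, independent of evaluation order). A tie-corrected normal
approximation (`test="asymptotic"`) is available for speed; at group sizes
as small as 6, and with ties from repeated values, the permutation route
is preferred. Benjamini–Hochberg adjustment (via statsmodels) is applied
per the `fdr` policy: "auto" turns it on when the smaller group exceeds 50
samples — with fewer samples the power cost outweighs the FDR benefit —
and off otherwise.

## Simulation framework

The benchmark emulates two-group studies by resampling a pool of
relative-abundance profiles:

1. per-group sample size n ~ U(6, 100); n pool columns drawn per group
   with replacement;
2. per-sample total loads Psi_j ~ U(1e10, 1e11) — the roughly 10-fold
   spread of flow-cytometry total cell counts per gram in human stool;
   absolute abundances a_ij = Psi_j o_ij;
3. a DA proportion rho ~ U(0.05, 0.95) selects ceil(rho * n_taxa) taxa
   whose treatment absolute abundances are multiplied by 2^{c_i},
   c_i ~ U(−10, 10);
4. observed treatment relative abundances are renormalized from the
   perturbed data; the control table is untouched;
5. ground truth: true delta_psi is the difference of group means of log2
   total load (mean-of-logs, matching the estimand); true delta_M_i the
   difference of detected-sample group means of log2 absolute abundance,
   mirroring the estimator's zero-handling so MAE measures estimation
   error, not convention mismatch.

The width of the Psi distribution matters: per-sample Psi scalars cancel
in the observed proportions, so the group imbalance of mean log2 Psi is an
*unestimable* component of the true delta_psi with standard deviation
SD(log2 Psi) · sqrt(2/n). Very wide load distributions therefore bound the
achievable accuracy of any relative-abundance method; the ~10-fold default
keeps this floor at realistic levels. For the same reason a deliberate
group-level load offset (`group_offset_log2`) is invisible in relative
data — it reproduces the method's documented blind spot (a uniform change
of all taxa degenerates to delta_M_i = delta_psi with no compositional
signal) and is off by default.

The synthetic pool draws per-taxon log-normal base abundances
(`base_sigma=3.0` natural-log units between taxa), jitters them per sample
(`dispersion=1.0`), zeroes the lowest `sparsity=0.3` fraction of each
column (a detection floor), and renormalizes. These defaults reproduce the
dominance structure of genus-level human-gut profiles: median top-taxon
share ≈ 0.32, top-5 share ≈ 0.70, ~30% zeros. Real pools can be supplied
as TSV (counts or proportions).

Evaluation: MAE = (1/n) sum_i |delta_M_hat_i − delta_M_i| over taxa with
both quantities defined; FNR/FPR from the 2×2 table of predicted vs truly
perturbed taxa among the taxa the method evaluated. Baselines: RAC uses
d_i itself as the delta_M estimate (quantification only); MWU is the
unshifted rank test on logged relative abundances (identification only).
The benchmark driver records per-instance metrics in tidy TSV and
summarizes per-method medians plus the OLS regression (slope, adjusted R²)
of estimated on true delta_psi.

At the default desk scale (50 instances from a 200-taxa × 100-sample
pool; the reproduction helpers in `qmd.reproduce` use this size), the
regression's adjusted R² is ≈ 0.97–0.99 and the median MAE ≈ 0.2–0.3 log2
units across seeds. The reproduction helpers run the pipeline with the
asymptotic test option because the reported quantities do not depend on
p-values; the estimator is identical.

## What the synthetic benchmark does and does not show

The generator reproduces compositional coupling, realistic dominance,
sparsity, and load variation, but not sequencing-depth count noise,
overdispersion beyond log-normal jitter, taxon–taxon correlations, or
batch effects. Passing benchmarks demonstrates correct recovery of the
quantities the model defines under its own assumptions — not performance
on data that violate them (e.g. a community where most taxa change).

## Numerical choices and degenerate inputs

- Grid construction uses an integer point count to avoid floating-point
  drift at the endpoints; tie detection uses a 1e-12 relative tolerance on
  the piecewise-linear objective.
- Relative-abundance columns must sum to 1 within 1e-9; zero-total samples
  are an error (normalization undefined; silently dropping them would bias
  detection rates).
- Group labels are recoded to T/C at metadata read time so the sign
  convention delta_psi = T − C is fixed once.
- All randomness flows from a single seed through spawned SeedSequence
  streams (benchmark instance → per-taxon test), making every output
  byte-identical across repeated seeded runs.

## Known limitations

- **Uniform-change blind spot.** If all taxa change by a similar factor
  (e.g. broad-spectrum antibiotics), relative abundances barely move and
  the estimate collapses to delta_psi ≈ 0, delta_M_i ≈ 0.
- **Conservative testing under the global null.** The shift is estimated
  from the same data as a weighted median of −d_i, so under a global null
  it absorbs the common-mode compositional fluctuation of the d_i; the
  shifted residuals are then less variable than label permutation assumes
  and the realized size falls below alpha (measured ≈ 0.02 at alpha = 0.05
  on null benchmark instances, versus ≈ 0.05 for the unshifted test on the
  same data). The test is never anti-conservative in these conditions, but
  exact size-alpha calibration should not be expected.
- **Tied profiles are conservative too.** Resampling with replacement from
  a pool smaller than the group size duplicates whole profiles; the
  permutation distribution then carries large atoms and the ≥-observed
  convention deflates size further. Calibration studies should use pools
  large relative to the group size.
- Accuracy degrades as the DA proportion approaches 1 (the sparsity
  assumption fails); in the benchmark the median MAE stays below 1 log2
  unit for proportions up to 90%.
- No confidence interval on delta_psi is provided, and no covariate
  adjustment, paired designs, more than two groups, or longitudinal
  structure.
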