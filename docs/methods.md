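# Methods

This note records the statistical conventions the package implements,
the choices made where the literature leaves the convention open, and
what the synthetic-data generator does and does not emulate.

## Data model

The unit of analysis is a simultaneous lineup of `k` faces (default 6)
shown to one witness. Outcomes are classified as suspect ID, filler ID
or no ID, each with a 7-point confidence rating (1 = guessing,
7 = certain) and optionally a response time in seconds. With no
designated innocent suspect, a target-absent lineup can only yield
filler IDs or rejections; the data model enforces this. Rejection
confidence is retained in tables and in the simulator (frequency tables
publish it) but is never used by the ROC, CAC or model-fitting code,
which operate on identifications only.

The packaged fixture holds the full outcome-frequency tables of a
2 (age group) x 2 (description condition) lineup study with 250
target-present and 250 target-absent lineups per cell. Its integrity is
pinned by regression tests: every row sum reproduces the published
identification rates and all four published chi-square statistics to
four decimals.

## Identification rates and contrasts

* Correct ID rate = TP suspect IDs / n_TP.
* Estimated false ID rate = TA filler IDs / n_TA / k. This estimates how
  often an *innocent suspect* would be picked when no lineup member is
  designated as such; requesting it for a designated-suspect design
  raises an error rather than silently estimating.
* Condition contrasts are Pearson chi-square tests on the 2x2 table of
  outcome counts versus the remainder, df = 1, **without** Yates
  continuity correction — the only variant consistent with the published
  statistics — with two-sided p from the chi-square distribution.

## Confidence binning

The default scheme pools ratings into low (1-3), medium-low (4),
medium-high (5) and high (6-7) confidence; the extreme raw levels are
too sparse for resampling. Binning is an exact partition of the scale
and conserves totals; any partition may be supplied.

## ROC and pAUC

ROC points cumulate counts from the strictest bin downwards:
point j = (cumulative TA filler IDs at bins >= j / n_TA / k,
cumulative TP suspect IDs at bins >= j / n_TP), with an anchor at
(0, 0). Both coordinates are nondecreasing by construction and the last
point equals the overall rate pair.

* **pAUC** is the trapezoidal area from x = 0 to the cutoff. A cutoff
  inside a segment is handled by linear interpolation; a cutoff beyond
  the rightmost point extrapolates the final positive-width segment
  linearly and flags the result, since the cutoff rule below is designed
  to avoid extrapolation.
* **Cutoff rule:** the smaller of the two curves' rightmost false ID
  rates (the more conservatively responding condition); ties are
  identical cutoffs.
* **Bootstrap:** a case bootstrap over lineups — equivalently a
  multinomial redraw of the outcome-category counts — done independently
  for TP and TA lineups, 10,000 replicates by default. For a difference,
  replicates are paired by index across conditions with independent
  resampling per condition; Z divides the observed pAUC difference by
  the standard deviation (ddof = 1) of the replicate differences, and p
  is two-sided normal. Zero bootstrap variance is guarded (Z = 0 or
  signed infinity, never NaN).
* The pAUC *point values* depend on the anchoring/interpolation
  convention, which published analyses rarely state; the inferential
  conclusions (sign, significance pattern) are the stable quantities and
  are what the regression tests pin.

## CAC and RAC

Per bin, suspect-ID accuracy = CID / (CID + FID / k), with k read from
the table rather than hard-coded. Bins with no identifications are
undefined (NaN), never 0. Response-time bins are half-open [low, high)
with the first bin open below and the last open above; a response at
exactly an edge falls in the upper bin. The default edges are 6, 12 and
18 s. Uncertainty is a percentile bootstrap (independent TP/TA
resampling, 10,000 replicates, central 68% interval ~ +-1 SE); bins
empty in more than half the replicates are flagged unstable. Curve
comparison follows the graphical rule of the field — non-overlapping
error bars — exposed as a predicate, deliberately not as a p-value.

Sparse bins can be re-merged: the smallest bin below `min_count` is
repeatedly folded into its smaller neighbour until all bins hold at
least `min_count` identifications (default 10, a common
rule-of-thumb minimum for resampling a proportion; published analyses
re-bin on bootstrap infeasibility without stating a threshold). The
merge log is returned.

## Signal-detection model

Independent-observations rule: each member draws an independent
strength, fillers from N(0, 1), the target from N(mu_t, sigma_t); the
maximum is identified iff it exceeds c_1, with confidence given by the
highest criterion exceeded. Category probabilities are differences of
the above-criterion curves:

* TP suspect ID above c: integral over x >= c of
  phi((x - mu_t)/sigma_t)/sigma_t * Phi(x)^(k-1),
* TP filler ID above c: (k-1) * integral of
  phi(x) * Phi(x)^(k-2) * Phi((x - mu_t)/sigma_t),
* TA any-ID above c: 1 - Phi(c)^k (closed form), split evenly over the
  k fillers.

Integrals use fixed 256-node Gauss-Legendre quadrature truncated 10 SD
beyond the relevant mean; against adaptive quadrature at tolerance
1e-12 the error is at machine precision, far below the 1e-8 target, and
the fixed rule is orders of magnitude faster inside the optimiser.
A 10^6-draw Monte-Carlo oracle independently confirms the category
probabilities across a grid of means, criteria and lineup sizes.

Fitting maximises the multinomial log-likelihood (TP and TA blocks
summed) over mu_t and the criteria; sigma_t is pinned at 1 in the
default equal-variance mode and free otherwise. Rejection confidence is
not modelled: no-ID counts are collapsed across confidence, because the
ROC/pAUC analyses the model supports use identifications only. The
criteria are parametrised as c_1 plus log-increments to enforce strict
ordering, initialised from the empirical cumulative TA ID rates through
the closed form (c = Phi^-1((1 - rate)^(1/k))), and optimised with
Nelder-Mead from three starting points (target-mean starts 1.0, 0.3,
2.0 with small deterministic jitter on the criteria) to guard against
local optima. Non-convergence is flagged in the result. Pearson
chi-square minimisation is available as an alternative objective for
sensitivity checks, and the goodness-of-fit chi-square is always
reported. d' = (mu_t - mu_l)/sigma_l is defined only for the
equal-variance model; the unequal-variance index d_a is intentionally
not provided.

Parameter recovery on simulated data (mu_t = 1.5, seven criteria,
20,000 lineups per type) is within +-0.1 on mu_t and +-0.05 on every
criterion. On the packaged young-control cell the fitted model
reproduces the observed correct ID rate within binomial sampling error,
and the model ROC passes within the 95% bootstrap band of three of the
four empirical points; the miss at the strictest point is the classic
signature of unequal target variance, which the equal-variance model
cannot express — a known limitation, not a defect of the fit.

## Simulator

`simulate_trials` draws member strengths per lineup, applies the max
rule and criteria, and emits trial records. Two pieces are generative
inventions, since the analyses they feed state no generative model:

* **Response times** are lognormal:
  rt = exp(log(base) - slope * margin + noise), margin = s_max - c_1.
  Defaults base = 10 s, slope = 0.35, noise_sd = 0.45 give median RTs
  in the 3-15 s range typical of lineup decisions and produce the
  fast-decisions-are-accurate structure the RAC analysis assumes
  (accuracy declining from ~0.88 below 6 s to ~0.65 above 18 s at the
  default generating parameters). The margin is measured from c_1 for
  every response so that strong-evidence identifications are fast and
  rejections are slow; distance to the *nearest* criterion was rejected
  because it makes all responses near-criterion and destroys the
  structure.
* **Rejection confidence** comes from thresholds below c_1 (default
  evenly spaced 0.4 apart): the further the strongest face falls below
  c_1, the more confident the "not present" response. It exists only so
  simulated tables have realistic no-ID columns; nothing downstream
  consumes it.

What the simulator does *not* emulate: witness covariates, own-age
effects, verbal-description content, within-participant correlation
(each lineup is one independent witness, as in the emulated design) and
any confidence-RT interaction beyond the shared dependence on margin.
Passing tests therefore validate the estimators under the model's own
assumptions, not the full richness of field data.

## Power analysis

For each per-cell lineup count n, both conditions are simulated from
their generating parameters, tabulated, binned, and pushed through the
complete pAUC bootstrap Z-test; power is the rejection fraction over
`n_sim` replicates (default 200; 2,000 bootstrap replicates per test by
default, 500 in the calibration runs). Replicates in which a condition
yields no identifications are skipped and counted. Under identical
generating parameters the test rejects at 0.055 with n = 100 per cell
(200 replicates, seed 1) — within Monte-Carlo error of the nominal 0.05
— and power rises towards 1 with the separation of the target means and
with n. Problem sizes in the shipped tests (n = 100-400 per cell,
200-500 bootstrap replicates for calibration runs, 8,000 lineups per
type for structure checks) were chosen as the smallest sizes at which
the Monte-Carlo error bands are informative.

## Reproducibility

Every stochastic routine takes a seed; nested randomness (power
analysis, the one-command pipeline) derives child seeds via
`numpy.random.SeedSequence` spawning, so a single integer reproduces
every interval and p-value exactly. The one-command report serialises
with sorted keys and is byte-identical across reruns at a given seed.
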