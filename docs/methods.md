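# Methods

## Signals and the gold standard

A squiggle is an ordered series of segmented step-current events.  The
gold standard of a sequence of length `L` under a k-mer model is the
series of `L − k + 1` table lookups obtained by sliding the k-length
window along the sequence; it is noise-free by construction, so per-k-mer
spread columns in pore-model files are read and ignored.  RNA input is
mapped U→T so a single alphabet serves both nucleic acids.

All comparisons are performed on z-normalized signals,
`(S − mean(S)) / std(S)`, using the population (divide-by-N) standard
deviation so the unit-variance contract is exact at any length; the
original moments are retained so the transform is invertible.  The
sample-variance alternative would be a one-line change.

The synthetic fixture (`make_fixture`) stands in for an OEM pore model
and a spike-in control: k-mer levels are i.i.d. Gaussian (mean 100,
spread 15, pA-scale — the typical magnitude of published pore models) and
the reference sequence is uniform over {A,C,G,T}.  Continuous levels make
gold event values pairwise distinct almost surely except at repeated
k-mers, which is the property the indel proxies are exact under.  Because
the pore model's word length is device-specific, k is a parameter
(default 5 in the examples; a 1314-nt sequence then gives the 1310-event
gold used throughout).

## DTW and the indel proxies

`dtw_align` computes the exact global alignment under local cost
`|aᵢ − bⱼ|` summed along a boundary-anchored monotone path with the
symmetric step set {(1,1),(1,0),(0,1)}, no band and no slope weighting.
The full (n × m) accumulated-cost matrix is built row-wise (numba
kernel, O(n·m) time) and retained for the backtrace.  Ties are resolved
deterministically — diagonal first, then the step consuming a squiggle
event, then the step consuming a gold event — which makes alignments
reproducible and biases degenerate ties toward the insertion-dominated
regime these signals live in.  Squared local cost is deliberately not
offered: absolute differences keep ensemble distances proportional to
length and noise amplitude.

A gold position matched by `c + 1` squiggle events contributes an
insertion count of `c`; a squiggle event matched by `c + 1` gold
positions contributes a deletion count of `c`.  Totals always reconcile:
Σ insertions − Σ deletions = m − n.  On noiseless duplication-only mocks
from a distinct-valued gold the proxies equal the generator's ground
truth exactly (verified against it in the tests, with the alignment
itself checked against an independent exhaustive-recursion oracle on
small instances).  Profiles pool counts above the reporting bins
(insertions > 5, deletions > 3) into the top bin.

Ensembles are compared to gold by the mean ± std of per-squiggle DTW
distances (the Frechet-style measure used for consensus-averaging work).
Inputs not flagged as z-normalized are normalized per squiggle on their
own moments; simulated ensembles are generated in the z-space of their
gold and carry the flag, so noiseless duplication-only mocks sit at
distance zero exactly.

## Simulation models

Mocks are built by walking the z-normalized gold positions in order.
Each position is first tested for deletion; a firing deletion removes a
run of positions (run length 1 for linear kinds, or drawn from the
renormalized {1,2,3} deletion categorical for table kinds — multi-base
deletion rates vanish so quickly that longer runs are pointless).
Surviving positions emit their gold value once plus extra copies:

* `chan_bernoulli` — at most one duplicate, probability p; mean LSF 1 + p.
* `chan_geometric` — emit-another with probability p (geometric
  duplication); mean LSF 1/(1 − p).
* `local_table` — counts drawn from the rate-curve categorical evaluated
  at a fixed reference LSF (`local_ref_lsf`, default 1.7, the empirical
  mean; the value such a model should be calibrated at is genuinely open,
  so it is an explicit knob).
* `global_linear` / `global_table` — a per-squiggle target LSF is drawn
  from a length model first and the probabilities
  `P = I₀ + I₁(1 − 1/LSF)` (or the table categorical) are evaluated
  there.  Realized length is stochastic around the target — there is no
  rejection step to hit it exactly; the extra spread is small relative to
  the width of the LSF distribution.

Length models are either empirical (step CDF over observed LSF values,
linear-interpolated inverse) or parametric (GEV, lognormal, loglogistic
on the raw length scale divided by the gold length).  Draws at LSF ≤ 1
are rejected (cap 1000 attempts, then the model is declared degenerate).

Noise is injected after distortion: i.i.d. Gaussian deviates of standard
deviation 1/SNR added to the z-normalized events, and the result is *not*
re-normalized — re-normalizing would shrink the realized noise and the
signal would no longer sit at the target SNR.  The squiggle keeps its
z-space flag; its realized moments are perturbed by design.

All randomness flows from one seeded generator per ensemble; seeds are
mandatory, never implicit.  The rejected alternative of re-reading
squiggle-side surplus matches as distortions rather than deletions is not
implemented: it zeroes the measured deletion rates and is a dead end.

## Rate curves, tails and the assembled categorical

Per-count rates are linear in (1 − 1/LSF) on the percent scale.  The
bundled reference curve (measured on MinION direct-RNA enolase
squiggles) has A = 90.2, B = −56.1 for zero insertions down to
A = −0.7, B = 6.2 for four, and A = 88.7, B = 17.7 down to A = 0.3,
B = −0.4 on the deletion side.  Deep insertion counts continue the
four-insertion slope geometrically, `B₄(1 − 1/LSF)/decay^(I−4)` with
B₄ = 6.2 and decay 1.3 (a 2.0 variant damps the tail harder).  Because
the curves are empirical fits, not a probability law, evaluations are
clamped to [0, 100] and assembled categoricals are renormalized (the raw
percent rows sum to ~96% at LSF 1.7 before the tail); insertion support
is truncated at 20, beyond which the tail is below 10⁻⁴ for LSF ≤ 3.5.
The tail extension is opt-in for table simulations: the per-base table
model is characterized without it (mean LSF ~1.5), and adding it is what
widens the global model's length distribution.

`fit_rate_curves` inverts the process: squiggles are grouped into length
bins (default 50 events, at least 3 bins required), each bin contributes
its DTW-proxy per-count mean percentages at its mean LSF, and each
count's (A, B) is fitted by weighted least squares against (1 − 1/LSF)
with bin sizes as weights.  Note that Eq-style generators are only
self-consistent between target and realized LSF for
`P = 100(1 − 1/LSF)`; the closed-loop recovery test therefore constructs
its ensemble so that the true zero-insertion fraction follows the known
(A, B) at the realized length.

## Length-distribution fitting

`fit_long_tailed` fits GEV, lognormal or loglogistic by maximum
likelihood.  The GEV shape is reported in the convention where negative
shape means a bounded upper tail (scipy's shape is its negative);
lognormal and loglogistic are parameterized on the log scale
(μ = log-median, σ = log-shape), so a ~2280-point median reports
μ ≈ 7.73.  scipy's starting fits are polished with Nelder-Mead — the
moment-started optimum is often not stationary enough for the observed
information to be positive definite — and 95% CIs come from the
finite-difference Hessian of the negative log-likelihood at the MLE
(normal approximation; a bootstrap would be straightforward but costs
two orders of magnitude more).  Degenerate data (constant lengths,
singular information) yields a flagged non-converged fit rather than an
exception.  Coverage is exercised in the tests: generating parameters
fall inside their own CIs in ≥ 90% of replicates at n = 2000.

## SNR estimation

Squiggles of similar length are assumed to share indel structure, so the
difference of the two warp-expanded series in a pairwise DTW is
predominantly noise: each pair contributes `K·√2 / std(DIFF)`, the √2
accounting for two noisy streams, and K (mean band length / gold length,
computed at full precision, overridable) absorbing residual indel
mismatch.  DIFF is taken along the full optimal path of both
warp-expanded series — whether a resampled common grid would serve
better is open; the full-path form is this package's convention.

Known limitation: the unconstrained warp preferentially matches noisy
values, so the estimator acquires an upward bias as SNR falls.  The test
suite bounds it — within 10% of truth at noise std ≤ 0.25 (SNR ≥ 4, the
regime real direct-RNA data occupies), biased high but within ~25% at
noise std 0.5 (SNR 2).  Estimates in the SNR ≈ 2 regime should be read
as upper bounds.

## Cleaning cascade

Order is fixed: short-read removal (anything shorter than gold is a
gross truncation, since real squiggles run longer than gold) → leader
stripping → 5σ outlier pruning → sectioned chimera rejection, with a
reconciled per-squiggle disposition report.  Ensemble statistics for
pruning are computed after leader stripping, because leaders are
non-biological and bias the moments.

Leader detection is a documented stand-in (the field has no canonical
rule): scanning from the start, the boundary is the first index whose
following window (default 50 events) matches the downstream stream in
mean (within 2 downstream std) and spread (within a factor of 2).
Boundaries shorter than half the window are reported as none, and the
scan is capped at the first quarter of the stream — enzyme leaders are
short, and without the cap a strongly chimeric stream has its entire
pre-breakpoint segment declared a leader and is then removed at the
wrong stage for the wrong reason.

Outlier pruning tests three per-squiggle statistics independently —
event mean, event std, length — each at 5 ensemble standard deviations
(squiggle lengths are not normal, so the usual 2σ rule would over-prune).
Chimera rejection splits each squiggle into contiguous equal sections
(default 10, remainder to the last), takes the mean of section stds, and
rejects at 2σ from the ensemble mean of that statistic.

Two caveats.  A single extreme outlier inflates the ensemble σ it is
judged against, so 5σ separation requires the outlier not to dominate
(the maximum attainable deviation among n squiggles is ~√n σ).  And the
2σ chimera re-test is not idempotent on noisy ensembles in general —
trimming shrinks the σ it recomputes — so cascade idempotence holds on
homogeneous ensembles (and is tested there) but a second pass over a
noisy ensemble may trim a few percent more.

## What the synthetic data does and does not show

The generator reproduces the features the analysis machinery is built
around: duplication-dominated distortion, the ~1.7 mean LSF, broad
long-tailed length distributions, white noise at a controlled
z-normalized SNR, and (for cleaning tests) planted leaders, chimeras and
outliers.  It does not model dwell times, per-k-mer noise spread,
raw-sample (pre-segmentation) signal, homopolymer ambiguity beyond what
repeated k-mers induce, or temporally drifting run conditions.  Passing
tests therefore demonstrate that the estimators are correct and
well-calibrated under the stated generative models — not that real
sequencer distortions follow those models; on real data the proxies are
estimators, exactness holds only in the noiseless distinct-valued limit,
and absolute DTW distances depend on the alignment conventions above.

## Problem sizes

Proxy fractions are per-position means and are length-invariant, so the
test suite runs its closed loops on 300-500-event golds with a few
hundred mocks; `scripts/acceptance.py` runs the two headline experiments
at the full scale of a 1310-event gold and 500 mocks per model.
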