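# Methods

## The measurement being modelled

A CMAP scan records a muscle's compound muscle action potential (CMAP)
amplitude — baseline to negative peak, in mV — in response to ~500
transcutaneous electrical stimuli whose intensity declines linearly across
the motor-unit recruitment range (0.1 ms pulses at 2 Hz; the pulse timing is
metadata only in this package, which models amplitudes, not waveforms).
Before the scan, an automatic search finds S0, the intensity that first
elicits the lowest-threshold motor unit, and S100, the intensity at which
the CMAP is maximal; the scan then sweeps a slightly wider range.

Three quantities are derived per scan:

* **maximum CMAP** — the largest amplitude observed;
* **D50** — the number of largest consecutive differences among the
  size-ranked amplitudes (as % of max CMAP) needed to accumulate 50% of the
  maximum; small D50 means a discontinuous curve built from few, large
  motor units;
* **MUNE** — a model-based motor unit number estimate obtained by fitting a
  motor-unit-pool model to the scan (an MScanFit-style procedure).

The cohort stage applies the clinical study's statistical plan to
per-subject tables: Kolmogorov–Smirnov normality screening, t-test vs
Mann–Whitney U selection, mean ± SD vs median (min–max) reporting, and
Pearson correlations between MUNE and clinical scores.

## Generative model

Each motor unit j has a MUAP amplitude a_j (mV), a mean activation
threshold mu_j (mA) and a relative spread rs_j (threshold SD as a fraction
of the mean).  At intensity I it fires independently with probability
Phi((I − mu_j)/(rs_j · mu_j)) — the standard threshold-tracking excitability
convention; no published functional form exists for this hardware, so the
Gaussian CDF was chosen as the field's default.  The recorded amplitude is
the sum of the firing units' amplitudes plus zero-mean Gaussian baseline
noise, floored at 0 mV because amplitudes are baseline-to-negative-peak
magnitudes.  Probabilistic overlap of nearly equithreshold units
("alternation") arises implicitly from independent Bernoulli firing.

Default parameters, chosen once as the package's study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| stimuli per scan | 500 | scan protocol |
| relative spread | 2.5% | typical motor-axon threshold variability |
| baseline noise SD | 0.03 mV | typical surface-EMG baseline |
| MUAP amplitude | lognormal, mean 0.155 mV, log-SD 0.5 | many small units, few large; mean = 16.75 mV / 108 units |
| healthy-like pool | ~108 units, ~16.75 ± 3.55 mV max CMAP, thresholds 4.5–16 mA | published control group |
| SCI-like pool | ~59 ± 37 units, ~8.01 ± 3.97 mV, thresholds 8.5–19.4 mA | published tetraplegia group |
| S0/S100 probability cutoffs | 0.05 / 0.95 | pre-scan search is not defined numerically; bisection to 0.1 mA |
| protocol margin | 5% of [S0, S100] per side | "entire recruitment range" is unspecified |

Cohort generation draws a unit count and a target maximum CMAP per subject
from the group distributions (truncated at 2 units / 0.3 mV) and rescales
the sampled amplitudes to the target.  A subject who draws few units but a
normal CMAP therefore has enlarged units — collateral reinnervation emerges
per subject rather than being imposed as a group-level factor, because the
published group means (59 units at 8.01 mV vs 108 at 16.75 mV) imply nearly
equal *mean* unit sizes while individual subjects deviate strongly.
`PoolSpec.reinnervation_factor` (≥ 1) is still available for constructing
single enlarged-unit pools explicitly.

S50 — reported clinically but never defined — is implemented as the
intensity at which the noise-free expected amplitude reaches 50% of the
maximum CMAP.

## D50

Amplitudes are floored at 0, expressed as % of the maximum, sorted
ascending (A), differenced (dA), re-ranked largest-first and accumulated
(M).  D50 is the smallest n with M_n strictly above 50%; the strictness is
configurable for sensitivity checks (an exact-50% boundary then picks the
previous n).  The formulas generalise to any N ≥ 2 even though the protocol
fixes N = 500.  Ties among equal differences cannot affect the cumulative
sums.  D50 depends only on the multiset of amplitudes, hence is invariant
to stimulus order and to positive rescaling.

## The MUNE fitter

The fitter is this package's own re-creation of a model-based scan-fitting
MUNE; the original program's internals are unpublished, so every numerical
choice below is a documented design decision of this implementation.

**Objective.**  A candidate model is scored by simulating R replicate scans
(default 16) at the recorded intensities with fixed ("common") random
numbers, and comparing two statistics against the recording, both as mean
absolute deviations in % of the maximum CMAP:

1. *rank component* — amplitudes sorted within consecutive windows of ~25
   stimuli along the intensity axis, recorded vs the replicate mean;
2. *scatter component* — the per-window SD of successive amplitude
   differences (a trend-free variance estimator), recorded vs replicates.

Stimulus-by-stimulus residuals are not fitted: they are floored by
alternation scatter and carry almost no count information.  The scatter
profile is the count-identifying statistic — per stimulus the alternation
variance is sum a_j² p_j(1−p_j), so at a fixed recruitment curve it scales
with unit size.  Its typical magnitude is about half the rank component's,
so it enters with weight 2 to contribute comparably.  The plain
stimulus-matched percentage error (MAD % of max, RMSE optional) is exposed
separately as `percentage_error`.

**Initialisation.**  Baseline noise is estimated robustly twice — from the
positive half of the floored sub-threshold tail (median / 0.6745) and from
successive differences on the supramaximal plateau — and averaged.  Every
sorted-amplitude step above 3× this noise SD becomes a unit whose threshold
is the matching rank of the sorted intensities; sub-floor differences are
accumulated into padding units.  The accumulation chunk is scanned over a
12-point geometric granularity grid (6× down to 0.25× the floor), producing
candidate models that assume coarser or finer sub-resolution structure.

**Refinement.**  Stochastic local search: per iteration one move from
{perturb amplitude, perturb threshold, perturb spread, split, merge, add,
delete} is accepted iff the objective decreases (count-increasing moves must
gain > 0.15 percentage points, which blocks splitting noise), stopping at
1500 iterations or 200 proposals without a gain > 1e−3.  Fitted spreads are
bounded below by 2 stimulus spacings so that sharp micro-units cannot
reproduce individual alternation flips verbatim.

**Run protocol.**  Per run, candidates are screened by raw objective, the
five leaders are briefly refined (450 iterations), and the winner — chosen
on a *held-out* replicate set of 32 draws to avoid the winner's curse of
comparing fits on their own random numbers — is refined fully.  Three such runs are performed (run k
seeded with seed + k); the minimum-validation-error run is accepted if its
error is below 7%, else further 3-run batches are attempted up to 5 before
an explicit non-convergence error carrying the best effort.  Accepted fits
therefore always satisfy the < 7% rule.

**Known limitations.**  Unit counts are only identified up to the scan's
resolution: units smaller than the noise floor, or packed many-per-spacing,
cannot be separated, so estimates compress toward ~70–100 for very large
pools (the sampling-limit regime; the recovery experiment reports the bias
at N = 80 rather than asserting it away).  The estimator assumes the same
Gaussian-threshold Bernoulli model as the simulator; real scans add
waveform-level effects (phase cancellation, electrode drift, impedance
changes) that neither the generator nor the fitter represents, so passing
recovery tests here demonstrates internal consistency of the method, not
field accuracy on recorded data.

## Cohort statistics

* SD uses the sample convention (n−1), which reproduces the published MUNE,
  CMAP and D50 SDs; the published pinch/grip SDs match neither convention
  exactly and are not asserted.
* The normality screen is a Monte-Carlo Lilliefors test: the null
  distribution of the one-sample KS statistic with estimated Gaussian
  parameters is simulated once per sample size (2000 draws, fixed internal
  seed, cached), making the decision deterministic; the asymptotic KS
  p-value is available but anticonservative here.
* Group comparison: equal-variance two-sided t-test when both groups pass
  the screen, else two-sided Mann–Whitney U (exact for combined n ≤ 8
  without ties, normal approximation with tie correction otherwise).  Welch
  was not used because the plan names the classical test.
* Pearson r with the t-distribution p-value (n−2 df).  No multiple-testing
  correction anywhere, matching the plan.
* Zero-variance vectors: normality p = 0 with a warning (degenerate),
  correlation raises.

## Problem sizes

The recovery experiment fits 50 scans per pool size (10, 20, 40, 80 units)
under the 500-stimulus protocol; the group power check simulates 100
cohorts of 13 vs 13; the paired reinnervation contrast fits 50 pairs at
matched ~11.5 mV maximum CMAP.  These sizes give stable Monte-Carlo
estimates while keeping a full run of the test suite and the acceptance
script in the minutes range on one CPU.

## What the synthetic data do and do not show

The generator emulates unit-count and unit-size structure, recruitment
thresholds anchored to the published stimulus-intensity ranges, alternation,
and additive noise.  It does not emulate MUAP waveform shape or phase
cancellation (amplitudes add linearly), skin-impedance drift, the elevated
S0 observed after SCI (attributed speculatively to skin changes), 2 Hz
timing effects, or any correlation between clinical covariates and
electrophysiology — generated clinical scores are independent draws.  The
packaged per-subject table, in contrast, is the published measurement
itself, so the cohort-statistics stage is validated against real numbers.
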