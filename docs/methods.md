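# Methods notes

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the pipeline, stage by stage.  It
states no empirical numbers beyond those the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic data: what it emulates and what it does not

The generator produces multichannel recordings in which each channel is a
sum over the five EEG bands of band-limited noise carriers whose
amplitude envelope is modulated multiplicatively on the log scale:

    signal_c(t) = Σ_b carrier_cb(t) · exp( μ_b + Σ_p loading_p(b,c)·s_p(t) + ε ),

with `s_p(t) = A_p sin(2π t/P_p + φ_p)` the latent modulator states and
ε white log-envelope noise at 30 s resolution (default SD 0.1).  Carriers
are white noise filtered with 4th-order Butterworth band-passes and
scaled to a 1/f-like base amplitude (δ 1.0, θ 0.7, α 0.5, β 0.35,
γ 0.25, arbitrary units).  For speed, sub-γ carriers are synthesised at a
decimated 80 Hz rate (their content lies below 30 Hz, far under the
40 Hz decimated Nyquist) and interpolated exactly by zero-padded FFT;
only γ is filtered at the full rate.  An optional flag lets modulator
frequency wander by ±10% (slow random walk) to exercise EMD's tolerance
to nonstationary rhythms.

Seizure "evolutions" are 2-D arcs (20–60 steps) whose extent, radius and
length are a squashed weighted sum of the modulator states at onset plus
noise, so the planted pairwise dissimilarity
`Σ_p w_p |s_p(t_a) − s_p(t_b)|` is recoverable both directly and through
DTW of the trajectories.

What the generator does **not** emulate: ictal waveforms, artefactual or
dropped channels, reference changes, non-sinusoidal or mutually coupled
rhythms, medication effects, and realistic spatial covariance between
channels.  Passing tests therefore demonstrate correct recovery of
planted structure under idealised envelope dynamics, not performance on
clinical recordings.

A band-power fast path (`generate_band_power`) draws the 30 s band power
directly as `(base·envelope)²` with log-normal measurement noise
(SD 0.08), which matches what Welch estimation of the synthesised
waveform yields up to estimation noise; multi-day tests of the slow
stages use it to avoid waveform synthesis entirely.

**Problem sizes.**  The desk-scale fixture subject used by the test suite
and the acceptance script is 4 channels × 256 Hz × 4 days (T = 11 520
epochs) with 8 seizures and two modulators: circadian (1 day, amplitude
1.0, δ–α on every channel) and ultradian (6 h, amplitude 0.8, β/γ on half
the channels).  Four channels rather than a larger grid keeps a full
five-seed end-to-end battery plus permutation studies within a desk-scale
compute envelope; every stage is channel-count-agnostic and the spatial
tests (loading patterns, Gini) use 8 channels via the band-power fast
path.

## Band power

30 s non-overlapping epochs (trailing partial epoch dropped); Welch PSD
from ten 3 s segments per epoch, Hamming taper, constant detrend,
one-sided density scaling; band power = Σ PSD·Δf over `[lo, hi)`.  The
taper and detrend are conventions (configurable); with them a
unit-variance in-band signal reports power ≈ 1.  Raw powers are floored
at 1e-12 before the log so silent test channels cannot produce −inf.
Per band, log powers are z-scored with the mean/SD pooled over that
band's channels × epochs — so relative differences between channels are
preserved — and mapped through 1/(1+e^−x).  Rows are stacked band-major
(all δ channels, then θ, …) and the ordering is recorded in `row_index`.
Seizure epochs are retained by default; a flag drops epochs overlapping
annotated seizures for the sensitivity variant.  A float32 batched-FFT
implementation of the same estimator is used on long recordings; the
suite asserts its agreement with the reference `scipy.signal.welch` path.

## NMF

Initialisation is nonnegative SVD with low-rank correction: the
dominant-sign parts of the first ⌈k/2⌉+1 singular triplets provide up to
2p−1 candidate rank-1 nonnegative terms, the k strongest (by
σ·‖u±‖·‖v±‖) seed W and H, and a few multiplicative passes against the
clipped rank-p approximation refine them.  The initialisation is
deterministic.

Refinement minimises the Frobenius objective by HALS (hierarchical
alternating least squares): each component's column/row is exactly
minimised in turn under nonnegativity, so the objective is monotonically
non-increasing and converges linearly.  Plain multiplicative updates were
rejected after measurement: their sublinear tail leaves a visible
reconstruction error on exactly low-rank inputs even after tens of
thousands of iterations, which breaks the exact-recovery contract of the
initialisation.  Initial factors are floored at 1e-9 of their maximum
because exact zeros are fixed points of both update families.  Defaults:
tol 1e-5 (relative objective change), max 500 iterations;
non-convergence is logged, not fatal.

Model order: k = 3…15 scanned; among ranks with mean absolute error
below 0.05 (X lives in (0,1), so this is an absolute mean deviation), the
smallest redundancy `c` wins; exact ties (1e-12) go to the smallest k.
If no rank passes the error bar, the smallest-error factorization is
returned flagged.  Correlation means Pearson throughout; constant
columns/rows contribute 0 to `c`.

## MEMD

Directions: a scrambled Halton sequence mapped through the inverse normal
CDF and normalised — quasi-uniform on the sphere, deterministic per seed;
64 directions by default (≥ 2k for every k the NMF stage can select).
For k = 1 the "sphere" is {+1, −1}.

Sifting: project the multivariate remainder on each direction, take the
projection's strict local maxima/minima, interpolate the *multivariate*
signal at those times with natural cubic splines (mirroring two extrema
about each end), and subtract the direction-averaged envelope mean.
Stopping uses the Rilling criterion on `‖m(t)‖/a(t)` with
θ1 = 0.075, θ2 = 0.75, α = 0.075 — the defaults of the reference MEMD
implementation — and a hard cap of 100 sift iterations.  Tighter
thresholds (0.05/0.5/0.05) were measured to over-sift white noise,
compressing the filter-bank period ratio below the dyadic range the
analysis relies on.  Decomposition ends when every projection has fewer
than three extrema or the remainder is below 1e-12 of the input range;
the remainder is the residue.  Completeness (`Σ IMFs + residue = input`)
holds to floating-point accuracy by construction.

A single dimension of a multivariate IMF is mode-aligned rather than a
strict univariate IMF: its extrema and zero-crossing counts agree only to
within a few percent, and the property test uses a 15% relative
tolerance; likewise later-IMF-is-slower can show isolated inversions
(mode mixing), which are tolerated, not failures.

## Hilbert spectral analysis

Analytic signal via the frequency-domain transform.  Instantaneous
frequency is the central difference of the unwrapped phase in cycles/day.
The first and last 4% of samples are masked: the narrower 2% mask left
measurable boundary ripple in the instantaneous frequency of a test
chirp, and mirror-extension repairs the chirp but contaminates exactly
periodic signals, so widening the mask is the only change that preserves
both closed forms.  Negative instantaneous frequencies (unwrapping
glitches) are masked, not clamped, so the marginal spectrum's energy
bookkeeping stays exact on the valid set: per IMF, each dimension's
a²(t)/k is accumulated into the log-spaced bin (48/decade, anchored so
1 cycle/day is a bin centre) containing f(t), spanning two cycles per
record up to the 1440 cycles/day Nyquist of the 30 s epoch series.
Out-of-range frequencies are clipped into the edge bins rather than
dropped.  Peak frequency = geometric centre of the argmax bin, ties to
the lower frequency (logged).  The circadian IMF is the in-band
(period 0.8–1.25 days) IMF with the largest total marginal power; no
smoothing is applied before peak-picking.  Cycle length = 1/frequency is
used for reporting.

## Contributions and Gini

`E_ij` averages a² over the valid (edge-masked) samples, consistent with
the spectral stage.  The residue is carried as an extra row using its raw
mean square (it is not oscillatory, so a Hilbert amplitude would be
meaningless); an exactly zero residue gets a zero relative-power row and
NaN band percentages with a warning rather than an error.  The Gini index
follows the sorted-rank formula `G = 1 − 2 Σ (x_i/‖x‖₁)((N−i+½)/N)`;
it is scale- and permutation-invariant, 0 for constant vectors and
1 − 1/N for one-hot vectors.  Heterogeneity applies it to the channel
entries of each band slice of `C_i = Σ_j R_ij W_j`; an empty band slice
yields NaN with a warning.

## Seizure distances, DTW

Onset epochs are `floor(onset_s/30)` (0-based); two seizures sharing one
epoch produce a zero distance and a warning.  `lag = 1` reproduces the
pre-ictal variant (epoch before onset).  DTW uses the symmetric step
pattern (diagonal/horizontal/vertical), boundary anchoring, no warping
window, Euclidean local cost; the dissimilarity is the mean local cost
along the optimal path, with diagonal-preferred tie-breaking in the
backtrack (ties are measure-zero for continuous features, but the
convention keeps the oracle comparison exact).  Deriving the evolution
matrices themselves from raw ictal EEG is out of scope: they are inputs,
or synthetic.

## Regression and permutation inference

Upper-triangle vectorisation; response and every predictor standardised
(population SD); constant predictors dropped with a warning; a constant
response marks the dataset degenerate (reported non-significant).
Subjects with fewer than six seizures are refused.

The nonnegative LASSO minimises `1/(2N)‖y − Zw‖² + λΣw, w ≥ 0` on the
grid λ = 10^−3 … 10^2 in steps of 10^0.05 (101 values).  It is solved
*exactly* by a piecewise-linear homotopy in λ (active-set path with
entering/leaving events), evaluated at all grid points at once; the suite
verifies coefficient agreement with coordinate-descent reference
solutions to ~1e-8 across random problems.  The exact path is what makes
hundreds of CV × permutation refits affordable on one CPU.
Cross-validation: pairs shuffled once per fit with the run seed, split
into 10 contiguous folds; λ minimising mean held-out MSE, ties to the
largest λ (sparsest model).  The non-independence of seizure pairs
sharing a seizure is inherited from the analysis design and documented
rather than corrected.  OLS refit (intercept included) provides
standardised-scale coefficients, t-based 95% CIs and the adjusted R²; an
empty selection reports adjusted R² = 0 with a flag and no OLS stage.

Permutation tests (500 iterations by default): (i) random onset epochs
drawn uniformly over {lag…T−1} (discrete, since predictors are
epoch-indexed; duplicates allowed), all distance predictors including the
temporal one rebuilt, response unchanged; (ii) seizure order permuted by
relabelling the dissimilarity matrix, timing and predictors unchanged
(identity permutations allowed).  p = plain fraction of permuted adjusted
R² values strictly larger than the observed one, as a percentage rule; a
flag switches to the (b+1)/(n+1) correction.  Sorted versus unsorted
random onset draws yield identical pair sets, so the distinction has no
functional consequence.  Scaled-down calibration (desk scale): 100 null
replicates at 200 permutations each are used to check the 5%-level
rejection rate and approximate uniformity of p-values.

At the CV-selected penalty the LASSO usually keeps, besides the
substantive predictors, a few coefficients one to two orders of magnitude
smaller; parameter-recovery checks therefore look at the *dominant*
coefficients (at least 10% of the largest), treating the trailing ones as
shrinkage artifacts rather than selections.  Planted rhythms can spread
over adjacent IMFs (mode leakage), so recovery is judged per planted
period — some dominant IMF matches it — rather than per selected IMF.

One property of the null deserves note: under the global null the CV
LASSO frequently selects nothing, so the adjusted R² statistic has a
large point mass at exactly 0.  The plain strictly-larger p-value is
still exactly calibrated at conventional levels (the atom sits at the
bottom of the distribution), but it cannot be uniform; the uniformity
check therefore uses tie-randomized p-values, `(b + U·(e + 1))/(n + 1)`
with `b` the count of strictly larger and `e` the count of tied permuted
values, which are exactly uniform for an exchangeable test.  The reported
p-value keeps the plain rule.  The observed statistic's CV folds are
drawn from a random stream separate from the permutation draws.

## Orchestration

One master seed derives per-stage seeds via `SeedSequence([master,
offset])`, so partial reruns reproduce the full run.  Run directories
carry per-stage artifacts (HDF5 matrices, delimited tables, a JSON
report) and a manifest with a parameter hash per stage; resuming with a
changed configuration aborts loudly.  The test suite's pipeline
configuration caps the NMF scan at k ≤ 8 — with two planted modulators
the admissible ranks sit well below that — and the acceptance script uses
three fixture seeds for the detection-rate report while the suite runs
five.

## Known limitations

- EMD/MEMD have no convergence theory; mode mixing can split or merge
  planted rhythms, and IMF counts are data- and parameter-dependent.
- Multidien rhythms longer than ~a third of the record cannot be
  resolved as IMF peaks (two-cycle lower bound on the frequency axis).
- The LASSO CV treats seizure pairs as exchangeable observations; pairs
  sharing a seizure are dependent, so CV error is optimistic.
- The permutation tests permute onsets/order only; they do not address
  autocorrelation of the dissimilarity residuals.
- Synthetic envelopes are log-sinusoidal; none of the tests probe
  robustness to non-sinusoidal rhythm shapes (e.g. square-ish sleep/wake
  alternation), although EMD itself does not assume sinusoidality.
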