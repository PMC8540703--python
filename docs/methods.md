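# Methods

This note documents the models, algorithms and defaults implemented in
`drowsyindex`, the choices made where the procedure left room, and what
the synthetic-data tests do and do not demonstrate.

## Signal model and feature extraction

Input fragments are six-channel EEG (F3, F4, C3, C4, O1, O2; 10/20
system) sampled at 200 Hz, 600 s long, with wakefulness (W) in the first
300 s and stage-1 sleep (S1) in the second. Preprocessing removes the
per-channel mean and applies a 6th-order Butterworth band-pass at
1–40 Hz. Filtering is zero-phase (forward–backward, `sosfiltfilt`), so
the effective attenuation order doubles; we accept that in exchange for
exact epoch alignment across channels, since the transition-window logic
downstream is sensitive to timing.

Each stage segment is epoched **independently** with 5 s epochs at 50 %
overlap: 119 epochs per 300 s segment, 238 per fragment, and no epoch
ever mixes W and S1 samples. (Epoching the full 600 s as one segment
would yield 239 epochs, one of them straddling the boundary with an
ambiguous label.)

Per epoch and channel, the power spectral density is estimated by
Welch's method with 2 s Hann segments at 50 % overlap — four averaged
segments per epoch and 0.5 Hz resolution, the minimum that resolves the
0.5 Hz lower delta edge. Band powers are integrals of the
piecewise-linear PSD over half-open intervals [low, high): δ 0.5–4,
θ 4–8, α 8–12, β 12–30, γ 30–40, σ 12–14, α1 8–10, α2 10–12 Hz. The
gamma band is capped at 40 Hz because nothing above the filter cut-off
survives. End-point interpolation makes band powers exactly additive
over contiguous partitions (α1 + α2 = α to rounding), which the tests
exploit. Units are µV²; every downstream index is a ratio, so absolute
calibration is irrelevant.

Welch segment length, window type and the zero-phase choice are this
package's declared defaults (all configurable via `FeatureConfig`), not
values recovered from any external description.

## The index family and its two published members

A multichannel index is `I(e) = Σ C_ij F_ij(e) / Σ K_ij F_ij(e)` with
non-negative 8×6 coefficient matrices; 48 + 48 coefficients in total.
Because band powers are non-negative, the denominator can only vanish on
degenerate all-zero epochs; the default policy floors it at
1e-12 × median denominator with a warning, and a strict mode raises.

`index1_spec()` returns the 13-coefficient solution
(αF3 + 4αO2 + 9α1F3 + 3α1C3 + 9α1C4 + α1O2 + 4α2O1 + 8α2O2) /
(δF3 + 3δF4 + 3δC3 + 2δC4 + 9δO2); `index2_spec()` returns
(δF3 + δF4 + δO2) / (αC3 + α2O2). Both are frozen constants with tests
pinning their structure.

Post-processing: a sequential 10 % clamp confines each epoch's value to
[0.9, 1.1] × the **previous clamped output**. The published recurrence
does not say whether the reference is the raw or already-clamped
previous value; we compare against the clamped one because the raw
reference lets a single spike re-enter the series rescaled (one clamped
epoch, then an unconstrained jump back). The raw-reference variant is
available via `reference="raw"`. Per-subject min-max normalization maps
each series to [0, 1]; a constant series (undefined under min-max) maps
to all-0.5 with a warning.

The seven single-channel baselines (θ/α, β/α, (θ+α)/β, θ/β,
(θ+α)/(α+β), γ/δ, (γ+β)/(δ+α)) are evaluated on all six channels — 42
series per subject. The two gamma-based indices historically derive from
wavelet sub-band energies rather than Welch powers; we implement a
5-level Daubechies-4 periodized DWT at 200 Hz with the dyadic mapping
A5≈δ (0–3.1 Hz), D5≈θ, D4≈α, D3≈β, D2≈γ (25–50 Hz). The exact family
and levels of the original wavelet formulation are not recoverable from
our sources; this mapping is a documented approximation. Epochs are
zero-padded to a multiple of 2⁵ so the periodized transform stays
orthogonal and sub-band energies sum exactly to signal energy.

## The two-objective step fitness

For one candidate index on one fragment (after the 10 % clamp — see
below):

1. **Transition-window search.** Window starts j ∈ [30, n−60] are
   scanned; for each j, `avg_left` is the mean of epochs before j and
   `avg_right` the mean after j + 30. The j maximizing
   |avg_right − avg_left| wins, last-wins on ties. The printed pseudocode
   this reproduces contains two defects: the running maximum is reset
   inside the loop (making the comparison vacuous, so the last window
   always wins) and one line is garbled. We implement the evident intent
   — a true arg-max — and keep the literal printed behaviour behind
   `compat_printed_scan=True`.
2. **Moved zero.** The reference point is 1 % below the series minimum:
   `min − 0.01·|min|`, and −0.01 when the minimum is 0. The unmodified
   formula `min − 0.01·min` rises *above* the minimum for negative
   series; the literal version sits behind `compat_printed_moved_zero`.
3. **O1.** The relative separation is
   `|right − left| / min(left − z, right − z)` (z the moved zero; the
   denominator can approach 0 when one plateau sits at the series
   minimum, so it is floored at 1e-12). The graded penalty is 1/x for
   x ≥ 5, 10/x on [1, 5), 100/x on [0.5, 1) and a flat 1000 below 0.5 —
   monotone non-increasing with 10× tier jumps.
4. **O2.** Adjacent-epoch relative changes
   `|(xₑ − xₑ₋₁)/(xₑ₋₁ − z)|` outside the window located in step 1
   contribute 1000 / 100 / 10 / 1 for changes ≥ 5 / 1 / 0.5 / 0.25 and
   nothing below.

Across fragments, O1 and O2 are arithmetic means of the per-fragment
scores. The clamp is applied before scoring by default (it was
introduced as part of the optimization context, to damp oscillations and
aid convergence); `clamp=False` scores raw series. Whether the same
located window feeds both objectives is implied by the shared variable
in the printed evaluation loop; we share it.

## NSGA-II search and simplification

Chromosomes are 96 real genes in [0, 10] — C in the first half, K in the
second, band-major then channel. The search is standard elitist NSGA-II:
fast non-dominated sorting, crowding distance, binary tournament on
(rank, crowding), simulated-binary crossover (pair probability 0.9,
distribution index 15) and polynomial mutation (gene probability 1/96,
index 20). The crossover/mutation settings are conventional real-coded
defaults, declared not recovered; all are in `SearchConfig`. Runs are
bit-reproducible from the seed. The full-scale profile is population 100
over 107 generations on 16 training fragments; `SearchConfig.reduced()`
(population 40, 40 generations) is the scale used by this package's own
test runs, chosen so a single search completes in a few seconds on one
core while still showing band-recovery behaviour.

Simplification mirrors the published workflow: count "large" genes
(≥ 5.0, the midpoint of the gene range — threshold configurable since no
value was stated) per band across the final front; freeze the losing
bands' genes at zero and re-search the halved space; floor all genes and
select the candidate with the most zero coefficients, ties broken by O1
then O2 (the original tri-criterion choice has no stated weighting —
lexicographic was chosen for determinism). Candidates whose floored
denominator vanishes are discarded. The constrained brute force for
binary indices enumerates all 0/1 coefficient assignments with ≥ 1 term
per side and ≤ `max_addends` total, over a caller-restricted position
subset: the unrestricted 96-position search at ≤ 5 addends is ~10⁸
evaluations, so the default workflow restricts to the bands surviving
frequency analysis.

## Synthetic data: what it emulates and what it does not

Each band is realized as unit-RMS band-limited Gaussian noise (4th-order
Butterworth-filtered white noise) scaled by a stage-dependent amplitude,
summed with a stationary pink (1/f) floor of 1 µV RMS; a sinusoid mode
substitutes centre-frequency tones for analytic tests. The stage change
is a linear amplitude cross-fade over 60 s centred on the boundary,
matching the expectation that the physiological transition spans several
epochs. Default W amplitudes (µV RMS): δ 4, θ 3, α 4, β 4, γ 1.5; the
W→S1 contrast is δ ×1.8, α ×1.8, θ ×1.4, β ×0.7, γ ×1 — the directions
the drowsiness literature reports. Alpha carries a ×1.5 occipital gain
and delta a ×1.3 frontal gain so that discovered indices can plausibly
localize the way the published ones do; this is a modelling choice of
the generator, not a measured property. Per-subject scale jitter is
log-normal (σ = 0.2), and cohorts split 16:12 train/test by proportion.

One consequence deserves emphasis: because the default contrast scales
delta and alpha by the same factor, any pure δ/α ratio — including
Index2 — cancels most of the stage change, and its residual separation
comes only from the stage-independent pink floor. Tests of contrast
propagation through the published indices therefore assert a modest
property (stage means differ at p < 0.05 on most seeds, direction not
fixed), and the power/monotonicity tests drive a one-sided δ-only
contrast, which the ratio indices see at full strength. Passing tests on
this generator show that the pipeline's plumbing and statistics behave
correctly — not that any index detects drowsiness in real recordings;
the generator has no artifacts, spindles, 1/f dynamics beyond the pink
floor, or inter-channel correlation.

## Evaluation protocol

Per subject and index, a two-sided Wilcoxon signed-rank test compares
the W and S1 halves, pairing the k-th W epoch with the k-th S1 epoch
(the pairing convention is ours; nothing in the protocol fixes it).
Zero differences are dropped (Wilcoxon's rule; Pratt handling by flag).
For ≤ 25 non-zero pairs the p-value comes from the exact conditional
null distribution computed by convolution over (possibly tied, hence
doubled) ranks — tie-aware, unlike the textbook exact tables — and from
the continuity-corrected normal approximation above that. Significance
uses α₀ = 0.01 with Bonferroni correction over (subjects × indices)
tests; 144 tests give 6.9×10⁻⁵. For single-channel baselines the
reported channel is the one minimizing the across-subject mean p-value,
ties broken by fixed channel order.

Classification is leave-one-subject-out: per held-out subject, a model
trained on all others predicts each of its 238 epochs; accuracy is the
fraction correct and precision is TP/(TP+FP) with S1 positive. A subject
for whom no epoch is predicted S1 gets *undefined* precision — reported
as missing and excluded from averages with an exclusion count, never
coerced to zero. The reference classifier is gradient-boosted trees at
learning rate 0.3, gamma 0, max depth 6; the comparison panel (naive
Bayes, kNN, logistic regression, decision tree, random forest, SVM) runs
at scikit-learn defaults. Classifiers consume the per-subject
min-max-normalized index values: one feature for a multichannel index,
six (one per channel) for each single-channel baseline.

## Numerical and degenerate-input choices

* Window-scan means use prefix sums (O(n) per scan); tests verify the
  selected window against a literal exhaustive scan.
* Tie-breaks: window arg-max keeps the last maximal start (fidelity to
  the printed ≥ comparison); best-channel and final-solution selection
  break ties by fixed ordering for determinism.
* Empty series, inverted bands, bands beyond Nyquist, epochs longer than
  a stage segment, chromosomes of wrong length, single-class subjects
  and sub-minimal series lengths all raise errors rather than
  degrading silently.
* All stochastic components (generator, search, classifiers) take
  explicit seeds and are reproducible bit-for-bit.

## Known limitations

* The NSGA-II implementation is single-threaded and unoptimized beyond
  vectorized objective evaluation; full-scale runs (100 × 107 on 16
  fragments) take minutes, not seconds.
* The wavelet band mapping is an approximation with dyadic edges that do
  not coincide with the Welch band edges (e.g. D4 spans 6.25–12.5 Hz
  versus α's 8–12 Hz).
* The EDF/WFDB readers target the plain 16-bit variants of those
  formats only.
* Timing comparisons between indices exist nowhere in this package; they
  are hardware-dependent and out of scope.
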