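# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `audlearn`.  It is written for a reader who wants
to judge what the package's computations — and its passing tests — do and do
not establish.

## Behavioral metrics

Sensitivity is d′ = z(hit) − z(FA), z the inverse cumulative standard
normal.  Rates are clipped to [1/(2N), 1 − 1/(2N)] per trial class before
the z-transform; this standard log-linear-style correction keeps d′ finite
for perfect sessions and does not move interior rates.  Learning curves use
consecutive non-overlapping bins (default 20 trials) in trial order;
per-stage d′ summaries use only the final third of a stage's trials, where
performance has stabilized.

Psychometric curves are 4-parameter logistics
p(x) = floor + (ceiling − floor)/(1 + e^{−k(x − x₀)}) fitted by least
squares on lick proportions, with x = log2(frequency) — the octave metric
used throughout — and the decision boundary reported as 2^{x₀} kHz.  Flat
or non-converging data return a result flagged `degenerate` rather than
raising.  Detection time is the center of the first 50-ms bin whose hit vs.
correct-rejection per-trial lick counts differ at p < α (Welch two-sample
t-test, α = 0.001 by default).  The first crossing is used, per-bin (not
cumulative) counts are tested, and no multiple-bin correction is applied —
these are deliberate protocol choices, so detection times should be read as
operational statistics, not calibrated p-values.

## Tuning analyses

PSTHs use 1-ms bins (spike times are treated at millisecond resolution).
The response window is the 100-ms stretch after stimulus onset maximizing
the summed PSTH, scanned at every bin edge (1-ms steps; the step size is a
convention — coarser steps change windows by at most a few ms); ties go to
the earliest window and are flagged.  Latency is the peak time of a
5-ms-smoothed PSTH (smoothing avoids single-spike peaks).  Responsiveness
and FRA significance are two-sample t-tests of evoked-window counts against
matched 100-ms pre-stimulus counts; FRA cells use the Bonferroni-corrected
level 0.05/(n_freq × n_level) (72 combinations on the default grid).  BF is
the argmax over frequencies of the level-averaged rate, ties to the lower
frequency.  Signal correlation is the Pearson r between two FRA matrices
over all combinations; "neighboring" pairs are approximated by a shared
synthetic recording-site label, standing in for anatomical distance.

## The generative basis-function model

The rate matrix (N neurons × 18 frequencies of trial-averaged window
counts) is decomposed by SVD without centering; the model keeps the K
largest singular directions.  Basis vectors are sign-oriented so the
largest-magnitude entry is positive.  The generative basis applies a
centered 3-point moving average with edge replication to each SVD frequency
vector; coefficients are computed against the **unsmoothed** (orthonormal)
basis — so reconstruction of an observed neuron with its own coefficients
and unsmoothed basis is exactly the rank-K SVD projection — while curve
assembly for generated neurons uses the smoothed basis.  (Fitting
coefficients against the smoothed basis instead is available via
`coefficients_from_smoothed=True`; the ambiguity is inherent to describing
smoothing and projection in either order.)

Sampling draws each coefficient independently from its empirical per-component
distribution: bootstrap resampling of the observed values by default (the
zero-bin-width limit of histogram sampling), or Freedman–Diaconis-binned
histograms with uniform within-bin jitter (`sampling="binned"`).  The
factorization is the model's stated approximation: generated ensembles have
cross-component coefficient correlations near zero even when observed
coefficients were correlated, and the test suite checks exactly that
property rather than pretending the joint distribution is preserved.
Negative assembled curves are floored at 0 and the flooring count is kept.

Model order is selected by trial-split cross-validation: 25 random 80/20
trial splits, model fitted on train-trial means, mean squared error scored
against test-trial means per candidate K; K* is the argmin (ties to the
smaller K).  On planted six-component ensembles at protocol scale
(100 neurons × 18 frequencies × 20 Poisson trials) the test error falls
until K = 6 and then plateaus; the minimum is broad, so K* values a little
above 6 are expected behavior, and K = 6 is the package default.  Trials
default to 20 per condition so a 16/4 decoder split is always available.

## Fisher information and decoding

For Poisson spiking, the per-neuron Fisher information about frequency is
I_i(f) = r_i′(f)²/r_i(f) in octave⁻² (rates in counts per 100-ms window,
f on the log2 axis); totals are exact sums over neurons, assuming
independence — noise correlations are deliberately absent from the model.
Derivatives are central differences on the octave grid, one-sided at the
ends.  Rates are floored at `floor_eps` (default 10⁻⁶) before division.
Note a genuine pathology: model-sampled curves floored at exactly zero have
boundaries where the derivative is finite but the rate is eps, making
r′²/r diverge; for model-derived profiles the pipeline therefore uses a
physiological floor of 0.05 counts/window.  The closed-form checks
(r = e^x ⇒ I = e^x; I = 0 at tuning peaks) use strictly positive curves and
are unaffected.

The decoder is a linear soft-margin SVM (C = 1; the slack cost is a
convention and is configurable — in the near-separable regimes probed here
the solution is insensitive to it) on per-neuron standardized counts
(train-set statistics only).  Each iteration draws fresh Poisson trials
(16 train + 4 test per class); iterations stop at 500 or when the running
mean error moves < 10⁻³ over 50 iterations (`converge_tol=0` forces the
full budget).  The error-to-sensitivity conversion is the equal-prior,
symmetric-criterion d′ = 2 z(1 − error), with the error clipped into
[1/(2M), 1 − 1/(2M)], M the total test-trial count — so a zero measured
error maps to a finite, M-dependent ceiling.  Pooled (not per-class) mean
test error is used.

**Validity regime of the FI–d′ identity.**  d′ = Δf √(total FI) holds for a
(near-)optimal readout of a large, independent population at small Δf.  A
classifier trained on 16 trials per class with p = 200 standardized features
suffers weight-estimation shrinkage of roughly D²/√(D² + p/8) (D the
population d′): at D ≈ 4 the trained decoder reaches only ~60% of the bound,
while for D ≳ 10 the error becomes unmeasurable within 4000 test trials and
the clipping ceiling binds.  The consistency study therefore uses a strongly
driven, band-focused Gaussian ensemble (BFs uniform within ±0.4 octave of
the probe, σ = 0.18 octave, peak 10 counts/window ≈ 100 Hz evoked,
spontaneous 0.1) putting D ≈ 8 — the window where the identity is actually
observable under the 16-trial protocol; measured SVM d′ lands at ~80% of
the FI prediction.  Passing this check shows the decoder approaches the
information-theoretic bound in its validity regime; it does not show that
16-trial decoders are near-optimal for weakly driven ensembles (they are
not, and cannot be).

**Flank-enhancement construction.**  The matched naive/expert pair shares an
identical 140-neuron background (BF uniform over the grid span, σ = 0.4
octave, peak 6, spontaneous 0.2), so in-band information agrees by
construction.  Naive extras (60) sit > 1.3 octave from the training-band
center, contributing negligibly near it; expert extras (60) sit at the band
edges (7.1 and 10 kHz) with a steep slope facing away from the band
(σ = 0.25) and a shallow slope into it (σ = 1.0).  Resulting totals: flank
FI (0.25 octave outside the edges) ≈ 2.3× naive, in-band FI within ~2%.
Decoding one-grid-step pairs (0.2198 octave) shows the same signature —
experts ahead at intermediate population sizes on the flank pair, matched
in-band, both saturating at large N.

## Vocalization analyses

Responses are organized per (neuron, call variant, syllable, trial) as
100-ms window counts; 12 syllables and 16 repetitions per variant are the
protocol defaults, with variants indexed by a speeding factor s ∈ (0, 1]
(1 = the original call).  The time-warp that builds a variant multiplies
local playback speed by a linear ramp from s at syllable onset to 2 − s at
offset (a 0.6 factor plays the onset 0.4 slower and the offset 0.4 faster);
since the ramp integrates to 1, syllable duration is preserved, and the
warped waveform is cubic-interpolated at the remapped positions.

Lifetime sparseness follows the normalized formula above on per-syllable
trial-mean rates of the original call; all-zero neurons are undefined and
flagged.  Population sparseness is 100 minus the percentage of neurons with
a significant per-syllable response (same t-test machinery as the FRA).
Similarity matrices correlate per-syllable rate vectors by default (1-ms
PSTH mode is available when spike times were generated); zero-variance
neurons are excluded from a pair's mean with the count reported.  Fano
factors (unbiased variance / mean) are reported per condition and as
across-condition means, since either summary is defensible.

Cumulative-syllable decoding uses the same SVM conventions as the tone task
on concatenated per-neuron, per-syllable counts for syllables 1..k, scored
by leave-one-out (15 train / 1 test per class) over the 16 fixed trials,
1000 iterations by default.  A property of this protocol worth knowing:
leave-one-out on a *fixed* null sample is pessimistically biased (~0.35
rather than 0.5 at these dimensions), because excluding a trial shifts its
class's training mean away from it.  The bias is shared by both groups in
any comparison, and discriminable variants sit far above it; chance-level
tests assert "no spurious signal" rather than exact 0.5.

## Synthetic generators: what they emulate, and what not

Tuning curves are two-sided (independently drawn widths below/above BF)
Gaussian bumps on the octave axis with an optional second mode (20% of
neurons) — emulating the asymmetric, occasionally bimodal shapes of real
frequency tuning; BF mixtures place naive ensembles uniformly and shift
expert mass toward the 7.1–10 kHz training band.  Counts are independent
Poisson per trial; level gains scale evoked rates monotonically across the
four sound levels.  Behavior logs implement the staged curriculum
(49 → 26 → 14 → 6 %/octave separations; 70% target probability; 6% catch
trials when enabled) with Bernoulli lick decisions whose stage
probabilities are calibrated to land stage d′ near the reported group means
(≈2.4, 1.9, 1.4).  Vocal response sets control sparseness through the
fraction of responsive (neuron, syllable) pairs and across-variant
decorrelation through ρ(s) = e^{−λ(1−s)} on underlying mean-rate vectors.

Group defaults are calibration choices, not measured values: naive
(responsive fraction 0.5, evoked 1.5 counts/window, spontaneous 0.3,
λ = 1.5) and expert (0.25, 1.5, 0.2, λ = 6) land lifetime sparseness near
46% vs. 63% with the expert code less correlated across variants — the
qualitative signature of perceptual learning on natural-sound
representations, at realistic low cortical rates.  The expert's slightly
lower spontaneous rate mirrors the weaker population responses seen after
learning.

None of the generators include inter-neuron noise correlations, non-Poisson
count dispersion, adaptation within or across trials, or acoustic realism
of the calls (no spectrograms are synthesized; `warp_syllable` operates on
arbitrary waveforms).  Tests passing on these ensembles validate the
analysis code and its stated invariants — they do not certify behavior on
recordings whose statistics violate Poisson independence.

## Numerical conventions and degenerate inputs

Ties: earliest response window; lowest-frequency BF; smaller K in model
selection.  Zero-variance inputs: responsiveness returns p = 1 on identical
samples; signal correlation and Fano factor return NaN (flagged undefined);
similarity excludes the neuron from that pair.  Empty ensembles, empty
stage lists, single-trial conditions, K above the matrix rank, negative
rates and out-of-range speeding factors all raise `ValueError` with the
offending quantity named.  All stochastic functions take integer seeds and
use independent `numpy` generators; pipeline stages derive child seeds from
one config seed via `SeedSequence`, making full runs byte-identical.

Study problem sizes (100–200 observed neurons, 200–500 model neurons,
20 trials per condition, 10–20 study seeds, 30–500 decoder iterations) were
chosen to keep each validation study's Monte-Carlo error well inside its
decision margin; all complete in seconds to a few minutes on one CPU.

## Known limitations

* The FI–d′ consistency holds only in the documented strong-signal regime;
  the package reports the decoder's shortfall honestly elsewhere.
* Detection-time p-values are uncorrected across bins by design.
* The factorized coefficient model discards cross-component structure; the
  generated ensembles match marginals, not joints.
* Leave-one-out decoding is pessimistic at chance (see above).
* The level dimension of the synthetic FRA uses a fixed monotone gain
  profile; non-monotone level tuning (e.g., intensity-tuned cells) is not
  emulated.
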