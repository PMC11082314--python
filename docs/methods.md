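# Methods

This note records the models the package implements, the assumptions
behind the synthetic benchmark, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Recordings are multichannel surface-EMG (E = 8 channels per hand) with
gesture events annotated by three times: movement onset, posture
recognition, and release (start of the return-to-rest movement).
Preprocessing is: resample to 2,048 Hz (polyphase), 50 Hz notch with
5 Hz bandwidth, 30–500 Hz band-pass (4th-order Butterworth), both
applied forward–backward so the net filter has zero phase, then
per-channel division by the maximum absolute amplitude observed during
maximum-voluntary-contraction (MVC) calibration. The order
resample → notch → band-pass → normalize is fixed; since all filters
are linear the only consequential choice is that normalization uses raw
MVC maxima, which is how the calibration is defined.

Epochs are anchored at posture recognition: the phasic window is the
500 ms before recognition (one per gesture); tonic windows are 500 ms
long at a 256 ms stride starting 500 ms after recognition. The default
policy keeps five tonic windows per gesture (starts at +500 … +1,524 ms,
the last window ending at +2,024 ms), which makes the tonic:phasic
epoch count exactly 5:1; a strict-containment policy (all windows end by
+2,000 ms, four per gesture) is available via `policy="strict"`. At
2,048 Hz a 500 ms window is 1,024 samples; pipelines that want a fixed
512-sample geometry can pass `epoch_samples=512`, which keeps the first
512 samples of each window. Both behaviors exist because the two
conventions (500 ms at 2,048 Hz vs an 8 × 512 array) cannot hold
simultaneously and neither is privileged here.

Quality screening is deterministic and flag-based (`flag_artifacts`):
repeated sharp amplitude steps (≥ `min_events` first differences above
`step_threshold`·σ per channel), saturation (>1% of samples pinned at
the channel maximum), and flatlines. Flagged recordings are only
dropped when explicitly requested — never silently.

## Classification pipelines

**Time-domain features.** Eleven features per channel (see
`features.py` for the exact formulas): MAV, RMS, MAA, waveform length,
zero crossings, slope-sign changes, Wilson amplitude, maximum fractal
length, kurtosis, Hurst exponent and sample entropy. The sign-based
features are implemented literally as signed sums with sgn(0) = 0,
which means ZC/SSC/WA can be negative on monotone stretches; the Wilson
amplitude thresholds on the per-epoch standard deviation and the
sample-entropy tolerance is σ/10, making both gain-invariant. Sample
entropy uses embedding m = 2 with template-extension length 3,
Chebyshev distance, self-matches excluded, and the N−m-template pairing
in which every m-template has an extension. The Hurst exponent is the
least-squares slope of log(R/S) over a dyadic window ladder from 8 to
N/2; R/S estimation on short windows has a known upward bias for white
noise, so the estimator is validated in distribution (mean over seeds
within 0.5 ± 0.1 at N = 1,024), not pointwise. No feature selection or
decorrelation is applied. The classifier is a one-vs-rest L2 logistic
regression (liblinear).

The logistic wrapper uses a per-sample penalty convention
(C = reg_c / n_train): duplicating every training point leaves the
decision function unchanged, which makes cross-validation folds of
different sizes comparable. The default budget reg_c = 500 recovers
the conventional C ≈ 1 at the training sizes a guided session produces.

**Covariance / tangent space.** Per-epoch covariances use the OAS
shrinkage estimator on row-centered epochs — the convex combination
(1−ρ)·S + ρ·(tr S/d)·I is positive definite whenever tr S > 0, which
keeps downstream matrix logarithms defined even for short windows.
Tangent projection at a reference point R is the whitened log
Φ(Σ) = logm(R^{-1/2} Σ R^{-1/2}), vectorized over the upper triangle
with √2 off-diagonal weights, so ‖Φ(Σ)‖₂ equals the affine-invariant
distance d(R, Σ) — the property the test suite asserts against an
eigenvalue oracle. R is the Fréchet (Karcher) mean of the *training*
covariances of each fold, never of test data. The Karcher flow starts
at the arithmetic mean, uses step 1.0 with step-halving whenever the
gradient norm increases (augmented covariances can be ill-conditioned
enough to make the fixed-step flow oscillate), tolerance 1e-8, at most
50 iterations; non-convergence raises an error carrying the last
iterate, which the estimator surface downgrades to a warning.

**xDAWN.** Filters per class solve the symmetric generalized
eigenproblem (P⁽ᵏ⁾P⁽ᵏ⁾ᵀ, D) with D = Σᵢ XᵢXᵢᵀ; the top F = 4
eigenvectors per class are kept (F is not dictated by anything in the
analysis; 4 keeps the augmented covariance 2KF = 32 well conditioned
for 500 ms epochs, and it is configurable). A singular D gets a
trace-scaled jitter of 1e-10·tr(D)/E, logged. Note that with
non-phase-locked EMG the class prototype is a finite-sample residual
rather than a deterministic evoked shape; its principal subspace still
aligns with the class's spatial pattern, which is exactly what the
planted-pattern recovery test checks (|cos| > 0.95 at SNR ≥ 5). The
augmented epoch stacks the filtered prototypes (identical rows for
every epoch) above the filtered signal; whether those rows are centered
before covariance estimation is controlled by `Covariances(center=...)`
(default: centered, consistent with the zero-mean covariance model).

**CNN.** The architecture is fixed (see README); choices the design
leaves open are set as: spatial dropout 0.25, batch size 32, categorical
cross-entropy, Adam β₁ = 0.9, β₂ = 0.999, ε = 1e-8, max 200 epochs with
early stopping on validation loss (patience 20) when a validation
fraction is configured. Temporal convolutions use "same" padding
(7 left / 8 right for the 16-tap kernel); the spatial convolution is
"valid" and collapses the electrode axis, as an (E × 1) kernel must to
act as a full spatial filter. Glorot-uniform bounds use
fan_in/fan_out with convolutional fans counting the receptive field.
The network, backward pass and optimizer are written directly on numpy
arrays in float32; epochs must have S divisible by 16 (two ×4 mean
poolings). Training is deterministic given the seed. Test and
acceptance fits use small inputs (S = 128–256, ≤ 200 epochs/class, ≤ 6
training epochs) — ample for the sanity properties being asserted,
and sized so the whole battery runs comfortably on one desktop core.

## Cross-validation and statistics

Intra-subject: stratified 5-fold within each subject; per-subject mean
over folds, then an unweighted mean over subjects. Inter-session:
leave-one-session-out over all subjects pooled. Inter-subject:
leave-one-subject-out. Every fitted component (scaler, xDAWN filters,
Fréchet reference, classifier, CNN) is cloned and refit inside each
fold. Folds whose training split lacks a class are skipped with a
warning. Multiclass ROC/AUC is one-vs-rest, macro-averaged.

Pipeline comparison uses per-row midranks (rank 1 best) averaged per
pipeline and the Nemenyi critical distance with the studentized-range
quantile (q₀.₀₅(4) = 2.569); a Friedman omnibus p-value is computed
alongside for information but does not gate the Nemenyi comparison.
Which accuracies form the rank-table rows (per-subject, per-fold, or
pooled across regimes) is the caller's choice — `rank_report` takes the
table as-is.

Label-shuffle controls permute labels *within subject* so the four
classes stay balanced in every stratified split; a global permutation
would let majority-class imbalance pull "chance" above 1/K.

## The synthetic benchmark

The generator plants the quantities the analysis is supposed to
recover. Per gesture, the move command m(t) is a raised-cosine burst
(default 0.3 s, peak 1.0 in normalized units) at movement onset plus an
identical burst at release; the hold command is its running integral
h(t) = (1/fs)·Σ m (exact in discrete arithmetic). Posture recognition
is 0.4 s after onset, the hold lasts 2.0 s, inter-trial gaps are
uniform in [1, 2] s (the protocol does not fix them; these are the
declared defaults). Channel signals are

x_e(t) = p_k[e] · (m+h)(t) · c(t) + b₀ · n_e(t),

with p_k a unit-norm class spatial pattern, c(t) a band-limited
Gaussian carrier shared across channels within a gesture (so class
information lives in a spatial *direction*, recoverable by spatial
filtering), and n_e independent baseline noises at rest amplitude
b₀ = peak/snr. Carriers are normalized to unit mean Hilbert envelope
and clipped at |c| ≤ 3.5 (≈4.4σ), which yields a deterministic
amplitude bound; MVC segments are scaled 10% above that bound, so MVC
normalization provably maps task signals into [−1, 1].

Carrier band: 60–350 Hz, where real sEMG spectra concentrate. This is
deliberately inside the 30–500 Hz analysis band: a carrier filling the
full band loses a measurable fraction of its power when the zero-phase
band-pass (whose magnitude response is squared by the forward–backward
application) is applied again in preprocessing, which would bias every
planted amplitude by several percent for no physiological reason.

Subject- and session-level variability apply a random rotation (angle
scale = dispersion, in radians) plus per-channel gain jitter
(σ = dispersion/2) to the spatial patterns, renormalized to unit norm.
Defaults: subject dispersion 0.35, session dispersion 0.12 — enough to
reproduce the qualitative ordering intra-subject ≥ inter-session ≥
inter-subject without collapsing transfer entirely. The default
snr = 400 describes clean, MVC-scale laboratory recordings (rest noise
floor a fraction of a percent of the burst peak, as pre-gelled
electrodes deliver); the planted-pattern recovery properties are
additionally exercised down to snr = 5.

What the generator does **not** emulate: motor-unit action-potential
trains and their firing statistics, electrode-skin impedance drift,
motion artifacts, crosstalk between muscles, amplitude nonstationarity
within a hold, or any kinematic signal. Consequently, passing tests
show that the *pipelines are correct* (they recover what was planted,
they do not leak across folds, their invariants hold) — they do not
show that real-data accuracies would reach the same values. Ceiling
accuracies on the synthetic benchmark are expected and are not evidence
about real EMG.

## Move/hold decomposition details

The envelope is the magnitude of the analytic signal (frequency-domain
Hilbert transform) smoothed by a zero-phase 20 Hz low-pass;
rectification is implicit in the magnitude. Baseline removal subtracts
the per-channel median envelope over rest intervals; the default is
linear subtraction with clipping at zero, and `mode="power"`
(√(env² − baseline²)) is provided because the envelope of a signal plus
an independent noise floor adds in quadrature — linear subtraction
over-corrects active segments by roughly the full floor, while
power-domain removal is unbiased. The ground-truth recovery analyses
use the power mode for that reason.

Integration starts at movement onset (t₀), not at recognition: the
recursion is defined from the beginning of the move command. The stored
`hold` array is the lagged integrator state H_{T−1}, which makes
S = M + H an exact per-sample identity and `hold` exactly the exclusive
running sum of `move`/f; the post-update state (matching the closed
form c(1−(1−1/f)^{T+1}) for a step input) is the same array advanced
one sample (`hold_state`). One sample of lag is irrelevant at 2,048 Hz
for every downstream use. Negative move transients are kept: the
recursion defines them, and clipping would break conservation. The
hold command keeps integrating through the release burst; the
integrated tail after return-to-rest has no physiological reading but
retains class information, so it is not discarded.

Hold similarity pairs, per channel, one point per gesture:
x = mean raw envelope over the hold minus the rest baseline,
y = mean extracted hold command over the same interval; it reports
Pearson r and the identity-line R² (1 − SSres/SStot with predictions
= x). The identity-line convention is what makes a constant offset
drive R² negative while r stays high — the diagnostic signature of a
gain/offset mismatch rather than a shape mismatch.

## Problem sizes

The default benchmark for end-to-end properties is 6 subjects ×
5 sessions × 24 gestures (720 phasic, 3,600 tonic epochs), run single-
threaded; the acceptance script completes in a few minutes. Decomposition
recovery aggregates all events of the first 6–10 recordings; CNN sanity
fits use generated epoch sets of 80–200 epochs per class at S = 128–256.
These sizes were chosen so that every asserted property is measured with
comfortable statistical margin while the whole battery stays desk-scale.

## Known limitations

* The CNN is a faithful but compact numpy implementation; it is not
  performance-tuned for large inputs (no im2col reuse across layers, no
  threading), and early stopping is off by default in the estimator.
* `flag_artifacts` uses global per-channel statistics; a long recording
  with slowly drifting amplitude can hide step artifacts from the
  σ-scaled threshold.
* The rescaled-range Hurst estimator is biased upward for short white
  sequences; treat absolute values comparatively, not as calibrated H.
* The synthetic benchmark's rank-1 per-gesture mixing makes spatial
  structure easier to exploit than real EMG's; inter-subject transfer
  difficulty is controlled entirely by the dispersion parameters.
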