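# emgdecode

Decoding hand gestures from phasic and tonic surface-EMG, with a
neural-integrator decomposition of the EMG envelope into "move" and
"hold" commands.

## The problem

During a guided gesture (here: extension of the thumb, index, middle or
pinky finger, held for ~2 s), forearm surface-EMG shows two regimes: a
**phasic** burst while the hand moves, and a sustained, lower-amplitude
**tonic** component while the posture is held. This package implements,
and exercises end to end, the analysis needed to ask two questions:

1. *How well can the gesture be decoded from 500 ms windows of either
   component, and how does that decoding generalize across sessions and
   across subjects?*
2. *Does the tonic amplitude behave like the time integral of the phasic
   command (a neural integrator), and does extracting that integrated
   "hold command" improve sustained-posture decoding?*

The intended users are researchers in myoelectric control and EMG signal
processing who want a tested, reusable reference implementation of these
pipelines with a synthetic benchmark that makes every stage verifiable.

## What is inside

Four classification pipelines over labeled epochs X ∈ ℝ^(E×S) (E = 8
channels per hand, S = 500 ms windows), all scikit-learn estimators:

* **td** — 11 time-domain features per channel (MAV, RMS, MAA, WL, ZC,
  SSC, WA, MFL, kurtosis, Hurst exponent via rescaled range, sample
  entropy with m = 2, r = σ/10), standardized, one-vs-rest L2 logistic
  regression.
* **cov** — OAS-shrunk covariance Σᵢ = (1/S)XᵢXᵢᵀ per epoch, projected
  into the tangent space of the SPD manifold at the Fréchet mean of the
  training covariances, Φ(Σ) = logm(Σ_ref^{-1/2} Σ Σ_ref^{-1/2})
  (affine-invariant metric), then logistic regression.
* **xdawncov** — xDAWN spatial filters, per class k maximizing the SSNR
  w* = argmax (wᵀP⁽ᵏ⁾P⁽ᵏ⁾ᵀw)/(wᵀDw) with P⁽ᵏ⁾ the class-mean epoch and
  D the second moment of all epochs (a generalized eigenproblem); epochs
  are augmented to [W⁽¹⁾ᵀP⁽¹⁾; …; W⁽ᴷ⁾ᵀP⁽ᴷ⁾; WᵀX] before the same
  covariance → tangent-space → logistic stack.
* **cnn** — a compact convolutional network (temporal conv 128×(1×16),
  spatial conv 16×(8×1) + batch norm + ReLU + mean-pool + spatial
  dropout, temporal conv 128×(1×16) + the same block, two dense-128
  layers, softmax), Glorot-uniform init, Adam at learning rate 0.005,
  implemented directly in numpy.

Three cross-validation regimes (`evaluate.crossval`): intra-subject
(stratified 5-fold per subject), inter-session (leave-one-session-out)
and inter-subject (leave-one-subject-out), plus a voting ensemble,
confusion/ROC/AUC reporting, and average-rank comparison with the
Nemenyi critical distance CD = q₀.₀₅(k)·√(k(k+1)/(6N)).

The **move/hold decomposition** (`decompose`): the Hilbert-envelope
S of the band-passed EMG is split by the per-sample iteration

    M_T = S_T − H_{T−1},    H_T = H_{T−1} + M_T / f,

so the hold command H is the running integral of the move command M and
S = M + H holds exactly at every sample. `hold_similarity` quantifies
how well H matches the measured tonic amplitude (Pearson r and
identity-line R²), and `evaluate.window_sweep` probes decoding accuracy
of raw/move/hold signals in 0.5 s windows across the gesture.

Because no public recording set accompanies this analysis, the
`synthio` module generates the full study: 16-channel-equivalent
(8 per hand) recordings at 2,048 Hz, 6 repetitions × 4 gestures per
session, 5 sessions per subject, raised-cosine move bursts with planted
integrator ground truth, class-specific spatial patterns with
subject/session-level dispersion, MVC calibration segments, and
artifact-free rest baselines. Every downstream claim is tested against
that planted ground truth.

## Worked example

```python
import numpy as np
from emgdecode import SynthConfig, make_pipeline
from emgdecode.preprocess import build_epochsets
from emgdecode.synthio import synthesize_dataset
from emgdecode.evaluate import CvConfig, crossval

config = SynthConfig(n_subjects=3, n_sessions=2, rng_seed=42)
phasic, tonic = build_epochsets(synthesize_dataset(config))
print(f"phasic epochs: {phasic.data.shape}, tonic epochs: {tonic.data.shape}")

for mode in ("intra_subject", "inter_session", "inter_subject"):
    rep = crossval(phasic, make_pipeline("xdawncov"), CvConfig(mode=mode, seed=0))
    print(f"xDAWN-covariance {mode:14s} accuracy: {rep.mean_accuracy:.3f}"
          f"  (macro AUC {rep.auc_macro:.3f})")
```

prints

```
phasic epochs: (144, 8, 1024), tonic epochs: (720, 8, 1024)
xDAWN-covariance intra_subject  accuracy: 1.000  (macro AUC 1.000)
xDAWN-covariance inter_session  accuracy: 1.000  (macro AUC 1.000)
xDAWN-covariance inter_subject  accuracy: 0.833  (macro AUC 0.985)
```

The shape (144, 8, 1024) is 3 subjects × 2 sessions × 24 gestures, each
a 500 ms, 8-channel window at 2,048 Hz; tonic windows outnumber phasic
ones 5:1 (five 500 ms windows at a 256 ms stride per hold). Within a
subject the gestures are decoded perfectly; transferring to an unseen
subject loses accuracy because each synthetic subject carries its own
spatial-pattern perturbation — the qualitative signature real
inter-subject EMG transfer shows.

Decomposing one gesture and checking the planted integrator ground
truth:

```python
from emgdecode.synthio import synthesize_recording, synthesize_mvc, rest_intervals
from emgdecode.preprocess import preprocess_recording
from emgdecode.decompose import Envelope, decompose_move_hold, envelope, remove_baseline

config = SynthConfig(rng_seed=42)
rec, truth = synthesize_recording("S01", "sess1", "right", config)
_, mvc = synthesize_mvc(config)
clean = preprocess_recording(rec, mvc)

env = envelope(clean.signal, clean.fs)
env = remove_baseline(env, rest_intervals(clean, config), mode="power")

gt = truth.events[0]
dec = decompose_move_hold(Envelope(env.values[:, gt.start_index:gt.stop_index],
                                   config.fs), 0)
h_true = gt.h_true / mvc.max_abs[:, None]
err = np.linalg.norm(dec.hold - h_true) / np.linalg.norm(h_true)
print(f"gesture: {gt.event.label}")
print(f"hold-command recovery, relative L2 error: {err:.3f}")
```

prints

```
gesture: middle
hold-command recovery, relative L2 error: 0.062
```

i.e. integrating the measured move command reproduces this gesture's
planted hold command to ~6% (about 3% averaged over a full benchmark);
the conservation identity S = M + H holds to machine precision.

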