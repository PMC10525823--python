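# Methods

## The problem

Scalp EEG carries two kinds of structure this package models separately:
a *subject* signature — who produced the signal — and a *task* signature —
what the person was doing while it was recorded.  Subject identification
treats EEG as a biometric: inter-subject variability in spectral shape and
rhythm frequency is large and stable enough to distinguish individuals.
Task classification exploits the band-power modulation that activities such
as motor imagery impose on ongoing rhythms.

Both models consume raw signals.  The classical preprocessing chain
(standardization, band-pass filtering, AR/PSD feature extraction) exists
only to feed the comparison baselines.

## Data model and segmentation

A recording is a `K x L` matrix at sampling rate `fs` with subject and task
labels.  Two segmentation modes feed the two models:

* **Horizontal** (subject identification): the recording is cut along time
  into `r = floor(L / l̃)` consecutive, non-overlapping `k̃ x l̃` windows.
  The remainder of fewer than `l̃` samples is dropped, not padded — padding
  would fabricate signal.  When `k̃ < K`, channels are subsampled at evenly
  spaced indices (round half-up, first and last channels always kept); the
  subsetting rule for partial montages is this package's own convention.
* **Vertical** (task classification): the recording splits into `K`
  single-channel `1 x L` sequences.  Cutting time would destroy the
  long-range band-power structure the task classifier depends on, so each
  channel is kept whole.

Splits for evaluation are **task-wise within subject**: a ratio `a:b`
(`a + b = M` tasks) puts whole recordings of `a` tasks in training and `b`
in testing, per subject, and the fold index rotates the held-out block.
Segments of one recording therefore never appear on both sides of a split.

## Subject model: stacked peephole LSTM

Five identical peephole-LSTM layers process a window column by column (the
`k̃`-vector of channel samples is the per-step input, `l̃` steps).  Gates:

    I_t = σ(W_I x_t + U_I h_{t-1} + v_I ⊙ c_{t-1} + b_I)
    F_t = σ(W_F x_t + U_F h_{t-1} + v_F ⊙ c_{t-1} + b_F)
    c_t = F_t ⊙ c_{t-1} + I_t ⊙ tanh(W_C x_t + U_C h_{t-1} + b_C)
    O_t = σ(W_O x_t + U_O h_{t-1} + v_O ⊙ c_t + b_O)
    h_t = O_t ⊙ tanh(c_t)

Design points:

* Peephole weights are elementwise (diagonal), the standard peephole form.
* The output gate peeks at the *current* cell `c_t`; input and forget gates
  at `c_{t-1}`.  This asymmetric form is implemented deliberately.
* The forget-gate bias initializes to 1.0 ("forgetting rate 1.0"), the
  usual trick to retain memory early in training.
* The final hidden state of layer 5 feeds a linear softmax head with one
  output per subject; softmax uses max-subtraction.
* Defaults: hidden size 64 (32 in the desk-scale experiments below),
  uniform fan-in-scaled initialization, gradient clipping at global norm 5.

Training minimizes cross-entropy with Adam (stepsize 1e-3, decay rates
0.9/0.999, eps 1e-8), batch size 32, deterministic given the config seed.
The implementation is pure numpy with hand-written backpropagation through
time; a vectorized cell is tested against an independent explicit-loop
scalar implementation to 1e-10, and all analytic gradients are checked
against central differences.

Recording-level identification takes the per-segment argmax and a majority
vote across segments, ties broken by summed probability.

## Task model: five-block 1-D CNN

Input is one whole channel (`1 x L`).  Blocks (all convolutions kernel 3,
stride 1, same padding; all pools window 2, stride 2 along time):
block 1 has two 16-filter convolutions then one pool; blocks 2-5 have one
convolution each with 32, 64, 128, 128 filters and a pool.  Batch
normalization precedes every convolution's input (including the first);
activations are ReLU; dropout (rate 0.5) acts in the last two blocks only,
and only during training.  The flattened block-5 map feeds a linear softmax
head directly — no hidden dense layer.  For `L = 9600` (60 s at 160 Hz)
the post-pool maps are 4800x16, 2400x32, 1200x64, 600x128, 300x128; the
head dimension is computed from the shape arithmetic at build time, so any
`L >= 32` works.  The optimizer setup is shared with the LSTM.

Recording-level task prediction majority-votes the per-channel argmaxes,
ties broken by summed probability.

## Classical branch (baselines only)

* **Standardization**: per channel, `(x - μ)/σ` with the *population*
  standard deviation; a zero-variance channel raises an error naming it.
* **Band-pass**: 0.5-45 Hz, 4th-order Butterworth applied forward-backward
  (zero phase).  The pass-band edge behaviour is contract-tested (10 Hz
  tone within 5% RMS; 60 Hz tone attenuated >= 20 dB at fs = 160).
* **AR features**: Yule-Walker (via statsmodels) on the demeaned series;
  order p = 6 by default.  Only the AR part of the quoted ARMA family is
  fitted — the printed difference equation is purely autoregressive.
* **Welch PSD**: Hann window, nperseg 256, 50% overlap, density scaling;
  band powers integrate the density over delta (0.5-4), theta (4-7.5),
  alpha (8-13), beta (14-30) and gamma (30-45 Hz).
* Feature vectors concatenate per-channel AR coefficients and band powers
  (`K (p + 5)` dimensions); either block can be switched off since the
  original feature mix per dataset is not documented.

Baselines: linear-kernel SVM, LDA, 1-nearest-neighbour, decision tree,
Gaussian naive Bayes, AdaBoost, MLP — scikit-learn implementations at
library defaults, standardized inputs for the margin-based ones.

## Metrics

Per class, precision `TP/(TP+FP)` and recall `TP/(TP+FN)` with the 0
convention for empty denominators; macro averages `P*`, `R*` are unweighted
class means; `F1 = 2 P* R* / (P* + R*)` is the harmonic mean of the two
macro numbers (not the mean of per-class F1).  Metrics are computed from an
explicit confusion matrix so the two routes (labels vs counts) can be
cross-checked.

## Synthetic EEG generator

Each synthetic subject owns: per-channel stationary AR(6) backbones (drawn
via reflection coefficients in (-0.7, 0.7), so stationarity is guaranteed
by construction; innovation SD uniform in 0.3-0.7 per channel), an alpha
oscillation at a subject-specific peak frequency (centres evenly spaced
over 8-13 Hz so ten subjects sit >= 0.5 Hz apart), a per-channel amplitude
pattern (uniform 0.8-1.2), and white sensor noise (SD 0.3).  The
oscillation is a narrowband stochastic process: its instantaneous phase
diffuses (Wiener phase noise, ~0.3 Hz linewidth) and its envelope waxes and
wanes (low-passed Gaussian envelope, 0.5 Hz bandwidth, clipped at 0.2).
A constant-phase sinusoid would instead make the cross-channel phase
pattern a *recording* fingerprint, which no real biometric property
corresponds to.

A task multiplies the oscillation amplitude on a set of affected channels
(default: all).  With `Q` classes and gain ratio `g`, class `q` receives
gain `g^(q - (Q+1)/2)`: adjacent classes differ by exactly `g` and the
modulation stays centred on 1 rather than growing with `Q`.  The spatial
amplitude jitter is deliberately modest (±20%) so that class membership
remains decodable from a single channel, which matches the regime of real
motor-imagery corpora where single-channel task classification is nearly
perfect.  Class assignment over tasks is round-robin; seeds fan out
hierarchically (dataset → subject → task), so enlarging a dataset never
changes recordings already drawn.  Burn-in of 10p samples is discarded
before each AR trajectory is used.

What the generator does *not* emulate: eye-blink and muscle artifacts,
50/60 Hz line noise, volume conduction and inter-channel correlation,
non-stationary drift across a session.  Passing tests on this data show the
pipeline recovers planted subject and task structure; they do not certify
performance on real recordings.

## Desk-scale experiment sizes

The published protocol (109 subjects, 64 channels, minute-long recordings,
hours of training) is far beyond a test suite, so the end-to-end checks run
scaled-down versions whose sizes were fixed in advance:

* Subject identification: 10 subjects x 4 tasks, 8 channels, 20 s
  recordings at 160 Hz (L = 3200), window l̃ = 160 (inside the optimal
  120-160 range for this sampling rate), 4-class task modulation at gain
  ratio 2, split 3:1 by tasks, hidden size 32, up to 100 epochs.  Gate:
  held-out segment accuracy >= 0.5 against 0.1 chance.
* Task classification: 8 subjects x 6 tasks, 3 classes at gain ratio 3,
  8 channels, 10 s recordings (L = 1600), split 4:2 by tasks, up to 30
  epochs.  Gate: held-out per-channel accuracy >= 0.9 against 1/3 chance.

Both runs early-stop once training accuracy reaches 1.0.

## Numerical notes and edge cases

* All math is float64; softmax and sigmoid are clipped/stabilized.
* Yule-Walker uses the MLE (1/n) autocovariance scaling; `p = 0`
  degenerates to intercept = sample mean.  The intercept is recovered from
  the stationary-mean relation `c = μ (1 - Σ a_i)`.
* A horizontal split with `l̃ > L` raises rather than returning an empty
  batch; a constant channel fails standardization loudly; `high >= fs/2`
  fails the filter before scipy would alias it silently.
* Ties in majority votes (both models) break by summed probability, which
  is deterministic.
* Batch-norm running statistics use momentum 0.9 and are saved with
  checkpoints; evaluation mode is exactly deterministic.

## Known limitations

* The generator's subject signal is strongly spectral; it cannot probe
  cues (e.g. connectivity patterns) the real corpus may carry.
* The LSTM is the slowest component (pure numpy BPTT); minute-scale inputs
  with 64 channels are out of reach of the test suite, though the code
  accepts them.
* Baseline hyperparameters are library defaults on purpose; no tuning
  harness is provided.
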