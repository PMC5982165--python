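# Methods

`emgfault` implements a fault-tolerant surface-EMG (sEMG) movement
classification system: contaminated channels are detected online and replaced
by a model-based *virtual sensor* driven by the remaining clean channels, and
the effect on movement-classification accuracy is quantified across seven
evaluation settings.  This note documents the models, the tunable parameters,
the synthetic data the package is validated on, and the numerical and design
choices that were genuinely open.

## Signal model and acquisition protocol

The target recording is a 12-electrode upper-limb montage sampled at 2 kS/s:
eight uniformly spaced electrodes on the forearm ring, flexor and extensor
digitorum electrodes, and bicep/tricep electrodes.  The protocol comprises 17
movements, each held 5 s and followed by 3 s of rest, repeated 6 times
(816 s of labelled timeline).  Per-sample labels are 0 (rest) or 1–17;
repetitions are indexed 1–6 (0 during rest).

Because the package must be testable without any external database, the
`synthetic` module generates protocol-faithful recordings from a latent-source
model: `n_sources` (default 6) Gaussian carriers band-limited to 20–450 Hz are
mixed into the channels through a spatially smooth mixing matrix (Gaussian
profile, σ = 2 electrode spacings, rows normalized), then amplitude-modulated
per movement segment by a 250 ms raised-cosine envelope times a movement- and
channel-specific activation gain.  Each movement strongly activates a random
subset of 4 channels (gains in [0.6, 1.0]) against a weak background
([0.05, 0.25]); a band-limited noise floor at −20 dB relative to the mean
movement RMS is present throughout.  Shared carriers give the cross-channel
correlation the virtual sensor requires; sparse, partially colliding
activation patterns make single-channel corruption genuinely harmful to
classification, as it is in real sEMG.

What the generator does *not* emulate: motor-unit physiology, force
modulation, electrode-skin impedance drift, inter-subject variability, or the
amplitude nonstationarity of fatigue.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the *direction*
of the fault-tolerance effects on a controlled substrate — not clinical
performance on real recordings.

## Preprocessing

Order-20 Butterworth band-pass, 20–500 Hz, realized as cascaded second-order
sections (a direct-form order-20 polynomial is numerically unstable at these
edge frequencies) and applied zero-phase.  Normalization is per-channel
max-absolute over the full record (offline; an MVC-style online calibration is
exposed but not the default path).  Segmentation uses 300 ms sliding windows
advanced by 75 ms (600/150 samples), window label = majority per-sample label
with ties broken toward the smaller id.

## Contaminant simulators

Five canonical contaminants, inserted into the raw signal over the whole
record before preprocessing, into the channel sets of the 16 degradation
cases (single ring electrodes 1–8; flexor; extensor; bicep; tricep;
flexor+extensor; bicep+tricep; all four; the whole ring):

* **Motion artifact** — band-limited (<7 Hz) stochastic drift whose intensity
  is modulated by a slow burst envelope (continuous sway plus 0.3–1.2 s
  tugs), plus a small wide-band component (2.5% of total power, <60 Hz,
  burst-gated) representing electrode-gel transients; ≥95% of the power stays
  below 10 Hz.  The wide-band tail is deliberate: a strictly sub-10 Hz
  artifact would be annihilated by the 20 Hz high-pass edge and could never
  affect classification, contradicting what is observed with recorded motion
  artifacts.  Default level: unit power (0 dB re 1); this level is a free
  parameter of the simulator, not a literature constant.
* **Electrode displacement** — additive white Gaussian noise at 15 dB SNR
  relative to the channel's own power.
* **Amplifier saturation** — six sinusoids at uniform-random frequencies in
  200–240 Hz with random phases.  The per-component amplitude is not fixed by
  the source description; the default 0.5 (sum RMS ≈ 0.87) makes the artifact
  comparable to movement-level sEMG, befitting saturation.
* **Power line** — 60 Hz fundamental of amplitude 0.4 plus harmonics k·60 Hz
  with amplitude 0.4/k (k = 2..4); fundamental dominance, deterministic.
* **ECG bleed-through** — synthetic P-QRS-T template (sum of Gaussian bumps
  per beat, ±2% beat-period jitter), normalized and scaled to maximum
  absolute amplitude 0.2.

## Fault detection (SFTD)

A two-class RBF-kernel SVM flags each 300 ms window of each channel as clean
or contaminated.  Features (11): MAV, RMS, WL, MFL, PWR plus six spectral
descriptors — periodogram centroid, power fraction below 20 Hz (motion
artifact), in 55–65 Hz (mains), above 450 Hz (wide-band noise), the
out-of-band spectral slope P(>700 Hz)/P(>450 Hz) (amplitude-invariant,
separates spectrally flat added noise from the rolled-off sEMG spectrum),
and the spectral peak fraction (largest periodogram bin over total power),
which flags narrowband interference such as saturation sinusoids however the
channel is scaled.  Detection runs on the raw (normalized, unfiltered)
windows: the sub-20 Hz and mains cues would be suppressed by the
preprocessing band-pass.  Training examples of the contaminated class are
constructed exactly as they appear in deployment — contaminant inserted into
the raw channel, channel renormalized by its own new maximum — so the
detector cannot rely on amplitude cues that normalization removes.

Temporal logic per channel: the virtual sensor activates when more than 70%
of the window positions in the trailing 3 s (37 positions at the default
geometry) are flagged — unfilled buffer slots count as clean, which is what
makes contamination bursts shorter than 0.7 × 3 = 2.1 s unable to activate —
and the channel is removed from retraining (setting 3) when ≥80% of the
windows over the evaluation span are flagged.

## Virtual sensor

**MCC.** For target channel *t*, each available source channel *x* receives
weight p_{x,t} = c_{x,t} / Σ_{x'≠t available} c_{x',t}, where c is the
magnitude of the zero-lag Pearson correlation (absolute value so that
anticorrelated channels still contribute as informative, nonnegative
weights).  Channels flagged contaminated have their correlation rows zeroed
and the normalization is redone, so the weights toward every target always
sum to one and the exogenous input u_t(n) = Σ_x p_{x,t} y_x(n) is a convex
combination of the clean channels.  The MCC is estimated once per activation
event from the most recent clean 3 s buffer.

**TVARMA.** A time-varying ARMA(P=4, Q=2) whose coefficients are expanded on
a finite basis f(n, m), m = 0..V (default Legendre polynomials on time
normalized to [−1, 1], V = 2; Fourier and raw time-power families are
selectable).  The model is linear in the expansion coefficients, so
estimation is least squares on the clean history.  Two estimators are
provided:

* *joint* — one-step-ahead regression on the lagged-output and lagged-input
  regressors jointly.  This is the classical identification estimator and
  recovers the generating coefficients when the data come from the model
  (verified by simulation), **but** on strongly autocorrelated signals it
  attributes almost all predictability to the output lags: the fitted AR
  polynomial acquires near-unit-circle poles and the input coefficients
  shrink toward zero.  Once the channel is degraded its own past is exactly
  what is unavailable, and the free-running (zero-innovation) prediction of
  such a model ignores the cross-channel input and decorrelates from the
  truth.
* *two-stage* (default for reconstruction) — first regress the output on the
  lagged exogenous input alone (the b(j, n) coefficients; the basis lets this
  mapping track slow amplitude changes), then fit the AR part on the
  residual.  The mean prediction is then the exogenous filter (the residual's
  AR free response is zero-mean), which is input-driven by construction and
  empirically reconstructs held-out channels with normalized RMSE < 1.

**TVK.** Kalman state estimator with identity state matrices (scalar state).
The steady-state error covariance solves the discrete algebraic Riccati
equation (fixed-point iteration to 1e−10 with a direct-solver fallback) and
the innovation gain is M = P Cᵀ(C P Cᵀ + R)⁻¹.  The exogenous input of the
state recursion is the *increment* of the amplitude-calibrated MCC signal
(calibration gain λ = ⟨y, u⟩/⟨u, u⟩ on the clean history), so the identity-A
prior tracks the MCC estimate while the measurement update blends in the
measured channel.  Noise covariances: R₀ = residual variance of the clean
history fit; during contamination the measurement noise is inflated
(R = 10 R₀, configurable) so the estimate leans on the MCC prior;
Qw = 0.1 R₀.

**Reconstruction.** Samples of windows that are both flagged and covered by
an active state are replaced by the selected model's output; all other
samples and channels are untouched, and a provenance record lists the
replaced spans per channel.  Whole-record contamination (the evaluation
protocol) leaves no clean history on the degraded channel, so the evaluation
harness supplies the pre-degradation buffer from the clean preprocessed
record.  The buffer spans one full repetition block (every movement once):
the channel-to-channel amplitude mapping is movement-dependent, so a fit on
a buffer covering a single movement does not transfer across the movement
inventory, whereas any system running before the fault has a representative
stretch of clean history available.  `reconstruct_channel` falls back to the
leading 3 s of the recording when no history is supplied.

## Features and classification

Per window and channel: MAV, RMS, WL, MFL (= log10 √Σ(Δx)², base-10, with a
−16 sentinel for constant windows), PWR (= RMS² exactly), computed on the
signed filtered-normalized view (all five are sign-invariant).  No feature
reduction.  Classification is an 18-class one-vs-all RBF SVM (prediction =
argmax of decision values), with majority voting over the last three raw
window predictions (three-way ties keep the current prediction).  Folds are
the C(6,3) = 20 complementary train/test partitions of the six repetitions.
Rest windows carry repetition 0, so for fold assignment each window also
carries the repetition of the nearest preceding movement (`fold_repetition`).

Settings: (1) clean/clean; (2) clean/contaminated; (3) retrain and test
without removal-flagged channels; (4, 6) clean train, TVARMA/TVK-replaced
test; (5, 7) TVARMA/TVK replacement in train and test.  Hyperparameters are
grid-searched once per subject (cost and kernel width over powers of two) on
clean training data and reused across settings and folds.

## Statistical analysis

Fixed-effects full-factorial three-way ANOVA of mean accuracy with factors
classification setting × contaminant × channel case, all two- and three-way
interactions, sequential sums of squares (equal to the classical balanced
decomposition; verified against a two-pass textbook computation; the SS
partition the total exactly).  Multiple comparisons use per-group 95%
confidence intervals with pooled MSE; two means differ significantly when
their intervals are disjoint.

## Problem sizes, defaults and numerical choices

* Desk-scale study defaults (`StudyConfig`): 17 movements × 6 repetitions at
  2 s movement / 1 s rest (306 s of signal), contaminants
  {displacement, saturation, motion artifact} × cases {1, 15}, folds
  {0, 9, 19} of the 20, coarse 3×3 hyperparameter grid.  The paper-scale
  protocol (5 s/3 s, all 16 cases, 20 folds, full grid) is reachable by
  parameters.
* Riccati iteration tolerance 1e−10, iteration cap 1e5, direct DARE solver
  fallback.
* Rank-deficient TVARMA designs fall back to ridge with λ = 1e−8·tr(XᵀX)/p,
  logged.
* TVARMA prediction is clipped to a guard bound (50× the seed/input scale)
  and flagged if the recursion leaves it.
* Degenerate inputs: constant windows get an MFL sentinel; constant channels
  get zero cross-correlation (logged); identically zero channels pass
  normalization unscaled with a warning.
* Determinism: every stochastic component takes an integer seed and uses an
  independent, tagged `numpy` generator stream; identical inputs give
  bit-identical outputs.

## Known limitations

* The synthetic substrate encodes movements mainly in multichannel amplitude
  patterns; effects that depend on fine spectral differences between
  movements are not represented.  Two consequences follow.  First, the
  classifier is very robust to *weak* contaminants: 15 dB additive noise or
  the post-filter residue of a low-frequency motion artifact shifts
  movement-window features by only a few percent, well inside the class
  margins, so direct classification of such contaminated signals loses
  little or no accuracy — and where nothing is lost, replacing the channel
  by a virtual sensor cannot recover anything (it can at best match the
  undegraded baseline).  The accuracy-recovery behavior of the virtual
  sensor is therefore demonstrated on the harsh contaminant (saturation,
  which destroys the channel's features); for the weak contaminants the
  system correctly detects them and replacement is neutral-to-harmful,
  mirroring what happens for weak interference on real data.  Second,
  channel removal is nearly costless here — a handful of channels already
  separates the movement inventory — so retraining without the degraded
  channels is not measurably worse than retraining with virtual-sensor
  replacements on this fixture, unlike on real recordings where discarded
  channels carry unique information.
* ECG and power-line interference are intentionally weak contaminants at the
  classification stage (most of their energy is removed or negligible after
  preprocessing); consistent with the above, virtual-sensor replacement is
  not expected to help there.
* The virtual sensor reconstructs a degraded channel from linear combinations
  of the remaining ones, so it cannot restore information that only the lost
  channel carried; what it restores is the representation the classifier was
  trained on.
* Detector quality is data-dependent; the reported held-out accuracy and
  false-positive rates are properties of the synthetic fixture.
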