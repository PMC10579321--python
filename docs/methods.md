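# Methods

This note documents the models, parameter choices and numerical decisions
behind `somnoloop`, and what the synthetic benchmarks do and do not show.

## Scoring model

Sleep is scored in 30-second epochs over four stages — wake (W), light
sleep (LS, the N1+N2 merge), deep sleep (DS, N3) and REM (R) — plus an
explicit UNSCORED symbol (U) for epochs the real-time path cannot score.
Epoch *i* covers the half-open interval [30·i, 30·i+30) seconds; a trailing
partial epoch is discarded. The 4-stage alphabet reflects the low
inter-rater reliability of the N1/N2 boundary and the need for a stage
granularity a closed-loop controller can act on.

### Channel quality and re-referencing

Each epoch × channel window passes five screens, any of which marks it
unscorable:

| metric | default threshold | rationale |
|---|---|---|
| flatline fraction (samples in near-constant runs ≥ 0.5 s, tol 0.05 µV) | > 0.2 | lost contact / railed amplifier |
| saturation fraction (\|x\| ≥ 900 µV) | > 0.05 | rail clipping |
| high-amplitude fraction (1-s windows with peak-to-peak > 400 µV) | > 0.3 | movement artifact |
| RMS amplitude | < 0.5 µV or > 150 µV | dead or wild channel |
| mains-band ratio (45–55 Hz power / 0.3–35 Hz power) | > 1.0 | poor contact impedance |

Thresholds are conventional artifact screens, all configurable; the
high-amplitude and RMS bounds sit comfortably above clean deep-sleep
delta (≈ 250 µV peak-to-peak at default amplitudes). Scorability is decided
per epoch with no hysteresis, so post-outage stabilization time is an
emergent measurement rather than an imposed lockout.

Re-referencing derives virtual channels from the usable set. The
`contralateral_be` scheme subtracts the opposite-side behind-ear (BE)
channel from each forehead (FH) and over-the-ear (OTE) channel and emits
nothing when the reference is unusable; the `dynamic` scheme falls back
contralateral BE → ipsilateral BE → raw pass-through (and passes BE itself
through if nothing else survives), so it can never score fewer epochs than
the contralateral scheme. The priority order maximizes agreement with the
contralateral scheme on clean data. Subtraction is plain sample arithmetic.

### Features

Per derived channel and epoch: Welch power spectral density (4-s segments,
50 % overlap), absolute and relative band power over Delta/Theta/Alpha/Beta
(relative powers normalized by the four-band sum, so they always sum to 1),
normalized spectral entropy and 95 % spectral edge in 0.5–30 Hz; spindle
events (11–16 Hz band, 250-ms moving-RMS envelope above 3× its median for
0.5–2 s) with count and mean peak-to-peak amplitude; slow-wave events
(0.3–2 Hz negative half-waves, trough ≥ 40 µV, duration 0.25–3 s) with
count and mean trough; low-band (< 4 Hz) EOG power and 20–45 Hz EMG power
(log scale). Channel-wise vectors are averaged over the usable derived
set; left–right Alpha/Delta asymmetries are appended when both sides
contribute, else imputed 0 with a flag. The EMG band stops at 45 Hz
because a 0.3–35 Hz-referenced chain at 200 Hz cannot represent ~100 Hz
muscle content faithfully; the upper band still carries muscle-tone
contrast.

The spindle/slow-wave detector parameters follow common sleep-medicine
conventions (envelope-threshold spindle detection; amplitude-and-duration
criteria for slow waves); detector bands and criteria are configurable.

### Classifiers

Both the primary (ExG-feature) and secondary (vitals-feature) models are
multinomial logistic regressions over standardized features with
inverse-frequency class weighting — chosen because they expose calibrated
class probabilities, deterministic training, and a transparent warm-start
path. A cold start fits with L-BFGS. A warm start reuses the initial
model's feature scaling and runs 100 full-batch softmax gradient steps
(step 0.5 on the weight-normalized gradient, L2 1e-4): early-stopped
gradient descent from the pretrained weights acts as an implicit prior, so
with one or two nights of new data the solution stays anchored to the
pretrained optimum instead of overfitting the new subjects. This is what
produces the pre-training advantage in the low-data regime; with ample
data the two initializations converge to similar solutions.

The secondary model sees causal 10-epoch context windows of HR mean/SD/
trend, RR mean/SD, motion RMS mean/max, posture-change count, and HR
relative to the running night median. It scores epochs whose window has at
least one valid HR or RR; all-invalid windows stay unscored.

### Fusion and offline smoothing

Real-time fusion is causal: the primary prediction wins whenever present;
within a run of consecutive primary-unscored epochs, epochs beyond the
first `gap_min` minutes (default 5, i.e. 10 epochs) take the secondary
prediction, earlier ones stay UNSCORED. The gap operationalizes "switch to
vitals only after the ExG has been unstable for a sufficient time";
applying it by position-within-run keeps the rule causal — truncating the
input streams never changes already-emitted outputs.

Offline, the stage path is decoded by Viterbi dynamic programming in log
space under a bigram transition model (maximum-likelihood counts with
additive smoothing ε = 1e-4, pairs involving UNSCORED skipped). UNSCORED
epochs enter with uniform emissions, so the decoder scores them from
temporal context alone and every epoch receives a stage. A rule pass then
replaces single-epoch islands (X, Y, X with Y ≠ X) with the flanking stage,
iterated to a fixed point; the island rule is the minimal "remove unlikely
transitions" rule, and larger structures are left to the transition model.

## Closed-loop controller

PoAs is an exponentially weighted moving average of the scored probability
of not being awake: `poas_t = α·poas_{t−1} + (1−α)·(1−p_W)`, α = 0.8,
initial value 0, carry-forward on unscored epochs. One parameter
reproduces the observed behavior of such a sleepiness index: geometric
convergence toward 1−p_W (rate α), a rapid early rise as wake probability
drops, a plateau while the user is settling, and a final rise past ~0.8 at
sleep onset.

SOL is the index of the first epoch starting a run of ≥ k consecutive
non-wake epochs (k = 3; k = 1 gives the literal first-transition rule).
The persistence guard ignores single-epoch blips, at the cost of detecting
onset k−1 epochs (1 min) after the run begins.

The audio timeline plays guided breathing voice from t0 with a fade-out
ending at t1, relaxation voice on [t1, t2], and background music from t0
onward, alone and slowly fading after t2 (defaults t0 = 0, t1 = 8,
t2 = 16 min, 30-s fades); every gain is 0 from SOL detection or the 50-min
cap onward. Automatic Content Switching fires when, within the first
20 min, the PoAs slope over a trailing 5-min window is below 0.01/min and
at least 5 min (dwell) have passed since the last switch; the dwell
prevents thrashing. Switching restarts the component timeline for the new
content.

Content recommendation is Thompson sampling over per-content normal value
posteriors with known observation variance σ_r² = 1e-3: the conjugate
update is `σ²_new = 1/(1/σ² + 1/σ_r²)`, `μ_new = σ²_new(μ/σ² + r/σ_r²)`,
with reward r = the PoAs least-squares slope over the interval the content
played. Posterior updates are applied at session end (rewards from the
previous session, not online). A recommendation samples every eligible
posterior and returns the argmax, excluding the most recently used
content; callers that have no exclusion (e.g. the first session) pass
none.

## Synthetic polysomnography

The simulator provides ground truth the pipeline can be measured against.
Per night (one "subject"), seeded end to end:

- **Hypnogram**: an initial wake run drawn from a truncated normal SOL
  prior (mean 15, SD 5 min, ≥ 1 epoch — the healthy-adult 10–20 min
  range), then a first-order Markov chain over the four stages with
  self-transition ≈ 0.85 and W→LS→DS / LS→REM-favoring exits.
- **ExG**: per-channel 1/f background (10 µV RMS) plus stage-conditional
  sources — wake: Hann-windowed 8–13 Hz alpha bursts (20 µV) and biphasic
  blink deflections (100 µV); light sleep: 11–16 Hz spindle bursts at
  3/min (30 µV), occasional K-complex transients (90 µV), low theta;
  deep sleep: amplitude-modulated 0.6–1.8 Hz delta (80 µV); REM: 4–8 Hz
  theta plus rapid EOG deflections (70 µV). Broadband EMG noise is local
  to each electrode and scaled by stage (wake 1.0 → REM 0.08). Cortical
  sources couple strongly to FH/OTE sites and weakly (0.25) to the BE
  reference sites — which is exactly why re-referenced virtual channels
  retain the oscillatory content; EOG couples mostly frontally. Per-night
  lognormal amplitude scale (SD 0.15) and per-channel gains (SD 0.05)
  model inter-subject and inter-electrode variability; this heterogeneity
  is what makes pre-training on many nights genuinely useful.
- **Vitals**: stage-conditional HR (W 70, LS 62, DS 57, REM 68 bpm ± SD,
  plus a per-subject offset and epoch-to-epoch smoothing) drives a
  phase-integrated pulse waveform at 64 Hz; RR (W 15, LS 13, DS 12,
  REM 16 brpm) modulates the accelerometer (50 Hz) around the posture
  gravity vector; posture changes only during wake (p = 0.1/epoch) among
  five canonical orientations; wake epochs carry 0.3 g movement bursts
  (p = 0.25). PPG and accelerometer rates are configurable defaults — the
  device's native rates are not pinned by the hardware description.
- **Artifacts**: per channel, contact-loss events at 1/hour with
  log-uniform 30 s–20 min durations, realized as flatline, ±1000 µV rail
  saturation, or 800 µV low-frequency motion noise. The mask marks
  epoch × channel cells the event covers by ≥ 50 %; boundary epochs with
  smaller overlap are deliberately left unmasked and absorbed into the
  specificity budget of the detection benchmark.
- **Virtual sleeper**: latent sleep propensity x starts at 0 and follows a
  drift–diffusion step per epoch, drift = relax rate (0.05/min) + the
  current content's true effect, diffusion `effect_sd·√dt`. The onset
  threshold is `relax_rate × baseline SOL` (default 40 min — a
  difficulty-falling-asleep population), so effective content shortens
  time-to-threshold proportionally. Emissions mix two sigmoids of x (soft
  relaxation step at 0.3× threshold, sharp onset step at the threshold),
  which produces the three-part PoAs profile by construction.

What the simulator does **not** emulate: real EEG microstructure
(waveform asymmetries, 1/f slope changes, arousals), sleep architecture
beyond first-order dynamics (no REM cycling with time of night),
pathology (apnea, periodic limb movements), oximetry, or realistic PPG
morphology and motion-coupled PPG artifacts. Benchmarks on it therefore
measure pipeline correctness — that each component recovers the structure
the generator put in, and that the pieces compose — not clinical
performance; held-out accuracies here are far above what any real
population yields, and no clinical claim should be read into them.

## Benchmark problem sizes

The staging corpus is 40 training + 10 held-out nights of 2 hours
(240 epochs) each — about 9,600 training epochs, enough for stable
logistic fits and stage coverage while a full benchmark run stays in
minutes on one core. The pre-training comparison fine-tunes on 2 nights
drawn from a 6-night pool, paired over 5 seeds. The missing-segment
experiment uses three 4-hour sessions (so a 120-min removed segment still
leaves context on both sides), durations {5, 30, 75, 120} min × 10 trials.
The closed-loop efficacy comparison runs 20 sequential sessions per arm
(adaptive = Thompson sampling + content switching; control =
uniform-random content with no adaptation) with paired seeds.

## Numerical choices

- Zero-phase filtering throughout (`sosfiltfilt`); Butterworth designs,
  order 4 for analysis bands, cached per (band, rate).
- Viterbi in log space with probabilities floored at 1e-300; transition
  floors (ε = 1e-4) keep unseen transitions decodable.
- Degenerate inputs: zero-power spectra yield uniform relative band powers;
  flat PPG or < 10 beats → invalid HR; accelerometer gravity < 0.3 g →
  invalid posture; empty usable channel set → epoch routed to the
  secondary model / UNSCORED; all-tied consensus votes resolve to the
  technician with the highest mean pairwise agreement, then lowest index.
- EDF is written with fixed physical ranges per modality (±1000 µV ExG,
  ±10 a.u. PPG, ±4 g accelerometer) so 16-bit quantization error is
  data-independent (≈ 0.03 µV for ExG); round trips are exact to that
  quantization. The internal codec exists because no installed library
  both writes EDF and preserves per-modality native rates on read; `mne`
  is used as an independent read oracle in the tests.
- Pure-function determinism: every stochastic component takes either a
  seed or a `numpy.random.Generator`; child streams are derived via
  `SeedSequence` spawning, so outputs are byte-identical across runs.

## Known limitations

- The classifiers are linear in the engineered features; on real data a
  richer family (gradient boosting, small CNNs) would be warranted. The
  warm-start mechanism (early-stopped gradient descent from pretrained
  weights) transfers to any differentiable family.
- The island-removal rule is the only hand rule in the smoother; real
  scoring pipelines typically carry a larger rule set.
- SOL deviation against a reference scorer and the Bland–Altman utilities
  are implemented and tested, but with synthetic data both "scorers" see
  the same generator truth, so those analytics only exercise the
  arithmetic.
- The bandit assumes stationary per-user content effects and known
  observation variance; non-stationary preferences would need a
  forgetting factor.
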