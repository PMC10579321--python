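# somnoloop

Wearable 4-stage sleep scoring and closed-loop acoustic stimulation, with a
synthetic polysomnography simulator for end-to-end testing.

Consumer sleep-aid headbands record a handful of dry-electrode biopotential
channels (EEG/EOG/EMG, collectively "ExG"), photoplethysmography (PPG) and a
3-axis accelerometer, and must score sleep *in real time* so that an audio
program can be stopped the moment the wearer falls asleep. That setting
brings problems clinical polysomnography does not have: electrodes lose skin
contact when the wearer moves, the usable channel set changes from one 30-s
epoch to the next, and whole stretches of a night can have no usable ExG at
all. `somnoloop` implements the full computational stack for this problem,
for researchers and engineers building or evaluating such systems:

- **Quality screening and dynamic re-referencing** — per-epoch, per-channel
  scorability decisions (flatline / saturation / motion / mains-noise / RMS
  screens) and virtual channel derivation with a fallback chain
  (contralateral behind-ear reference → ipsilateral → raw), plus
  availability analytics (per-channel fail ratio, stabilization time).
- **Feature extraction** — relative spectral power over the Delta
  (0.5–4 Hz), Theta (4–8), Alpha (8–13) and Beta (13–30 Hz) bands, spectral
  entropy/edge, sleep-spindle and slow-wave event detectors, EOG and EMG
  band summaries.
- **Two probabilistic classifiers** over the stages {W, LS, DS, REM}: a
  primary model (PML) on ExG features and a secondary model (SML) on
  heart-rate / respiratory-rate / posture / motion features, the latter
  substituting only after the ExG has been continuously unscorable for a
  configurable gap (default 5 min). Warm-start training supports
  pre-training on a large corpus and fine-tuning on a night or two.
- **Offline smoothing** — maximum a posteriori hypnogram decoding (Viterbi)
  under a fitted stage-transition model, with uniform emissions on unscored
  epochs, followed by single-epoch-island removal; every epoch ends up
  scored.
- **Closed-loop stimulation control** — a Probability-of-being-Asleep
  (PoAs) trace `poas_t = α·poas_{t−1} + (1−α)·(1−p_W)`, sleep-onset-latency
  (SOL) detection with a persistence guard, a three-component audio
  timeline (guided breathing voice, relaxation voice, background music)
  with a 50-min cap, Automatic Content Switching when the early PoAs slope
  is too low, and Thompson-sampling content recommendation over
  normal-conjugate preference posteriors rewarded by PoAs slope.
- **A synthetic polysomnography simulator** — Markov hypnograms,
  stage-conditional ExG (alpha bursts and blinks in wake, spindles and
  K-complexes in light sleep, high-amplitude delta in deep sleep, rapid EOG
  deflections in REM), stage-conditional vitals, contact-loss artifacts
  with ground-truth masks, and "virtual sleepers" whose time-to-sleep
  responds to audio content — so the whole stack is testable with no data
  download.
- **Evaluation utilities** — confusion-matrix agreement with Cohen's κ,
  Bland–Altman limits of agreement, MAE/MAPE, SOL deviation summaries,
  one-way ANOVA with Tukey post-hoc.

Recordings are read and written as EDF (channels FH_L, FH_R, OTE_L, OTE_R,
BE_L, BE_R at 200 Hz, PPG, ACC_X/Y/Z); hypnograms as CSV
(`epoch,stage` with stages W/LS/DS/R/U).

## Worked example

Simulate a night and run five closed-loop stimulation sessions on a virtual
sleeper whose true per-content PoAs-slope effects are 0.06 ("calm"), 0.02
("tones") and 0.0 ("rain") per minute:

```sh
$ somnoloop simulate --seed 3 --duration-min 60 --out demo.edf --hypnogram truth.csv
wrote demo.edf (120 epochs)

$ somnoloop closedloop-sim --nights 5 --seed 5 --out cl_logs
SOL minutes per session: 21.5, 29.5, 26.0, 33.5, 20.0
```

Each session log (`cl_logs/session_000.jsonl`) holds one epoch per line —
PoAs value, inferred stage, active content and component gains — and
`cl_logs/posteriors.json` the learned preference posteriors:

```json
"mean": { "calm": 0.0201, "rain": 0.0118, "tones": 0.0157 }
```

After five sessions the bandit already ranks "calm" (the content with the
largest true effect) highest: its posterior mean PoAs slope, 0.020/min, is
the reward the controller measured while that content was playing, and the
posterior variances have shrunk from the diffuse prior (1.0) to ~3e-4. The
SOL line shows the per-session minutes from lights-off to the first
sustained non-wake run (3 epochs); sessions where the sleeper was served
better content fall asleep sooner.

The Python API mirrors the CLI; see `somnoloop.experiments` for the
end-to-end benchmark runners (corpus generation, training, held-out
evaluation, the pre-training comparison and the missing-segment
experiment).

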