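"""Synthetic polysomnography: multimodal nights with known ground truth.

The simulator produces everything the scoring and closed-loop stacks consume
— six-channel ExG, PPG, 3-axis accelerometer, a ground-truth hypnogram, an
artifact mask, and per-epoch vitals truth — with the statistical structure
the pipeline assumes:

* a first-order Markov hypnogram preceded by an initial wake run drawn from a
  truncated normal (the sleep-onset-latency generator);
* stage-conditional ExG phenomenology on a 1/f background: alpha bursts and
  blink-like EOG in wake, 11–16 Hz spindles and K-complexes in light sleep,
  high-amplitude delta in deep sleep, mixed theta plus rapid EOG deflections
  in REM, with stage-dependent broadband EMG;
* a pulse-shaped PPG at stage-conditional heart rate and an accelerometer
  carrying posture gravity plus respiratory modulation;
* contact-loss artifacts (flatline, rail saturation, high-amplitude motion);
* a "virtual sleeper" whose latent sleep propensity drifts toward onset at a
  rate that depends on the audio content being played — the test bed for the
  closed-loop controller.

Every generator is a pure function of (config, seed): identical seeds give
byte-identical outputs.  Per-night inter-subject variability (global and
per-channel amplitude scales) is part of the model — it is what makes
pre-training on many nights genuinely useful to a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .signal_io import (
    EXG_CHANNELS, EPOCH_LEN_S, STAGES, Hypnogram, Recording,
)

STAGE_IDX = {s: i for i, s in enumerate(STAGES)}

#: Default per-epoch stage transition matrix (rows/cols W, LS, DS, R).
DEFAULT_TRANSITIONS = np.array([
    [0.850, 0.130, 0.005, 0.015],
    [0.030, 0.850, 0.080, 0.040],
    [0.010, 0.120, 0.850, 0.020],
    [0.040, 0.100, 0.010, 0.850],
])

DEFAULT_AMPLITUDES = {
    "alpha_uv": 20.0,      # 8-13 Hz bursts in wake
    "spindle_uv": 30.0,    # 11-16 Hz bursts in light sleep
    "kcomplex_uv": 90.0,   # biphasic transient, light sleep
    "delta_uv": 80.0,      # 0.5-2 Hz waves in deep sleep
    "theta_uv": 15.0,      # mixed-frequency background, REM/LS
    "rem_eog_uv": 70.0,    # rapid eye-movement deflections
    "blink_uv": 100.0,     # wake blinks (<4 Hz EOG)
    "emg_uv": 5.0,         # broadband muscle tone, scaled by stage
}

DEFAULT_HR_BY_STAGE = {"W": (70.0, 3.0), "LS": (62.0, 2.0),
                       "DS": (57.0, 2.0), "R": (68.0, 3.0)}
DEFAULT_RR_BY_STAGE = {"W": (15.0, 1.0), "LS": (13.0, 0.8),
                       "DS": (12.0, 0.6), "R": (16.0, 1.2)}

#: Canonical gravity directions (unit vectors, device frame) per posture.
POSTURE_VECTORS = {
    "supine": np.array([0.0, 0.0, 1.0]),
    "prone": np.array([0.0, 0.0, -1.0]),
    "left": np.array([0.0, 1.0, 0.0]),
    "right": np.array([0.0, -1.0, 0.0]),
    "upright": np.array([1.0, 0.0, 0.0]),
}

#: EOG coupling per channel: blinks and eye movements project mostly onto the
#: forehead electrodes, weakly behind the ear.
_EOG_GAIN = {"FH_L": 1.0, "FH_R": 1.0, "OTE_L": 0.3, "OTE_R": 0.3,
             "BE_L": 0.15, "BE_R": 0.15}
#: Cortical oscillation coupling per site: the behind-the-ear sites act as
#: references and see far weaker brain activity, so re-referenced virtual
#: channels (FH-BE, OTE-BE) retain most of the oscillatory content.
_OSC_GAIN = {"FH_L": 1.0, "FH_R": 1.0, "OTE_L": 0.9, "OTE_R": 0.9,
             "BE_L": 0.25, "BE_R": 0.25}
_EMG_GAIN_BY_STAGE = {"W": 1.0, "LS": 0.4, "DS": 0.25, "R": 0.08}


@dataclass
class SimConfig:
    """All knobs of the night simulator; ``seed`` fixes every random draw."""

    seed: int = 0
    duration_min: float = 480.0
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_wake_run_min: tuple[float, float] = (15.0, 5.0)  # mean, sd
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    noise_uv: float = 10.0
    artifact_rate: float = 1.0          # contact-loss events / hour / channel
    hr_by_stage: dict = field(default_factory=lambda: dict(DEFAULT_HR_BY_STAGE))
    rr_by_stage: dict = field(default_factory=lambda: dict(DEFAULT_RR_BY_STAGE))
    posture_change_prob: float = 0.1    # per wake epoch
    movement_burst_prob: float = 0.25   # per wake epoch, accelerometer burst
    subject_scale_sd: float = 0.15      # log-sd of per-night amplitude scale
    exg_rate: float = 200.0
    ppg_rate: float = 64.0
    acc_rate: float = 50.0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (4, 4) or np.any(tm < 0):
            raise ValueError("transition_matrix must be 4x4 non-negative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition_matrix rows must sum to 1")
        self.transition_matrix = tm

    @property
    def n_epochs(self) -> int:
        return int(self.duration_min * 60 // EPOCH_LEN_S)


@dataclass
class ArtifactMask:
    """Epoch × channel corruption grid plus the underlying events."""

    mask: np.ndarray                      # bool, (n_epochs, 6)
    kinds: list[tuple[str, str, float, float]]  # (channel, kind, start_s, dur_s)

    def channel_mask(self, channel: str) -> np.ndarray:
        return self.mask[:, EXG_CHANNELS.index(channel)]


@dataclass
class VirtualSleeper:
    """Latent-propensity model of a user falling asleep under stimulation.

    Propensity x starts at 0 and drifts at ``relax_rate`` plus the effect of
    the audio content currently playing (both per minute); ``effect_sd``
    scales the diffusion term.  Sleep-stage emissions are a two-sigmoid
    function of x, so the probability-of-asleep trace shows the
    characteristic three-part profile: early rise as the user relaxes, a
    plateau, then a final rise past 0.8 at sleep onset.
    """

    baseline_sol_min: float = 40.0
    content_effect: dict[str, float] = field(default_factory=dict)
    effect_sd: float = 0.05
    relax_rate: float = 0.05
    sleep_split: tuple[float, float, float] = (0.85, 0.08, 0.07)  # LS, DS, R

    def __post_init__(self) -> None:
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")

    @property
    def onset_threshold(self) -> float:
        # unstimulated drift relax_rate crosses threshold at baseline SOL
        return self.relax_rate * self.baseline_sol_min

    def emission(self, propensity: float) -> np.ndarray:
        """Stage distribution (W, LS, DS, R) for a latent propensity."""
        th = self.onset_threshold
        relax = 1.0 / (1.0 + np.exp(-(propensity - 0.3 * th) / (0.15 * th)))
        onset = 1.0 / (1.0 + np.exp(-(propensity - th) / (0.08 * th)))
        p_sleep = np.clip(0.3 * relax + 0.7 * onset, 0.0, 1.0)
        ls, ds, r = self.sleep_split
        return np.array([1.0 - p_sleep, p_sleep * ls, p_sleep * ds, p_sleep * r])


def _rng(config_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), tag]))


# ---------------------------------------------------------------------------
# Hypnogram

def simulate_hypnogram(config: SimConfig) -> Hypnogram:
    """Initial wake run (truncated-normal SOL, >= 1 epoch) then a Markov chain."""
    rng = _rng(config.seed, 1)
    n = config.n_epochs
    if n < 1:
        raise ValueError("duration shorter than one epoch")
    tm = config.transition_matrix
    exit_w = 1.0 - tm[0, 0]
    if exit_w <= 0:
        warnings.warn("wake is absorbing in the transition matrix", stacklevel=2)
    mean, sd = config.initial_wake_run_min
    sol_min = max(0.5, rng.normal(mean, sd))
    wake_run = max(1, int(round(sol_min * 60 / EPOCH_LEN_S)))
    wake_run = min(wake_run, n)
    states = [0] * wake_run
    # enter sleep through the wake row's exit distribution (or stay W if absorbing)
    if wake_run < n:
        if exit_w > 0:
            first = rng.choice(4, p=np.r_[0.0, tm[0, 1:]] / exit_w)
        else:
            first = 0
        states.append(int(first))
        while len(states) < n:
            states.append(int(rng.choice(4, p=tm[states[-1]])))
    return Hypnogram([STAGES[i] for i in states[:n]])


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary stage distribution of the chain, by eigen-analysis."""
    w, v = np.linalg.eig(np.asarray(transition_matrix, float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# ExG synthesis

def _burst(t: np.ndarray, t0: float, dur: float, freq: float, amp: float,
           phase: float) -> np.ndarray:
    """Hann-windowed sinusoid burst starting at t0."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t < t0 + dur)
    if inside.any():
        x = (t[inside] - t0) / dur
        w[inside] = amp * np.sin(2 * np.pi * freq * (t[inside] - t0) + phase) \
            * 0.5 * (1 - np.cos(2 * np.pi * x))
    return w


def _biphasic(t: np.ndarray, t0: float, dur: float, amp: float) -> np.ndarray:
    """Single-cycle biphasic transient (K-complex-like): down then up."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t < t0 + dur)
    if inside.any():
        x = (t[inside] - t0) / dur
        w[inside] = -amp * np.sin(2 * np.pi * x) * np.sin(np.pi * x)
    return w


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                rms: float) -> np.ndarray:
    """1/f-power background noise with the requested RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phase = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n)
    x *= rms / max(np.std(x), 1e-12)
    return x


def _epoch_sources(stage: str, rng: np.random.Generator, t: np.ndarray,
                   amps: dict) -> tuple[np.ndarray, np.ndarray, float]:
    """(oscillatory EEG, EOG component, EMG gain) for one 30-s epoch."""
    osc = np.zeros_like(t)
    eog = np.zeros_like(t)
    if stage == "W":
        for _ in range(rng.poisson(4)):
            osc += _burst(t, rng.uniform(0, 27), rng.uniform(1, 3),
                          rng.uniform(8, 13), amps["alpha_uv"],
                          rng.uniform(0, 2 * np.pi))
        for _ in range(rng.poisson(3)):
            eog += _biphasic(t, rng.uniform(0, 29), rng.uniform(0.2, 0.5),
                             amps["blink_uv"])
    elif stage == "LS":
        for _ in range(rng.poisson(1.5)):   # 3 spindles/min
            osc += _burst(t, rng.uniform(0, 27), rng.uniform(0.5, 2.0),
                          rng.uniform(11, 16), amps["spindle_uv"],
                          rng.uniform(0, 2 * np.pi))
        if rng.random() < 0.3:
            osc += _biphasic(t, rng.uniform(0, 28), rng.uniform(0.8, 1.5),
                             amps["kcomplex_uv"])
        osc += amps["theta_uv"] * 0.7 * np.sin(
            2 * np.pi * rng.uniform(4, 7) * t + rng.uniform(0, 2 * np.pi))
    elif stage == "DS":
        env = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.02, 0.05) * t
                                 + rng.uniform(0, 2 * np.pi))
        osc += amps["delta_uv"] * env * np.sin(
            2 * np.pi * rng.uniform(0.6, 1.8) * t + rng.uniform(0, 2 * np.pi))
    elif stage == "R":
        osc += amps["theta_uv"] * np.sin(
            2 * np.pi * rng.uniform(4, 8) * t + rng.uniform(0, 2 * np.pi))
        for _ in range(rng.poisson(5)):
            eog += _biphasic(t, rng.uniform(0, 29), rng.uniform(0.3, 0.7),
                             amps["rem_eog_uv"])
    return osc, eog, _EMG_GAIN_BY_STAGE[stage]


def subject_gains(config: SimConfig) -> tuple[float, dict[str, float]]:
    """Per-night global amplitude scale and per-channel gains (seeded)."""
    rng = _rng(config.seed, 2)
    global_scale = float(np.exp(rng.normal(0.0, config.subject_scale_sd)))
    gains = {ch: float(np.exp(rng.normal(0.0, 0.05))) for ch in EXG_CHANNELS}
    return global_scale, gains


def synthesize_exg(hypnogram: Hypnogram, config: SimConfig) -> Recording:
    """Stage-conditional six-channel ExG on a 1/f background (microvolts)."""
    rng = _rng(config.seed, 3)
    rate = config.exg_rate
    n_ep = len(hypnogram)
    n_samp = int(round(rate * EPOCH_LEN_S))
    t = np.arange(n_samp) / rate
    scale, ch_gain = subject_gains(config)
    amps = {k: v * scale for k, v in config.amplitudes.items()}

    total = n_ep * n_samp
    chans = {ch: _pink_noise(rng, total, rate, config.noise_uv * scale)
             for ch in EXG_CHANNELS}
    for i, stage in enumerate(hypnogram):
        osc, eog, emg_gain = _epoch_sources(stage, rng, t, amps)
        sl = slice(i * n_samp, (i + 1) * n_samp)
        for ch in EXG_CHANNELS:
            # muscle noise is local to each electrode, not a shared source
            emg = rng.normal(0.0, amps["emg_uv"] * emg_gain, n_samp)
            chans[ch][sl] += ch_gain[ch] * (_OSC_GAIN[ch] * osc
                                            + _EOG_GAIN[ch] * eog) + emg
    return Recording(exg=chans, exg_rate=rate, ppg_rate=config.ppg_rate,
                     acc_rate=config.acc_rate,
                     meta={"seed": config.seed})


# ---------------------------------------------------------------------------
# Vitals synthesis

@dataclass
class VitalsTruth:
    """Per-epoch ground truth emitted alongside the synthetic traces."""

    hr_bpm: np.ndarray
    rr_brpm: np.ndarray
    posture: list[str]
    movement: np.ndarray  # bool, epochs containing a movement burst


def synthesize_vitals(hypnogram: Hypnogram,
                      config: SimConfig) -> tuple[np.ndarray, np.ndarray, VitalsTruth]:
    """PPG pulse train + accelerometer (gravity, respiration, movement)."""
    rng = _rng(config.seed, 4)
    n_ep = len(hypnogram)
    subj_hr = rng.normal(0.0, 2.0)
    subj_rr = rng.normal(0.0, 0.5)

    hr = np.empty(n_ep)
    rr = np.empty(n_ep)
    for i, stage in enumerate(hypnogram):
        key = stage if stage in config.hr_by_stage else "W"
        m, s = config.hr_by_stage[key]
        hr[i] = m + subj_hr + rng.normal(0.0, s)
        m, s = config.rr_by_stage[key]
        rr[i] = m + subj_rr + rng.normal(0.0, s)
    # smooth epoch-to-epoch wander (vitals do not jump instantaneously)
    for x in (hr, rr):
        for i in range(1, n_ep):
            x[i] = 0.5 * x[i - 1] + 0.5 * x[i]

    # --- PPG: phase-integrated pulse train at instantaneous HR
    fs_p = config.ppg_rate
    n_p = int(round(n_ep * EPOCH_LEN_S * fs_p))
    hr_inst = np.repeat(hr, int(round(EPOCH_LEN_S * fs_p)))
    jitter = rng.normal(0.0, 0.02 * hr_inst.mean(), n_p)
    jitter = np.convolve(jitter, np.ones(int(fs_p)) / fs_p, mode="same")
    phase = np.cumsum((hr_inst + jitter) / 60.0) / fs_p
    ppg = np.exp(3.0 * (np.cos(2 * np.pi * phase) - 1.0))
    ppg += rng.normal(0.0, 0.02, n_p)

    # --- ACC: posture gravity + respiration + wake movement bursts
    fs_a = config.acc_rate
    ep_a = int(round(EPOCH_LEN_S * fs_a))
    n_a = n_ep * ep_a
    postures = list(POSTURE_VECTORS)
    cur = "supine"
    posture_seq = []
    movement = np.zeros(n_ep, dtype=bool)
    acc = np.empty((n_a, 3))
    rr_inst = np.repeat(rr, ep_a)
    resp_phase = np.cumsum(rr_inst / 60.0) / fs_a
    resp = 0.01 * np.sin(2 * np.pi * resp_phase)
    for i, stage in enumerate(hypnogram):
        if stage == "W" and rng.random() < config.posture_change_prob:
            cur = postures[rng.integers(len(postures) - 1)]  # exclude upright
        posture_seq.append(cur)
        g = POSTURE_VECTORS[cur]
        sl = slice(i * ep_a, (i + 1) * ep_a)
        seg = np.outer(np.ones(ep_a), g)
        # respiration modulates the axes orthogonal to gravity
        ortho = np.array([g[1] - g[2], g[2] - g[0], g[0] - g[1]])
        nrm = np.linalg.norm(ortho)
        ortho = ortho / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        seg += np.outer(resp[sl], ortho)
        seg += rng.normal(0.0, 0.003, (ep_a, 3))
        if stage == "W" and rng.random() < config.movement_burst_prob:
            movement[i] = True
            b0 = int(rng.integers(0, ep_a - int(3 * fs_a)))
            blen = min(int(rng.uniform(2, 5) * fs_a), ep_a - b0)
            seg[b0:b0 + blen] += rng.normal(0.0, 0.3, (blen, 3))
        acc[sl] = seg
    return ppg, acc, VitalsTruth(hr_bpm=hr, rr_brpm=rr, posture=posture_seq,
                                 movement=movement)


# ---------------------------------------------------------------------------
# Artifacts

ARTIFACT_KINDS = ("flatline", "saturation", "high-amplitude-motion")
SATURATION_RAIL_UV = 1000.0


def inject_artifacts(recording: Recording,
                     config: SimConfig) -> tuple[Recording, ArtifactMask]:
    """Contact-loss events per channel at ``artifact_rate`` per hour.

    Each event replaces samples with a flatline, rail saturation, or
    high-amplitude motion noise for a log-uniform duration of 30 s – 20 min.
    A mask cell (epoch, channel) is set when the event covers at least half
    of that epoch.  The input recording is left unmodified.
    """
    rng = _rng(config.seed, 5)
    rate = recording.exg_rate
    n_ep = recording.n_epochs
    dur_s = recording.duration_s
    exg = {ch: v.copy() for ch, v in recording.exg.items()}
    mask = np.zeros((n_ep, len(EXG_CHANNELS)), dtype=bool)
    events: list[tuple[str, str, float, float]] = []
    hours = dur_s / 3600.0
    for ci, ch in enumerate(EXG_CHANNELS):
        for _ in range(rng.poisson(config.artifact_rate * hours)):
            dur = float(np.exp(rng.uniform(np.log(30.0), np.log(1200.0))))
            t0 = float(rng.uniform(0.0, max(dur_s - dur, 0.0)))
            kind = ARTIFACT_KINDS[rng.integers(len(ARTIFACT_KINDS))]
            _apply_event(exg[ch], rate, t0, dur, kind, rng)
            events.append((ch, kind, t0, dur))
            e0, e1 = t0 / EPOCH_LEN_S, (t0 + dur) / EPOCH_LEN_S
            for ep in range(int(e0), min(int(np.ceil(e1)), n_ep)):
                overlap = min(e1, ep + 1) - max(e0, ep)
                if overlap >= 0.5:
                    mask[ep, ci] = True
    out = Recording(exg=exg, exg_rate=rate, ppg=recording.ppg,
                    ppg_rate=recording.ppg_rate, acc=recording.acc,
                    acc_rate=recording.acc_rate, start_time=recording.start_time,
                    meta=dict(recording.meta))
    return out, ArtifactMask(mask=mask, kinds=events)


def _apply_event(x: np.ndarray, rate: float, t0: float, dur: float,
                 kind: str, rng: np.random.Generator) -> None:
    i0 = int(round(t0 * rate))
    i1 = min(int(round((t0 + dur) * rate)), len(x))
    n = i1 - i0
    if n <= 0:
        return
    if kind == "flatline":
        x[i0:i1] = x[i0]
    elif kind == "saturation":
        t = np.arange(n) / rate
        x[i0:i1] = SATURATION_RAIL_UV * np.sign(
            np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)) + 1e-9)
    else:  # high-amplitude motion
        lf = rng.normal(0.0, 1.0, n)
        k = max(int(rate * 0.25), 1)
        lf = np.convolve(lf, np.ones(k) / k, mode="same")
        x[i0:i1] += 800.0 * lf / max(np.std(lf), 1e-12)


# ---------------------------------------------------------------------------
# Closed-loop virtual sleeper

def simulate_closed_loop_step(
        sleeper: VirtualSleeper, current_content: str | None,
        propensity: float, rng: np.random.Generator,
        dt_min: float = EPOCH_LEN_S / 60.0) -> tuple[float, np.ndarray]:
    """One epoch of the sleeper's drift–diffusion propensity process.

    Returns the next latent propensity and the emitted stage distribution
    (W, LS, DS, R).  ``current_content=None`` models silence (no stimulation
    effect).  Unknown content ids raise.
    """
    if current_content is None:
        effect = 0.0
    else:
        if current_content not in sleeper.content_effect:
            raise KeyError(f"unknown audio content {current_content!r}")
        effect = sleeper.content_effect[current_content]
    drift = sleeper.relax_rate + effect
    nxt = propensity + drift * dt_min \
        + sleeper.effect_sd * np.sqrt(dt_min) * rng.standard_normal()
    return float(nxt), sleeper.emission(nxt)


# ---------------------------------------------------------------------------
# Convenience: a whole night in one call

@dataclass
class SyntheticNight:
    """A full simulated night: signals, truth, and the artifact mask."""

    config: SimConfig
    hypnogram: Hypnogram
    recording: Recording          # artifact-corrupted signals
    clean_recording: Recording    # pre-artifact ExG
    mask: ArtifactMask
    vitals_truth: VitalsTruth


def simulate_night(config: SimConfig) -> SyntheticNight:
    """Generate hypnogram, ExG, vitals and artifacts for one night."""
    hyp = simulate_hypnogram(config)
    clean = synthesize_exg(hyp, config)
    ppg, acc, truth = synthesize_vitals(hyp, config)
    clean.ppg, clean.acc = ppg, acc
    corrupted, mask = inject_artifacts(clean, config)
    return SyntheticNight(config=config, hypnogram=hyp, recording=corrupted,
                          clean_recording=clean, mask=mask, vitals_truth=truth)
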