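"""Closed-loop acoustic stimulation: PoAs, SOL detection, audio control.

The controller runs once per 30-s epoch.  A Probability-of-being-Asleep
(PoAs) trace — an exponentially weighted moving average of the scored
probability of not being awake — summarizes the user's sleep progress; its
slope over a trailing window drives two adaptive mechanisms:

* Automatic Content Switching (ACS): within the first 20 minutes, if the
  PoAs slope is below threshold, the background-music content is switched.
* Audio Content Recommendation (ACR): a Thompson-sampling multi-armed
  bandit over normal value posteriors, one per audio content, rewarded by
  the PoAs rate of change while that content played.  The most recently
  used content is excluded from a recommendation.

Audio follows a three-component timeline (guided breathing voice, relaxation
therapy voice, background music) and is cut the moment sleep onset is
detected or a 50-minute cap elapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import EPOCH_LEN_S, STAGES, UNSCORED
from .synthetic_psg import VirtualSleeper, simulate_closed_loop_step

EPOCH_MIN = EPOCH_LEN_S / 60.0
SESSION_CAP_MIN = 50.0


# ---------------------------------------------------------------------------
# PoAs

@dataclass
class PoAsTrace:
    """EWMA trace of the probability of being asleep, one value per epoch."""

    alpha: float = 0.8
    slope_window_min: float = 5.0
    values: list[float] = field(default_factory=list)

    def last(self) -> float:
        return self.values[-1] if self.values else 0.0


def update_poas(trace: PoAsTrace, dist: np.ndarray | None) -> PoAsTrace:
    """Append one epoch: ``poas_t = a*poas_{t-1} + (1-a)*(1 - p_w)``.

    ``dist`` is the scored stage distribution (W, LS, DS, R) or None for an
    UNSCORED epoch, which carries the previous value forward.  The trace
    starts at 0.
    """
    prev = trace.last()
    if dist is None or np.isnan(np.asarray(dist, dtype=float)).any():
        val = prev
    else:
        p_w = float(np.asarray(dist, dtype=float)[0])
        val = trace.alpha * prev + (1.0 - trace.alpha) * (1.0 - p_w)
    trace.values.append(float(np.clip(val, 0.0, 1.0)))
    return trace


def poas_slope(trace: PoAsTrace, window_min: float | None = None) -> float | None:
    """Least-squares slope (per minute) over the trailing window; None if
    the trace does not yet cover the window."""
    w = window_min if window_min is not None else trace.slope_window_min
    n = int(round(w / EPOCH_MIN))
    if len(trace.values) < n or n < 2:
        return None
    y = np.asarray(trace.values[-n:])
    t = np.arange(n) * EPOCH_MIN
    t = t - t.mean()
    return float((t @ (y - y.mean())) / (t @ t))


# ---------------------------------------------------------------------------
# Sleep-onset detection

def detect_sol(stages: list[str], k: int = 3) -> int | None:
    """First epoch index starting a run of >= k consecutive non-wake epochs.

    ``k`` is a persistence guard against single-epoch blips; ``k=1`` is the
    literal first-non-W rule.  Returns None when no such run exists (the
    caller converts epochs to minutes at 0.5 min/epoch).
    """
    run_start = None
    run_len = 0
    for i, s in enumerate(stages):
        if s != "W" and s != UNSCORED:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len >= k:
                return run_start
        else:
            run_start, run_len = None, 0
    return None


# ---------------------------------------------------------------------------
# Audio timeline

@dataclass
class AudioContent:
    """One audio asset: component timeline for GBV, RTV and BM (minutes)."""

    content_id: str
    t0_min: float = 0.0      # GBV + BM on
    t1_min: float = 8.0      # GBV out, RTV in
    t2_min: float = 16.0     # RTV out, BM alone then fades
    fade_min: float = 0.5

    def __post_init__(self) -> None:
        if not (self.t0_min <= self.t1_min <= self.t2_min):
            raise ValueError("timeline must satisfy t0 <= t1 <= t2")
        if self.fade_min < 0:
            raise ValueError("fade must be non-negative")


def _fade_out(now: float, t_end: float, fade: float) -> float:
    if now <= t_end - fade:
        return 1.0
    if now >= t_end or fade == 0:
        return 0.0
    return (t_end - now) / fade


def schedule_audio(content: AudioContent, now_min: float,
                   sol_detected: bool = False,
                   cap_min: float = SESSION_CAP_MIN) -> np.ndarray:
    """Component gain vector (GBV, RTV, BM), each in [0, 1].

    GBV plays from t0 and fades out ending at t1; RTV plays on [t1, t2];
    BM plays from t0, is the sole component after t2 and fades slowly
    thereafter.  All gains are 0 once SOL is detected or the cap elapsed.
    """
    if now_min < 0:
        raise ValueError("now_min must be >= 0")
    if sol_detected or now_min >= cap_min:
        return np.zeros(3)
    c = content
    gbv = _fade_out(now_min, c.t1_min, c.fade_min) if now_min >= c.t0_min else 0.0
    rtv = 1.0 if c.t1_min <= now_min < c.t2_min else 0.0
    if now_min < c.t0_min:
        bm = 0.0
    elif now_min < c.t2_min:
        bm = 1.0
    else:
        bm = _fade_out(now_min, cap_min, cap_min - c.t2_min)
    return np.array([gbv, rtv, bm])


# ---------------------------------------------------------------------------
# Automatic content switching

ACS_WINDOW_MIN = 20.0


def acs_should_switch(slope: float | None, elapsed_min: float,
                      min_since_switch: float,
                      threshold: float = 0.01,
                      dwell_min: float = 5.0) -> bool:
    """Switch iff within the first 20 min, the slope is defined and below
    threshold, and the dwell since the last switch has passed."""
    if slope is None:
        return False
    return (elapsed_min <= ACS_WINDOW_MIN and slope < threshold
            and min_since_switch >= dwell_min)


# ---------------------------------------------------------------------------
# Audio content recommendation (Thompson sampling)

@dataclass
class PreferencePosterior:
    """Normal value posteriors per content, known observation variance."""

    mean: dict[str, float]
    var: dict[str, float]
    obs_var: float = 1e-3            # reward (slope) observation variance
    count: dict[str, int] = field(default_factory=dict)

    @classmethod
    def diffuse(cls, content_ids: list[str], prior_var: float = 1.0,
                obs_var: float = 1e-3) -> "PreferencePosterior":
        return cls(mean={c: 0.0 for c in content_ids},
                   var={c: prior_var for c in content_ids},
                   obs_var=obs_var,
                   count={c: 0 for c in content_ids})


def acr_update(post: PreferencePosterior, content_id: str,
               reward: float) -> PreferencePosterior:
    """Conjugate normal update with known observation variance.

    ``var_new = 1/(1/var + 1/obs_var)``;
    ``mean_new = var_new * (mean/var + reward/obs_var)``.
    Variance strictly decreases with every observation.
    """
    if content_id not in post.mean:
        raise KeyError(f"unknown audio content {content_id!r}")
    v, m = post.var[content_id], post.mean[content_id]
    v_new = 1.0 / (1.0 / v + 1.0 / post.obs_var)
    m_new = v_new * (m / v + reward / post.obs_var)
    mean = dict(post.mean)
    var = dict(post.var)
    count = dict(post.count)
    mean[content_id], var[content_id] = m_new, v_new
    count[content_id] = count.get(content_id, 0) + 1
    return PreferencePosterior(mean=mean, var=var, obs_var=post.obs_var,
                               count=count)


def acr_recommend(post: PreferencePosterior, last_content: str | None,
                  rng: np.random.Generator) -> str:
    """Thompson sampling: draw from each eligible posterior, take the argmax.

    The most recently used content is excluded; with ``last_content=None``
    every content is eligible.  A single-content catalog with an exclusion
    raises (nothing left to recommend).
    """
    eligible = [c for c in post.mean if c != last_content]
    if not eligible:
        raise ValueError("catalog too small to exclude the last content")
    samples = {c: rng.normal(post.mean[c], np.sqrt(post.var[c]))
               for c in eligible}
    return max(samples, key=samples.get)


# ---------------------------------------------------------------------------
# Session runner

@dataclass
class EpochLog:
    epoch: int
    poas: float
    stage: str
    source: str
    content: str | None
    gains: tuple[float, float, float]
    switched: bool


@dataclass
class SessionLog:
    """One closed-loop sleep session: per-epoch records plus outcomes."""

    epochs: list[EpochLog]
    sol_epoch: int | None
    audio_off_epoch: int | None      # epoch at which all gains became 0
    stop_reason: str                 # sol_detected | cap_50min | session_end
    content_intervals: list[tuple[str, int, int]]  # (content, start_ep, end_ep)
    rewards: dict[str, float]

    @property
    def sol_min(self) -> float | None:
        return None if self.sol_epoch is None else self.sol_epoch * EPOCH_MIN


@dataclass
class ControllerConfig:
    """Closed-loop policy knobs."""

    poas_alpha: float = 0.8
    slope_window_min: float = 5.0
    acs_threshold: float = 0.01      # PoAs slope per minute
    acs_dwell_min: float = 5.0
    sol_guard_epochs: int = 3
    session_cap_min: float = SESSION_CAP_MIN
    max_epochs: int = 160            # simulate up to 80 min
    policy: str = "acr"              # "acr" | "random" | "fixed"
    use_acs: bool = True


def _interval_slope(poas: list[float], start_ep: int, end_ep: int) -> float | None:
    if end_ep - start_ep < 2:
        return None
    y = np.asarray(poas[start_ep:end_ep])
    t = np.arange(len(y)) * EPOCH_MIN
    t = t - t.mean()
    return float((t @ (y - y.mean())) / (t @ t))


def run_session(config: ControllerConfig, sleeper: VirtualSleeper,
                catalog: list[AudioContent], post: PreferencePosterior,
                seed: int, last_content: str | None = None
                ) -> tuple[SessionLog, PreferencePosterior]:
    """Simulate one closed-loop session on a virtual sleeper.

    Per epoch: sleeper step → stage distribution → PoAs update → ACS/ACR →
    audio gains.  Audio stops at detected sleep onset or the 50-min cap.
    Per-content rewards (PoAs slope over each play interval) update the
    preference posteriors at session end.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(seed)
    by_id = {c.content_id: c for c in catalog}

    if config.policy == "acr":
        current = acr_recommend(post, last_content, rng) if len(by_id) > 1 \
            else next(iter(by_id))
    elif config.policy == "random":
        current = str(rng.choice(sorted(by_id)))
    else:
        current = catalog[0].content_id

    trace = PoAsTrace(alpha=config.poas_alpha,
                      slope_window_min=config.slope_window_min)
    propensity = 0.0
    stages: list[str] = []
    logs: list[EpochLog] = []
    intervals: list[tuple[str, int, int]] = []
    cur_start = 0
    content_t0 = 0.0                # timeline restarts on a switch
    sol_epoch: int | None = None
    audio_off_epoch: int | None = None
    audio_on = True
    stop_reason = "session_end"

    for ep in range(config.max_epochs):
        now = ep * EPOCH_MIN
        content_for_step = current if audio_on else None
        propensity, dist = simulate_closed_loop_step(
            sleeper, content_for_step, propensity, rng)
        stage = STAGES[int(np.argmax(dist))]
        stages.append(stage)
        trace = update_poas(trace, dist)

        if sol_epoch is None:
            sol_epoch = detect_sol(stages, k=config.sol_guard_epochs)
            if sol_epoch is not None and audio_on:
                audio_on = False
                audio_off_epoch = ep
                stop_reason = "sol_detected"
                intervals.append((current, cur_start, ep + 1))
        if audio_on and now >= config.session_cap_min:
            audio_on = False
            audio_off_epoch = ep
            stop_reason = "cap_50min"
            intervals.append((current, cur_start, ep))

        switched = False
        if audio_on and config.use_acs and len(by_id) > 1:
            slope = poas_slope(trace)
            since = now - content_t0
            if acs_should_switch(slope, now, since,
                                 threshold=config.acs_threshold,
                                 dwell_min=config.acs_dwell_min):
                intervals.append((current, cur_start, ep + 1))
                if config.policy == "random":
                    nxt = str(rng.choice([c for c in sorted(by_id)
                                          if c != current]))
                else:
                    nxt = acr_recommend(post, current, rng)
                current = nxt
                cur_start = ep + 1
                content_t0 = (ep + 1) * EPOCH_MIN
                switched = True

        if audio_on:
            gains = schedule_audio(by_id[current], max(now - content_t0, 0.0),
                                   sol_detected=False,
                                   cap_min=config.session_cap_min)
        else:
            gains = np.zeros(3)
        logs.append(EpochLog(epoch=ep, poas=trace.values[-1], stage=stage,
                             source="primary", content=current if audio_on else None,
                             gains=tuple(float(g) for g in gains),
                             switched=switched))
        if sol_epoch is not None and ep >= sol_epoch + 10:
            break
    if audio_on:
        intervals.append((current, cur_start, len(stages)))

    rewards: dict[str, float] = {}
    for content, a, b in intervals:
        slope = _interval_slope(trace.values, a, b)
        if slope is not None:
            rewards[content] = rewards.get(content, 0.0) + slope
    new_post = post
    if config.policy == "acr":
        for content, r in rewards.items():
            new_post = acr_update(new_post, content, r)
    log = SessionLog(epochs=logs, sol_epoch=sol_epoch,
                     audio_off_epoch=audio_off_epoch, stop_reason=stop_reason,
                     content_intervals=intervals, rewards=rewards)
    return log, new_post
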