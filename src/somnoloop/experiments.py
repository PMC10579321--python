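"""End-to-end synthetic benchmarks: corpus generation, training, evaluation.

These runners tie the simulator to the scoring stack the way a validation
study would: generate a corpus of independent synthetic nights (each night a
different "subject" — its own amplitude scales, vitals offsets and artifact
realization), extract ExG and vitals features, train the primary and
secondary classifiers on a training split, and measure held-out agreement
with the generator's ground-truth hypnograms.

Problem sizes are deliberately modest — 2-hour nights for the staging
corpus, 4-hour sessions for the missing-segment experiment — enough epochs
for stable estimates while keeping a full benchmark run in minutes on one
core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Hypnogram, stage_indices
from .staging import (StagingModel, TransitionModel, fit_transitions,
                      fuse_realtime, night_exg_features, predict_primary,
                      predict_secondary, sml_features, smooth_offline,
                      train_primary, train_secondary)
from .synthetic_psg import SimConfig, SyntheticNight, simulate_night
from .vitals import extract_vitals
from .evaluation import agreement


@dataclass
class NightData:
    """One simulated night reduced to what the classifiers consume.

    Raw signals are dropped by default — a corpus of nights would otherwise
    hold gigabytes of waveform data; ``night`` is populated only when
    ``build_night(..., keep_signals=True)``.
    """

    truth: Hypnogram
    artifact_mask: np.ndarray      # (n, 6) bool, injected ground truth
    detected_bad: np.ndarray       # (n, 6) bool, quality screen output
    X_exg: np.ndarray              # (n, f) primary features, NaN if unscorable
    exg_scorable: np.ndarray       # (n,) bool
    X_sml: np.ndarray              # (n, f) vitals context features
    labels: np.ndarray             # (n,) ground-truth stage codes
    night: SyntheticNight | None = None


def build_night(config: SimConfig, scheme: str = "dynamic",
                keep_signals: bool = False) -> NightData:
    """Simulate one night and extract both feature streams."""
    night = simulate_night(config)
    X, scorable, report = night_exg_features(night.recording, scheme=scheme)
    vit = extract_vitals(night.recording)
    X_sml = sml_features(vit)
    labels = stage_indices(night.hypnogram.stages)
    return NightData(truth=night.hypnogram,
                     artifact_mask=night.mask.mask.copy(),
                     detected_bad=~report.scorable_matrix,
                     X_exg=X, exg_scorable=scorable,
                     X_sml=X_sml, labels=labels,
                     night=night if keep_signals else None)


def build_corpus(n_nights: int, seed: int, duration_min: float = 120.0,
                 scheme: str = "dynamic", keep_signals: bool = False,
                 **config_kwargs) -> list[NightData]:
    """Independent nights; night i uses seed ``seed*10000 + i``."""
    out = []
    for i in range(n_nights):
        cfg = SimConfig(seed=seed * 10000 + i, duration_min=duration_min,
                        **config_kwargs)
        out.append(build_night(cfg, scheme=scheme, keep_signals=keep_signals))
    return out


def _stack(nights: list[NightData], attr: str) -> np.ndarray:
    return np.concatenate([getattr(n, attr) for n in nights])


def train_models(nights: list[NightData], seed: int = 0,
                 init_primary: StagingModel | None = None
                 ) -> tuple[StagingModel, StagingModel, TransitionModel]:
    """Train PML, SML and the transition model on a corpus."""
    pml = train_primary(_stack(nights, "X_exg"), _stack(nights, "labels"),
                        init=init_primary, seed=seed)
    sml = train_secondary(_stack(nights, "X_sml"), _stack(nights, "labels"),
                          seed=seed)
    transitions = fit_transitions([n.truth for n in nights])
    return pml, sml, transitions


@dataclass
class StagingBenchmark:
    """Held-out agreement of the staging stack with generator truth."""

    primary_accuracy: float
    primary_kappa: float
    secondary_accuracy: float
    smoothed_accuracy: float
    percent_scorable: float


def evaluate_staging(pml: StagingModel, sml: StagingModel,
                     transitions: TransitionModel,
                     test_nights: list[NightData]) -> StagingBenchmark:
    """Score held-out nights with PML alone, SML alone, and the smoothed fusion."""
    acc_p, kap_p, acc_s, acc_sm, scor = [], [], [], [], []
    for nd in test_nights:
        p = predict_primary(pml, nd.X_exg, nd.exg_scorable)
        s = predict_secondary(sml, nd.X_sml)
        fused, _tags = fuse_realtime(p, s)
        rep_p = agreement(fused, nd.truth)
        acc_p.append(rep_p.accuracy)
        kap_p.append(rep_p.kappa)
        scor.append(rep_p.percent_scorable)
        s_hyp, _ = fuse_realtime(s, s, gap_min=0.0)
        acc_s.append(agreement(s_hyp, nd.truth).accuracy)
        sm = smooth_offline(np.where(np.isnan(p), s, p), transitions)
        acc_sm.append(agreement(sm, nd.truth).accuracy)
    return StagingBenchmark(
        primary_accuracy=float(np.mean(acc_p)),
        primary_kappa=float(np.mean(kap_p)),
        secondary_accuracy=float(np.mean(acc_s)),
        smoothed_accuracy=float(np.mean(acc_sm)),
        percent_scorable=float(np.mean(scor)))


def pretraining_comparison(pretrained: StagingModel,
                           corpus: list[NightData], n_finetune: int,
                           test_nights: list[NightData],
                           seeds: list[int]) -> dict:
    """Warm vs cold start with few training nights, paired over seeds.

    For each seed, ``n_finetune`` nights are drawn from ``corpus``; a
    warm-started model (fine-tuned from ``pretrained``) and a cold-started
    model (fit from scratch on the same nights) are evaluated on the same
    held-out nights.
    """
    warm_accs, cold_accs = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        # the classifiers require all four stages in the training labels;
        # redraw small subsets that happen to miss one
        for _ in range(50):
            pick = rng.choice(len(corpus), size=n_finetune, replace=False)
            sub = [corpus[i] for i in pick]
            y = _stack(sub, "labels")
            if len(np.unique(y[y >= 0])) == 4:
                break
        X = _stack(sub, "X_exg")
        warm = train_primary(X, y, init=pretrained, seed=seed)
        cold = train_primary(X, y, seed=seed)
        wa, ca = [], []
        for nd in test_nights:
            for model, acc in ((warm, wa), (cold, ca)):
                p = predict_primary(model, nd.X_exg, nd.exg_scorable)
                hyp, _ = fuse_realtime(p, p)
                acc.append(agreement(hyp, nd.truth).accuracy)
        warm_accs.append(float(np.mean(wa)))
        cold_accs.append(float(np.mean(ca)))
    return {"warm": warm_accs, "cold": cold_accs,
            "warm_mean": float(np.mean(warm_accs)),
            "cold_mean": float(np.mean(cold_accs))}


def channel_recovery(nights: list[NightData]) -> dict:
    """Epoch×channel artifact detection sensitivity/specificity vs the mask."""
    tp = fn = fp = tn = 0
    for nd in nights:
        det = nd.detected_bad
        m = nd.artifact_mask
        tp += int((m & det).sum())
        fn += int((m & ~det).sum())
        fp += int((~m & det).sum())
        tn += int((~m & ~det).sum())
    return {"sensitivity": tp / max(tp + fn, 1),
            "specificity": tn / max(tn + fp, 1),
            "masked_cells": tp + fn}


def missing_segment_sessions(pml: StagingModel, sml: StagingModel,
                             nights: list[NightData]) -> list[dict]:
    """Package nights as sessions for the missing-segment experiment."""
    sessions = []
    for nd in nights:
        sessions.append({
            "primary": predict_primary(pml, nd.X_exg, nd.exg_scorable),
            "secondary": predict_secondary(sml, nd.X_sml),
            "truth": nd.truth,
        })
    return sessions
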