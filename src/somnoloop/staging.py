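"""4-stage sleep scoring: classifiers, fusion, and offline smoothing.

Two probabilistic classifiers emit per-epoch stage distributions over
(W, LS, DS, REM): the primary model (PML) from ExG features and the
secondary model (SML) from vitals (heart rate, respiratory rate, posture,
motion) over a trailing context window.  A real-time fusion rule substitutes
SML output only after the ExG channels have been continuously unscorable for
a configurable gap, keeping the pipeline causal.  Offline, the distribution
stream is decoded into a maximum a posteriori stage path under a bigram
transition model (Viterbi), followed by a rule pass that removes
single-epoch stage islands; the smoothed hypnogram scores every epoch,
including those left unscored in real time.

Distribution streams are ``(n, 4)`` arrays; an all-NaN row marks an
UNSCORED epoch.

Both classifiers are multinomial logistic models.  A cold start fits from
scratch (L-BFGS, inverse-frequency class weighting); a warm start takes the
weights and feature scaling of an existing model and fine-tunes them with a
small-step SGD, which is what makes pre-training on a large corpus pay off
when only a night or two of new data is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_NAMES, exg_feature_matrix
from .quality import (QualityReport, QualityThresholds, assess_recording,
                      rereference, select_channels)
from .signal_io import (EPOCH_LEN_S, STAGES, UNSCORED, Hypnogram, Recording,
                        epochize, stage_indices, stages_from_indices)
from .vitals import VitalsSeries

N_STAGES = 4


def uniform_distribution() -> np.ndarray:
    return np.full(N_STAGES, 0.25)


def is_unscored(row: np.ndarray) -> bool:
    return bool(np.isnan(row).any())


# ---------------------------------------------------------------------------
# Consensus ground truth

def consensus_hypnogram(hypnograms: list[Hypnogram]) -> Hypnogram:
    """Majority vote over >= 3 technician hypnograms, per epoch.

    A fully tied epoch (all voters differ) takes the label of the technician
    with the highest mean pairwise epoch-agreement over the whole study;
    a tie among technicians breaks toward the lowest technician index.
    """
    if len(hypnograms) < 3:
        raise ValueError("consensus requires at least 3 hypnograms")
    n = len(hypnograms[0])
    if any(len(h) != n for h in hypnograms):
        raise ValueError("hypnograms must have equal lengths")
    k = len(hypnograms)
    # mean pairwise agreement per technician
    agree = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i != j:
                agree[i] += np.mean([a == b for a, b in
                                     zip(hypnograms[i], hypnograms[j])])
    agree /= (k - 1)
    best_tech = int(np.argmax(agree))  # argmax takes lowest index on ties
    out = []
    for ep in range(n):
        votes = [h[ep] for h in hypnograms]
        counts: dict[str, int] = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        top = max(counts.values())
        winners = [s for s, c in counts.items() if c == top]
        if len(winners) == 1:
            out.append(winners[0])
        else:
            out.append(hypnograms[best_tech][ep])
    return Hypnogram(out)


# ---------------------------------------------------------------------------
# Models

def _schema_hash(names: tuple[str, ...]) -> str:
    return hashlib.md5("|".join(names).encode()).hexdigest()[:12]


@dataclass
class StagingModel:
    """A trained stage classifier: scaling + multinomial logistic weights."""

    kind: str                      # "primary" | "secondary"
    feature_names: tuple[str, ...]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    coef: np.ndarray               # (4, n_features)
    intercept: np.ndarray          # (4,)
    metadata: dict = field(default_factory=dict)

    @property
    def schema_hash(self) -> str:
        return _schema_hash(self.feature_names)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature schema mismatch: "
                             f"{X.shape[1]} columns vs {len(self.feature_names)}")
        Z = (X - self.scale_mean) / self.scale_std
        logits = Z @ self.coef.T + self.intercept
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def save(self, path) -> None:
        obj = {"kind": self.kind, "feature_names": list(self.feature_names),
               "schema_hash": self.schema_hash,
               "scale_mean": self.scale_mean.tolist(),
               "scale_std": self.scale_std.tolist(),
               "coef": self.coef.tolist(), "intercept": self.intercept.tolist(),
               "metadata": self.metadata}
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def load(cls, path) -> "StagingModel":
        with open(path) as f:
            obj = json.load(f)
        return cls(kind=obj["kind"], feature_names=tuple(obj["feature_names"]),
                   scale_mean=np.array(obj["scale_mean"]),
                   scale_std=np.array(obj["scale_std"]),
                   coef=np.array(obj["coef"]),
                   intercept=np.array(obj["intercept"]),
                   metadata=obj.get("metadata", {}))


def _check_labels(y: np.ndarray) -> None:
    present = set(int(v) for v in np.unique(y))
    missing = [STAGES[i] for i in range(N_STAGES) if i not in present]
    if missing:
        raise ValueError(f"stage(s) absent from training labels: {missing}")


def _train(kind: str, X: np.ndarray, y: np.ndarray,
           feature_names: tuple[str, ...], init: StagingModel | None,
           seed: int, fine_tune_epochs: int = 100,
           fine_tune_eta: float = 0.5) -> StagingModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    keep = ~np.isnan(X).any(axis=1) & (y >= 0)
    X, y = X[keep], y[keep]
    _check_labels(y)
    counts = np.bincount(y, minlength=N_STAGES).astype(float)
    weights = len(y) / (N_STAGES * counts)
    sample_w = weights[y]
    if init is None:
        mean, std = X.mean(axis=0), X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        Z = (X - mean) / std
        clf = LogisticRegression(max_iter=1000, C=1.0)
        clf.fit(Z, y, sample_weight=sample_w)
        coef = np.zeros((N_STAGES, X.shape[1]))
        inter = np.zeros(N_STAGES)
        for ci, cls_ in enumerate(clf.classes_):
            coef[int(cls_)] = clf.coef_[ci]
            inter[int(cls_)] = clf.intercept_[ci]
        source = "cold"
    else:
        if init.feature_names != feature_names:
            raise ValueError("init model has a different feature schema")
        mean, std = init.scale_mean, init.scale_std
        Z = (X - mean) / std
        # full-batch multinomial softmax gradient steps from the pretrained
        # weights; early stopping keeps the solution anchored to the prior
        # when the new dataset is small
        coef = init.coef.copy()
        inter = init.intercept.copy()
        Y = np.zeros((len(y), N_STAGES))
        Y[np.arange(len(y)), y] = 1.0
        w = sample_w / sample_w.sum()
        for _ in range(fine_tune_epochs):
            logits = Z @ coef.T + inter
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            g = (p - Y) * w[:, None]
            coef -= fine_tune_eta * (g.T @ Z + 1e-4 * coef)
            inter -= fine_tune_eta * g.sum(axis=0)
        source = "warm"
    return StagingModel(kind=kind, feature_names=feature_names,
                        scale_mean=mean, scale_std=std, coef=coef,
                        intercept=inter,
                        metadata={"n_epochs": int(len(y)), "seed": int(seed),
                                  "init": source})


def train_primary(X: np.ndarray, labels: np.ndarray,
                  init: StagingModel | None = None,
                  seed: int = 0) -> StagingModel:
    """Train the ExG-feature classifier; ``labels`` are stage codes 0..3.

    All four stages must appear in the labels.  With ``init``, training
    warm-starts from that model's weights and scaling.
    """
    return _train("primary", X, labels, tuple(FEATURE_NAMES), init, seed)


def predict_primary(model: StagingModel, X: np.ndarray,
                    usable: np.ndarray | None = None) -> np.ndarray:
    """Per-epoch stage distributions; rows with no usable ExG are NaN.

    ``usable`` is a per-epoch boolean (ExG scorable at all); NaN feature
    rows are also treated as unscorable.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    out = np.full((n, N_STAGES), np.nan)
    ok = ~np.isnan(X).any(axis=1)
    if usable is not None:
        ok &= np.asarray(usable, dtype=bool)
    if ok.any():
        out[ok] = model.predict_proba(X[ok])
    return out


# --- secondary (vitals) model

SML_FEATURE_NAMES = (
    "hr_mean", "hr_std", "hr_delta", "rr_mean", "rr_std",
    "motion_mean", "motion_max", "posture_changes", "hr_rel_night",
)
SML_CONTEXT = 10  # epochs


def sml_features(vitals: VitalsSeries, context: int = SML_CONTEXT) -> np.ndarray:
    """Causal context-window features from the vitals series.

    Epoch t summarizes epochs [t-context+1, t].  Rows where HR and RR are
    invalid throughout the window are NaN (the SML cannot score them).
    """
    n = len(vitals.hr_bpm)
    X = np.full((n, len(SML_FEATURE_NAMES)), np.nan)
    hr = np.where(vitals.hr_valid, vitals.hr_bpm, np.nan)
    rr = np.where(vitals.rr_valid, vitals.rr_brpm, np.nan)
    _pcodes: dict[str, int] = {}
    post = np.array([_pcodes.setdefault(p, len(_pcodes))
                     for p in vitals.posture])
    for t in range(n):
        lo = max(0, t - context + 1)
        h, r = hr[lo:t + 1], rr[lo:t + 1]
        if np.isnan(h).all() and np.isnan(r).all():
            continue
        hist = hr[:t + 1]
        night_med = np.nanmedian(hist) if not np.isnan(hist).all() else np.nan
        hm = np.nanmean(h) if not np.isnan(h).all() else night_med
        X[t] = [
            hm,
            np.nanstd(h) if not np.isnan(h).all() else 0.0,
            (h[-1] - h[0]) if not (np.isnan(h[0]) or np.isnan(h[-1])) else 0.0,
            np.nanmean(r) if not np.isnan(r).all() else 13.0,
            np.nanstd(r) if not np.isnan(r).all() else 0.0,
            np.mean(vitals.motion_rms[lo:t + 1]),
            np.max(vitals.motion_rms[lo:t + 1]),
            float(np.sum(post[lo + 1:t + 1] != post[lo:t])),
            (hm - night_med) if not (np.isnan(night_med) or np.isnan(hm)) else 0.0,
        ]
    # residual NaN cells (e.g. HR-only windows) -> neutral zero after scaling
    rows = ~np.isnan(X).all(axis=1)
    X[rows] = np.where(np.isnan(X[rows]), 0.0, X[rows])
    return X


def train_secondary(X: np.ndarray, labels: np.ndarray,
                    init: StagingModel | None = None,
                    seed: int = 0) -> StagingModel:
    """Train the vitals classifier on :func:`sml_features` rows."""
    return _train("secondary", X, labels, SML_FEATURE_NAMES, init, seed)


def predict_secondary(model: StagingModel, X: np.ndarray) -> np.ndarray:
    """Distributions from vitals context features; all-invalid rows are NaN."""
    return predict_primary(model, X)


# ---------------------------------------------------------------------------
# Real-time fusion

def fuse_realtime(primary: np.ndarray, secondary: np.ndarray,
                  gap_min: float = 5.0) -> tuple[Hypnogram, list[str]]:
    """Causal fusion of the two classifier streams.

    The primary stream wins whenever it scored an epoch.  Within a run of
    consecutive primary-unscored epochs, epochs beyond the first
    ``gap_min`` minutes take the secondary prediction (when available);
    earlier epochs in the run stay UNSCORED.  Returns the argmax hypnogram
    and a per-epoch source tag in {primary, secondary, unscored}.
    """
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    if primary.shape != secondary.shape:
        raise ValueError("primary and secondary streams must align")
    gap_ep = int(round(gap_min * 60 / EPOCH_LEN_S))
    stages: list[str] = []
    tags: list[str] = []
    run = 0
    for t in range(len(primary)):
        if not is_unscored(primary[t]):
            run = 0
            stages.append(STAGES[int(np.argmax(primary[t]))])
            tags.append("primary")
        else:
            run += 1
            if run > gap_ep and not is_unscored(secondary[t]):
                stages.append(STAGES[int(np.argmax(secondary[t]))])
                tags.append("secondary")
            else:
                stages.append(UNSCORED)
                tags.append("unscored")
    return Hypnogram(stages), tags


# ---------------------------------------------------------------------------
# Transition model and offline smoothing

@dataclass
class TransitionModel:
    """Bigram stage-transition probabilities with an initial distribution."""

    matrix: np.ndarray                 # (4, 4), rows sum to 1
    initial: np.ndarray                # (4,)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"matrix": self.matrix.tolist(),
                       "initial": self.initial.tolist(),
                       "stages": list(STAGES)}, f)

    @classmethod
    def load(cls, path) -> "TransitionModel":
        with open(path) as f:
            obj = json.load(f)
        return cls(matrix=np.array(obj["matrix"]),
                   initial=np.array(obj["initial"]))


def fit_transitions(hypnograms: list[Hypnogram],
                    eps: float = 1e-4) -> TransitionModel:
    """Maximum-likelihood bigram counts with additive smoothing ``eps``.

    Pairs involving UNSCORED epochs are skipped.
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    counts = np.zeros((N_STAGES, N_STAGES))
    init = np.zeros(N_STAGES)
    for h in hypnograms:
        idx = stage_indices(h.stages)
        scored = idx[idx >= 0]
        if len(scored):
            init[scored[0]] += 1
        for a, b in zip(idx[:-1], idx[1:]):
            if a >= 0 and b >= 0:
                counts[a, b] += 1
    counts += eps
    init += eps
    row_sums = counts.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return TransitionModel(matrix=counts / row_sums, initial=init / init.sum())


def viterbi_path(emissions: np.ndarray, transitions: TransitionModel) -> np.ndarray:
    """Maximum a posteriori stage path by dynamic programming (log space)."""
    n = len(emissions)
    logA = np.log(np.maximum(transitions.matrix, 1e-300))
    logpi = np.log(np.maximum(transitions.initial, 1e-300))
    logB = np.log(np.maximum(emissions, 1e-300))
    delta = np.empty((n, N_STAGES))
    back = np.zeros((n, N_STAGES), dtype=int)
    delta[0] = logpi + logB[0]
    for t in range(1, n):
        scores = delta[t - 1][:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta[t] = scores[back[t], np.arange(N_STAGES)] + logB[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def remove_islands(stages: list[str]) -> list[str]:
    """Replace single-epoch islands (X, Y, X with Y != X) by the flank."""
    s = list(stages)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(s) - 1):
            if s[i - 1] == s[i + 1] != s[i]:
                s[i] = s[i - 1]
                changed = True
    return s


def smooth_offline(distributions: np.ndarray,
                   transitions: TransitionModel) -> Hypnogram:
    """Decode the MAP stage path, then remove single-epoch islands.

    UNSCORED epochs (NaN rows) enter the decoder with uniform emissions, so
    every epoch — including originally unscored ones — receives a stage.
    """
    dists = np.asarray(distributions, dtype=float)
    if dists.ndim != 2 or dists.shape[1] != N_STAGES or len(dists) < 1:
        raise ValueError("expected a (n, 4) distribution stream with n >= 1")
    emissions = dists.copy()
    bad = np.isnan(emissions).any(axis=1)
    emissions[bad] = 0.25
    path = viterbi_path(emissions, transitions)
    return Hypnogram(remove_islands(stages_from_indices(path)))


# ---------------------------------------------------------------------------
# Whole-night ExG feature extraction (pipeline glue)

def night_exg_features(recording: Recording, scheme: str = "dynamic",
                       thresholds: QualityThresholds | None = None
                       ) -> tuple[np.ndarray, np.ndarray, QualityReport]:
    """Quality screening + re-referencing + feature extraction per epoch.

    Returns (features (n, f) with NaN rows where no channel is usable,
    per-epoch ExG-scorable flags, the quality report).
    """
    epochs = epochize(recording)
    report = assess_recording(epochs, thresholds)
    derived_per_epoch = []
    for i, ep in enumerate(epochs):
        usable = select_channels(report.grid[i])
        derived_per_epoch.append(rereference(ep, usable, scheme) if usable else {})
    X = exg_feature_matrix(derived_per_epoch, recording.exg_rate)
    scorable = np.array([bool(d) for d in derived_per_epoch])
    return X, scorable, report


# ---------------------------------------------------------------------------
# Missing-segment experiment

def missing_segment_experiment(
        sessions: list[dict], durations_min: list[float],
        trials: int = 50, seed: int = 0,
        transitions: TransitionModel | None = None) -> pd.DataFrame:
    """Accuracy after smoothing when a contiguous ExG segment is lost.

    Each session dict carries ``primary`` and ``secondary`` (n, 4) streams
    and ``truth`` (a Hypnogram).  Per trial, a random contiguous segment of
    the given duration is marked ExG-unscorable; scenario ``with_sml`` fills
    it with secondary predictions before smoothing, ``without_sml`` leaves
    it unscored.  Returns mean accuracy per (duration, scenario).
    """
    rng = np.random.default_rng(seed)
    if transitions is None:
        transitions = fit_transitions([s["truth"] for s in sessions])
    rows = []
    for dur in durations_min:
        seg_ep = int(round(dur * 60 / EPOCH_LEN_S))
        accs = {"with_sml": [], "without_sml": []}
        for _ in range(trials):
            for sess in sessions:
                primary = np.asarray(sess["primary"], dtype=float)
                secondary = np.asarray(sess["secondary"], dtype=float)
                truth = stage_indices(sess["truth"].stages)
                n = len(primary)
                if seg_ep >= n:
                    continue
                start = int(rng.integers(0, n - seg_ep)) if seg_ep > 0 else 0
                for scenario in ("with_sml", "without_sml"):
                    dists = primary.copy()
                    if seg_ep > 0:
                        if scenario == "with_sml":
                            dists[start:start + seg_ep] = \
                                secondary[start:start + seg_ep]
                        else:
                            dists[start:start + seg_ep] = np.nan
                    smoothed = smooth_offline(dists, transitions)
                    est = stage_indices(smoothed.stages)
                    accs[scenario].append(float(np.mean(est == truth)))
        for scenario, vals in accs.items():
            if vals:
                rows.append({"duration_min": dur, "scenario": scenario,
                             "accuracy": float(np.mean(vals)),
                             "n_trials": len(vals)})
    return pd.DataFrame(rows)
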