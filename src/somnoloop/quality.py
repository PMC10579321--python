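"""Channel quality screening, dynamic re-referencing, and availability summaries.

Dry-electrode headbands lose skin contact when the wearer moves; individual
channels drop out and recover during the night.  This module decides, per
30-s epoch and per channel, whether the signal is scorable, derives
re-referenced virtual channels under three schemes, and summarizes channel
availability (fail ratio per channel, stabilization time after an outage).

Scorability is a deterministic function of five screening metrics computed
on the raw epoch window — flatline fraction, saturation fraction,
high-amplitude fraction, RMS amplitude, and mains-band power ratio — each
against a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import EXG_CHANNELS, EPOCH_LEN_S, EpochView


@dataclass
class QualityThresholds:
    """Screening thresholds; an epoch×channel is unscorable iff any trips."""

    flatline_frac: float = 0.2
    saturation_frac: float = 0.05
    highamp_frac: float = 0.3
    rms_min_uv: float = 0.5
    rms_max_uv: float = 150.0
    line_noise_ratio: float = 1.0
    saturation_uv: float = 900.0     # |x| above this counts as railed
    highamp_ptp_uv: float = 400.0    # 1-s peak-to-peak above this is motion
    flat_tol_uv: float = 0.05        # |dx| below this is "constant"


@dataclass
class ChannelQuality:
    rms_uv: float
    flatline_frac: float
    saturation_frac: float
    highamp_frac: float
    line_noise_ratio: float
    scorable: bool


@dataclass
class QualityReport:
    """Epoch × channel quality grid with availability summaries."""

    grid: list[dict[str, ChannelQuality]]         # per epoch
    fail_ratio: dict[str, float] = field(default_factory=dict)
    stabilization_time_s: list[tuple[str, float]] = field(default_factory=list)

    @property
    def scorable_matrix(self) -> np.ndarray:
        return np.array([[row[ch].scorable for ch in EXG_CHANNELS]
                         for row in self.grid])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ep, row in enumerate(self.grid):
            for ch, q in row.items():
                rows.append({"epoch": ep, "channel": ch, "scorable": q.scorable,
                             "rms": q.rms_uv, "flatline_frac": q.flatline_frac,
                             "saturation_frac": q.saturation_frac,
                             "highamp_frac": q.highamp_frac,
                             "line_noise_ratio": q.line_noise_ratio})
        return pd.DataFrame(rows)


def assess_channel(window: np.ndarray, rate: float,
                   thresholds: QualityThresholds | None = None) -> ChannelQuality:
    """Screen one 30-s epoch window of one channel.

    Metrics: RMS amplitude; fraction of samples inside near-constant runs of
    >= 0.5 s (flatline); fraction at the amplitude rails (saturation);
    fraction of 1-s windows with excessive peak-to-peak (motion); mains-band
    (45–55 Hz) over broadband (0.3–35 Hz) power ratio.  The window is
    unscorable iff any metric crosses its threshold.
    """
    th = thresholds or QualityThresholds()
    x = np.asarray(window, dtype=float)
    n_expect = int(round(rate * EPOCH_LEN_S))
    if len(x) != n_expect:
        raise ValueError(f"window length {len(x)} != rate*30 = {n_expect}")
    return _assess_batch(x[None, :], rate, th)[0]


def select_channels(row: dict[str, ChannelQuality]) -> set[str]:
    """Channels usable this epoch; empty set = epoch ExG-unscorable."""
    return {ch for ch, q in row.items() if q.scorable}


REREF_SCHEMES = ("dynamic", "contralateral_be", "none")

#: contralateral behind-the-ear reference for each non-reference channel
_CONTRA = {"FH_L": "BE_R", "OTE_L": "BE_R", "FH_R": "BE_L", "OTE_R": "BE_L"}
_IPSI = {"FH_L": "BE_L", "OTE_L": "BE_L", "FH_R": "BE_R", "OTE_R": "BE_R"}


def rereference(epoch: EpochView, usable: set[str],
                scheme: str = "dynamic") -> dict[str, np.ndarray]:
    """Derive referenced virtual channels for one epoch.

    ``none``: pass through each usable channel against its standard reference.
    ``contralateral_be``: FH/OTE channels minus the opposite-side BE channel,
    emitted only when both members are usable (least robust to dropouts).
    ``dynamic``: per channel, fall back contralateral BE → ipsilateral BE →
    raw pass-through, using whatever is usable.  Keys name the derivation,
    e.g. ``"FH_L-BE_R"``.
    """
    if scheme not in REREF_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected {REREF_SCHEMES}")
    if not usable <= set(EXG_CHANNELS):
        raise ValueError(f"unknown channels in usable set: {usable - set(EXG_CHANNELS)}")
    out: dict[str, np.ndarray] = {}
    if scheme == "none":
        for ch in EXG_CHANNELS:
            if ch in usable:
                out[ch] = epoch.exg[ch]
        return out
    for ch in ("FH_L", "OTE_L", "FH_R", "OTE_R"):
        if ch not in usable:
            continue
        contra, ipsi = _CONTRA[ch], _IPSI[ch]
        if contra in usable:
            out[f"{ch}-{contra}"] = epoch.exg[ch] - epoch.exg[contra]
        elif scheme == "dynamic":
            if ipsi in usable:
                out[f"{ch}-{ipsi}"] = epoch.exg[ch] - epoch.exg[ipsi]
            else:
                out[ch] = epoch.exg[ch]
    if scheme == "dynamic" and not out:
        # only BE electrodes left: pass them through rather than dropping
        # the epoch (the fallback chain only ever adds options)
        for ch in ("BE_L", "BE_R"):
            if ch in usable:
                out[ch] = epoch.exg[ch]
    return out


def _assess_batch(W: np.ndarray, rate: float,
                  th: QualityThresholds) -> list[ChannelQuality]:
    """Vectorized screening of a stack of 30-s windows, shape (m, n)."""
    m, n = W.shape
    rms = np.sqrt(np.mean(W ** 2, axis=-1))
    saturation_frac = np.mean(np.abs(W) >= th.saturation_uv, axis=-1)

    sec = int(rate)
    n_win = n // sec
    segs = W[:, : n_win * sec].reshape(m, n_win, sec)
    ptp = segs.max(axis=-1) - segs.min(axis=-1)
    highamp_frac = np.mean(ptp > th.highamp_ptp_uv, axis=-1)

    # coarse PSD is plenty for a mains-band ratio screen
    nper = min(256, n)
    freqs, psd = sps.welch(W, fs=rate, nperseg=nper, noverlap=0, axis=-1)
    bb = (freqs >= 0.3) & (freqs <= 35.0)
    ln = (freqs >= 45.0) & (freqs <= min(55.0, rate / 2 - 1))
    broadband = np.trapezoid(psd[:, bb], freqs[bb], axis=-1)
    line = np.trapezoid(psd[:, ln], freqs[ln], axis=-1) if ln.any() else np.zeros(m)
    line_ratio = np.where(broadband > 0, line / np.maximum(broadband, 1e-30), np.inf)

    flat = np.abs(np.diff(W, prepend=W[:, :1], axis=-1)) < th.flat_tol_uv
    min_run = int(rate * 0.5)
    out = []
    for i in range(m):
        edges = np.flatnonzero(np.diff(np.r_[0, flat[i].astype(np.int8), 0]))
        run_lens = edges[1::2] - edges[::2]
        ff = float(run_lens[run_lens >= min_run].sum()) / n
        scorable = not (
            ff > th.flatline_frac
            or saturation_frac[i] > th.saturation_frac
            or highamp_frac[i] > th.highamp_frac
            or rms[i] < th.rms_min_uv or rms[i] > th.rms_max_uv
            or line_ratio[i] > th.line_noise_ratio
        )
        out.append(ChannelQuality(
            rms_uv=float(rms[i]), flatline_frac=ff,
            saturation_frac=float(saturation_frac[i]),
            highamp_frac=float(highamp_frac[i]),
            line_noise_ratio=float(line_ratio[i]), scorable=scorable))
    return out


def assess_recording(epochs: list[EpochView],
                     thresholds: QualityThresholds | None = None) -> QualityReport:
    """Quality grid for a whole night, computed in one batched pass."""
    th = thresholds or QualityThresholds()
    if not epochs:
        raise ValueError("no epochs to assess")
    rate = epochs[0].exg_rate
    W = np.vstack([ep.exg[ch] for ep in epochs for ch in EXG_CHANNELS])
    flat_list = _assess_batch(W, rate, th)
    grid = []
    k = 0
    for _ep in epochs:
        row = {}
        for ch in EXG_CHANNELS:
            row[ch] = flat_list[k]
            k += 1
        grid.append(row)
    report = QualityReport(grid=grid)
    n = len(grid)
    for ch in EXG_CHANNELS:
        report.fail_ratio[ch] = sum(not row[ch].scorable for row in grid) / n
    return report


def summarize_quality(report: QualityReport,
                      events: list[tuple[str, str, float, float]] | None = None
                      ) -> QualityReport:
    """Attach fail ratios and, given artifact events, stabilization times.

    Stabilization time of an event is the delay from the event's end until
    the start of the first subsequent scorable epoch on that channel.
    """
    n = len(report.grid)
    for ch in EXG_CHANNELS:
        report.fail_ratio[ch] = sum(not row[ch].scorable for row in report.grid) / n
    report.stabilization_time_s = []
    for ch, _kind, t0, dur in events or []:
        end_s = t0 + dur
        ep = int(end_s // EPOCH_LEN_S)
        while ep < n and not report.grid[ep][ch].scorable:
            ep += 1
        if ep < n:
            report.stabilization_time_s.append((ch, max(ep * EPOCH_LEN_S - end_s, 0.0)))
    return report
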