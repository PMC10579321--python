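"""Heart rate, respiratory rate and posture from the PPG and accelerometer.

These per-epoch vitals are the inputs to the secondary sleep-stage
classifier, used when the ExG channels are unusable.  Heart rate comes from
systolic-peak detection on band-passed PPG (median inter-beat interval);
respiratory rate from the dominant spectral peak of the principal-axis
respiration band of the accelerometer over a two-epoch window; posture from
the nearest canonical gravity orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps


@lru_cache(maxsize=32)
def _butter_sos(order: int, lo: float, hi: float | None, btype: str, fs: float):
    wn = lo if hi is None else (lo, hi)
    return sps.butter(order, wn, btype=btype, fs=fs, output="sos")

from .signal_io import EPOCH_LEN_S, Recording
from .synthetic_psg import POSTURE_VECTORS

HR_RANGE = (20.0, 250.0)
RR_RANGE = (4.0, 60.0)


@dataclass
class VitalsSeries:
    """Per-epoch vitals with validity flags."""

    hr_bpm: np.ndarray
    hr_valid: np.ndarray
    rr_brpm: np.ndarray
    rr_valid: np.ndarray
    posture: list[str]
    motion_rms: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.hr_bpm)),
            "hr_bpm": self.hr_bpm, "hr_valid": self.hr_valid,
            "rr_brpm": self.rr_brpm, "rr_valid": self.rr_valid,
            "posture": self.posture, "motion_rms": self.motion_rms,
        })


def estimate_hr(ppg: np.ndarray, rate: float) -> tuple[float, bool]:
    """Heart rate (bpm) from one >= 30-s PPG window.

    Band-pass 0.5–8 Hz, adaptive-threshold peak picking with a 250 ms
    refractory period, HR = 60 / median inter-beat interval.  Invalid when
    fewer than 10 beats are found or the IBI coefficient of variation
    exceeds 0.5.  Scale-invariant by construction.
    """
    x = np.asarray(ppg, dtype=float)
    if len(x) < rate * EPOCH_LEN_S:
        raise ValueError("HR estimation needs at least 30 s of PPG")
    spread = np.percentile(x, 95) - np.percentile(x, 5)
    if spread <= 0:
        return np.nan, False
    sos = _butter_sos(3, 0.5, min(8.0, rate / 2 * 0.9), "bandpass", rate)
    y = sps.sosfiltfilt(sos, x)
    height = 0.4 * np.percentile(y, 95)
    peaks, _ = sps.find_peaks(y, height=height, distance=max(int(0.25 * rate), 1))
    if len(peaks) < 10:
        return np.nan, False
    ibi = np.diff(peaks) / rate
    if np.std(ibi) / np.mean(ibi) > 0.5:
        return np.nan, False
    hr = 60.0 / float(np.median(ibi))
    if not (HR_RANGE[0] < hr < HR_RANGE[1]):
        return hr, False
    return hr, True


def estimate_rr(acc: np.ndarray, rate: float,
                motion_rms_max: float = 0.04) -> tuple[float, bool, float]:
    """Respiratory rate (breaths/min) from a >= 60-s 3-axis window.

    Gravity is removed by low-pass subtraction; the 0.1–0.5 Hz band is
    projected on its principal axis and the dominant Welch peak taken.
    Returns (rr, valid, motion_rms); invalid when motion swamps respiration.
    """
    a = np.asarray(acc, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("acc must be (n, 3)")
    if len(a) < 60 * rate:
        raise ValueError("RR estimation needs at least 60 s of accelerometer")
    gravity = sps.sosfiltfilt(_butter_sos(2, 0.05, None, "lowpass", rate), a, axis=0)
    dyn = a - gravity
    motion_rms = float(np.sqrt(np.mean(dyn ** 2)))
    resp = sps.sosfiltfilt(_butter_sos(3, 0.1, 0.5, "bandpass", rate), dyn, axis=0)
    # principal axis of the respiration-band motion
    cov = resp.T @ resp
    _, vecs = np.linalg.eigh(cov)
    pc = resp @ vecs[:, -1]
    freqs, psd = sps.welch(pc, fs=rate, nperseg=min(len(pc), int(60 * rate)))
    band = (freqs >= 0.1) & (freqs <= 0.5)
    if not band.any() or psd[band].max() <= 0:
        return np.nan, False, motion_rms
    rr = 60.0 * float(freqs[band][np.argmax(psd[band])])
    valid = motion_rms <= motion_rms_max and RR_RANGE[0] < rr < RR_RANGE[1]
    return rr, valid, motion_rms


def classify_posture(acc: np.ndarray) -> str | None:
    """Nearest canonical gravity orientation of the mean acceleration vector.

    Returns None (invalid) when the gravity magnitude is far from 1 g.
    """
    a = np.asarray(acc, dtype=float)
    v = a.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 0.3:
        return None
    v = v / norm
    best, best_cos = None, -2.0
    for name, ref in POSTURE_VECTORS.items():
        c = float(v @ ref)
        if c > best_cos:
            best, best_cos = name, c
    return best


def extract_vitals(recording: Recording) -> VitalsSeries:
    """Per-epoch vitals for a whole night.

    HR uses each 30-s PPG epoch; RR uses a trailing two-epoch accelerometer
    window (value assigned to the trailing epoch, first epoch copies the
    second); posture uses the epoch's accelerometer mean.
    """
    if recording.ppg is None or recording.acc is None:
        raise ValueError("recording must carry PPG and accelerometer data")
    n_ep = recording.n_epochs
    n_p = int(round(recording.ppg_rate * EPOCH_LEN_S))
    n_a = int(round(recording.acc_rate * EPOCH_LEN_S))
    hr = np.full(n_ep, np.nan)
    hr_ok = np.zeros(n_ep, dtype=bool)
    rr = np.full(n_ep, np.nan)
    rr_ok = np.zeros(n_ep, dtype=bool)
    motion = np.zeros(n_ep)
    posture: list[str] = []
    for i in range(n_ep):
        hr[i], hr_ok[i] = estimate_hr(
            recording.ppg[i * n_p:(i + 1) * n_p], recording.ppg_rate)
        j0 = max(i - 1, 0) * n_a
        win = recording.acc[j0:(i + 1) * n_a]
        if len(win) >= 60 * recording.acc_rate:
            rr[i], rr_ok[i], motion[i] = estimate_rr(win, recording.acc_rate)
        p = classify_posture(recording.acc[i * n_a:(i + 1) * n_a])
        posture.append(p if p is not None else "unknown")
    if n_ep > 1:
        rr[0], rr_ok[0], motion[0] = rr[1], rr_ok[1], motion[1]
    return VitalsSeries(hr_bpm=hr, hr_valid=hr_ok, rr_brpm=rr, rr_valid=rr_ok,
                        posture=posture, motion_rms=motion)
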