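"""Recording and hypnogram I/O, epoch partitioning, and basic filtering.

A :class:`Recording` bundles the three wearable modalities — six ExG
(EEG/EOG/EMG) channels, one photoplethysmography (PPG) channel and a 3-axis
accelerometer — each at its own native sampling rate.  Recordings live on
disk as EDF (European Data Format), the de facto polysomnography container.
Sleep scoring operates on fixed 30-second epochs; :func:`epochize` partitions
a recording into half-open windows ``[30i, 30i+30)`` and drops any trailing
partial epoch.

The EDF codec here is deliberately small: 16-bit samples, 1-second data
records, one signal per channel.  It preserves each modality's native rate on
read-back, which matters because PPG and accelerometer streams run much
slower than the 200 Hz ExG channels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

#: Canonical ExG channel labels: forehead, over-the-ear and behind-the-ear
#: electrode pairs, left/right.
EXG_CHANNELS = ("FH_L", "FH_R", "OTE_L", "OTE_R", "BE_L", "BE_R")

#: Sleep-stage alphabet: wake, light sleep (N1+N2), deep sleep (N3), REM,
#: plus an explicit "unscored" symbol.
STAGES = ("W", "LS", "DS", "R")
UNSCORED = "U"
STAGE_ALPHABET = STAGES + (UNSCORED,)

EPOCH_LEN_S = 30

#: Default ExG analysis band (Hz), matching the clinical reference chain.
DEFAULT_BAND = (0.3, 35.0)


class MissingChannelError(KeyError):
    """A required ExG channel label is absent from a file."""


class TooShortError(ValueError):
    """Recording shorter than one 30-s epoch."""


@dataclass
class Recording:
    """Synchronized multimodal raw signals.

    ExG samples are in microvolts, accelerometer in g, PPG in arbitrary
    optical units.  All channels within a modality share one length.
    """

    exg: dict[str, np.ndarray]
    exg_rate: float = 200.0
    ppg: np.ndarray | None = None
    ppg_rate: float = 64.0
    acc: np.ndarray | None = None  # shape (n, 3)
    acc_rate: float = 50.0
    start_time: str = "22.00.00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exg_rate <= 0 or self.ppg_rate <= 0 or self.acc_rate <= 0:
            raise ValueError("sampling rates must be strictly positive")
        lengths = {len(v) for v in self.exg.values()}
        if len(lengths) > 1:
            raise ValueError("ExG channels have unequal lengths")
        if self.acc is not None:
            self.acc = np.asarray(self.acc, dtype=float)
            if self.acc.ndim != 2 or self.acc.shape[1] != 3:
                raise ValueError("acc must be (n, 3)")

    @property
    def duration_s(self) -> float:
        n = len(next(iter(self.exg.values())))
        return n / self.exg_rate

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_LEN_S)


@dataclass
class Hypnogram:
    """Per-epoch stage labels over the 5-symbol alphabet."""

    stages: list[str]
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError("epoch length is fixed at 30 s")
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.stages) - set(STAGE_ALPHABET)
        if bad:
            raise ValueError(f"unknown stage symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterator[str]:
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Hypnogram) and self.stages == other.stages


@dataclass
class EpochView:
    """One 30-s window across all channels of a recording."""

    index: int
    exg: dict[str, np.ndarray]
    exg_rate: float
    ppg: np.ndarray | None = None
    ppg_rate: float = 64.0
    acc: np.ndarray | None = None
    acc_rate: float = 50.0

    @property
    def t_start_s(self) -> float:
        return self.index * EPOCH_LEN_S


def epochize(recording: Recording) -> list[EpochView]:
    """Partition a recording into contiguous, non-overlapping 30-s epochs.

    Epoch ``i`` covers ``[30i, 30i+30)`` seconds; a trailing partial epoch is
    discarded.  Raises :class:`TooShortError` below 30 s.
    """
    n_ep = recording.n_epochs
    if n_ep < 1:
        raise TooShortError(
            f"recording of {recording.duration_s:.1f} s is shorter than one epoch"
        )
    n_exg = int(round(recording.exg_rate * EPOCH_LEN_S))
    n_ppg = int(round(recording.ppg_rate * EPOCH_LEN_S))
    n_acc = int(round(recording.acc_rate * EPOCH_LEN_S))
    out = []
    for i in range(n_ep):
        exg = {k: v[i * n_exg:(i + 1) * n_exg] for k, v in recording.exg.items()}
        ppg = None
        if recording.ppg is not None:
            ppg = recording.ppg[i * n_ppg:(i + 1) * n_ppg]
        acc = None
        if recording.acc is not None:
            acc = recording.acc[i * n_acc:(i + 1) * n_acc]
        out.append(
            EpochView(
                index=i, exg=exg, exg_rate=recording.exg_rate,
                ppg=ppg, ppg_rate=recording.ppg_rate,
                acc=acc, acc_rate=recording.acc_rate,
            )
        )
    return out


def bandpass(x: np.ndarray, rate: float, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band ({low}, {high}) outside (0, Nyquist={rate / 2})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# EDF container

def _pad(s, n: int) -> bytes:
    b = str(s).encode("ascii")
    if len(b) > n:
        b = b[:n]
    return b + b" " * (n - len(b))


def write_recording(recording: Recording, path) -> None:
    """Write a recording as EDF (16-bit, 1-second records).

    Channel order: the six ExG labels, then PPG, then ACC_X/Y/Z.  Physical
    ranges are fixed per modality so quantization resolution does not depend
    on the data: ±1000 µV for ExG, ±10 a.u. for PPG, ±4 g for accelerometer.
    """
    labels: list[str] = []
    data: list[np.ndarray] = []
    rates: list[int] = []
    units: list[str] = []
    ranges: list[tuple[float, float]] = []
    for ch in recording.exg:
        labels.append(ch)
        data.append(np.asarray(recording.exg[ch], dtype=float))
        rates.append(int(round(recording.exg_rate)))
        units.append("uV")
        ranges.append((-1000.0, 1000.0))
    if recording.ppg is not None:
        labels.append("PPG")
        data.append(np.asarray(recording.ppg, dtype=float))
        rates.append(int(round(recording.ppg_rate)))
        units.append("a.u.")
        ranges.append((-10.0, 10.0))
    if recording.acc is not None:
        for j, ax in enumerate(("ACC_X", "ACC_Y", "ACC_Z")):
            labels.append(ax)
            data.append(recording.acc[:, j])
            rates.append(int(round(recording.acc_rate)))
            units.append("g")
            ranges.append((-4.0, 4.0))
    n_rec = min(len(d) // r for d, r in zip(data, rates))
    ns = len(labels)

    hdr = b""
    hdr += _pad("0", 8) + _pad("X X X X", 80) + _pad("Startdate 01-JAN-2024 X X X", 80)
    hdr += _pad("01.01.24", 8) + _pad(recording.start_time, 8)
    hdr += _pad(256 * (1 + ns), 8) + _pad("", 44)
    hdr += _pad(n_rec, 8) + _pad(1, 8) + _pad(ns, 4)
    for values, width in [
        (labels, 16),
        ([""] * ns, 80),
        (units, 8),
        ([f"{r[0]:g}" for r in ranges], 8),
        ([f"{r[1]:g}" for r in ranges], 8),
        (["-32768"] * ns, 8),
        (["32767"] * ns, 8),
        ([""] * ns, 80),
        ([str(r) for r in rates], 8),
        ([""] * ns, 32),
    ]:
        for v in values:
            hdr += _pad(v, width)

    digital = []
    for d, (pmin, pmax) in zip(data, ranges):
        x = np.clip(d, pmin, pmax)
        q = np.round((x - pmin) / (pmax - pmin) * 65535.0 - 32768.0)
        digital.append(q.astype("<i2"))
    with open(path, "wb") as f:
        f.write(hdr)
        for rec in range(n_rec):
            for d, r in zip(digital, rates):
                f.write(d[rec * r:(rec + 1) * r].tobytes())


def _read_edf_raw(path) -> tuple[dict[str, np.ndarray], dict[str, int], str]:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256 or not head[:8].strip().startswith(b"0"):
            raise IOError(f"{path}: not a valid EDF file")
        start_time = head[176:184].decode("ascii").strip()
        n_rec = int(head[236:244])
        ns = int(head[252:256])
        sig_hdr = f.read(256 * ns)
        fields = {}
        off = 0
        for name, width in [
            ("label", 16), ("transducer", 80), ("dim", 8), ("pmin", 8),
            ("pmax", 8), ("dmin", 8), ("dmax", 8), ("prefilter", 80),
            ("nsamp", 8), ("reserved", 32),
        ]:
            fields[name] = [
                sig_hdr[off + i * width:off + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]
            off += ns * width
        labels = fields["label"]
        nsamp = [int(v) for v in fields["nsamp"]]
        pmin = [float(v) for v in fields["pmin"]]
        pmax = [float(v) for v in fields["pmax"]]
        dmin = [float(v) for v in fields["dmin"]]
        dmax = [float(v) for v in fields["dmax"]]
        per_rec = sum(nsamp)
        buf = np.frombuffer(f.read(n_rec * per_rec * 2), dtype="<i2")
        buf = buf[: n_rec * per_rec].reshape(n_rec, per_rec)
    out = {}
    col = 0
    for i, lab in enumerate(labels):
        raw = buf[:, col:col + nsamp[i]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out[lab] = pmin[i] + (raw - dmin[i]) * gain
        col += nsamp[i]
    rates = dict(zip(labels, nsamp))  # 1-s records: samples/record == Hz
    return out, rates, start_time


def read_recording(path) -> Recording:
    """Read an EDF recording; ExG channels are mapped by label (microvolts).

    Unknown channel labels are preserved under ``meta["extra_channels"]``.
    Raises :class:`MissingChannelError` if any of the six ExG labels is
    absent.  No resampling is performed; rates come from the file header.
    """
    chans, rates, start_time = _read_edf_raw(path)
    missing = [c for c in EXG_CHANNELS if c not in chans]
    if missing:
        raise MissingChannelError(f"missing ExG channel(s): {', '.join(missing)}")
    exg = {c: chans[c] for c in EXG_CHANNELS}
    ppg = chans.get("PPG")
    acc = None
    if all(a in chans for a in ("ACC_X", "ACC_Y", "ACC_Z")):
        acc = np.column_stack([chans["ACC_X"], chans["ACC_Y"], chans["ACC_Z"]])
    known = set(EXG_CHANNELS) | {"PPG", "ACC_X", "ACC_Y", "ACC_Z"}
    extra = {k: v for k, v in chans.items() if k not in known}
    return Recording(
        exg=exg, exg_rate=rates[EXG_CHANNELS[0]],
        ppg=ppg, ppg_rate=rates.get("PPG", 64),
        acc=acc, acc_rate=rates.get("ACC_X", 50),
        start_time=start_time,
        meta={"extra_channels": extra} if extra else {},
    )


# ---------------------------------------------------------------------------
# Hypnogram CSV

def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    """Serialize as CSV with header ``epoch,stage``; UNSCORED written as U."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "stage"])
        for i, s in enumerate(hypnogram.stages):
            w.writerow([i, s])


def read_hypnogram(path) -> Hypnogram:
    """Parse a hypnogram CSV; unknown symbols raise with the row number."""
    stages = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["epoch", "stage"]:
            raise ValueError(f"{path}: expected header 'epoch,stage'")
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            s = row[1].strip()
            if s not in STAGE_ALPHABET:
                raise ValueError(f"{path}: unknown stage {s!r} at row {rownum}")
            stages.append(s)
    return Hypnogram(stages)


def stage_indices(stages: Sequence[str]) -> np.ndarray:
    """Map stage labels to integer codes (W=0, LS=1, DS=2, R=3, U=-1)."""
    lut = {s: i for i, s in enumerate(STAGES)}
    lut[UNSCORED] = -1
    return np.array([lut[s] for s in stages], dtype=int)


def stages_from_indices(idx: Sequence[int]) -> list[str]:
    """Inverse of :func:`stage_indices`."""
    return [UNSCORED if i < 0 else STAGES[i] for i in idx]
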