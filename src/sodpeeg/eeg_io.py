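"""EDF reading, montage selection, segmentation and sub-band decomposition.

Scalp EEG arrives as EDF (European Data Format) recordings sampled at
256 Hz on a 23-channel bipolar montage, with seizure onsets/offsets given
as annotated intervals.  The preprocessing chain implemented here:

1. read the EDF (plus an optional ``start_s,end_s,label`` CSV sidecar with
   seizure intervals),
2. select/reorder the bipolar montage channels,
3. cut the record into sliding windows (20 s window, 15 s overlap by
   default) labeled seizure / seizure-free by strict containment in the
   annotated intervals (windows straddling a boundary are discarded),
4. decompose each window into the four clinical sub-bands
   delta (0-4 Hz), theta (4-8 Hz), alpha (8-15 Hz), beta (15-30 Hz)
   with a zero-phase (forward-backward) windowed-sinc FIR filter.

Zero net phase matters: the downstream features are geometric properties
of the second-order difference plot, which phase distortion would warp.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "BAND_ORDER",
    "CHB_MONTAGE",
    "EEGRecord",
    "Segment",
    "read_edf",
    "write_edf",
    "select_montage",
    "segment",
    "band_decompose",
    "reject_artifacts",
]

#: Clinical sub-bands as (low, high) edges in Hz; delta is a low-pass.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}

#: Fixed band order used everywhere a band combination is concatenated.
BAND_ORDER = ("delta", "theta", "alpha", "beta")

#: The 23-channel bipolar montage of CHB-MIT style recordings; the twice
#: recorded T8-P8 derivation is disambiguated with -0/-1 suffixes as in the
#: source EDFs.
CHB_MONTAGE = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1", "FP1-F3", "F3-C3", "C3-P3",
    "P3-O1", "FP2-F4", "F4-C4", "C4-P4", "P4-O2", "FP2-F8", "F8-T8",
    "T8-P8-0", "P8-O2", "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8-1",
)

FIR_ORDER = 512  # taps - 1; 2 s of impulse response at 256 Hz


@dataclass(frozen=True)
class EEGRecord:
    """A multichannel EEG recording in microvolts.

    ``seizure_intervals`` are half-open ``[start_s, end_s)`` intervals in
    seconds from the start of the recording.
    """

    signal: np.ndarray  # (channels, samples), microvolts
    fs: float
    channel_labels: tuple[str, ...]
    seizure_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be (channels, samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for lo, hi in self.seizure_intervals:
            if not (0.0 <= lo < hi <= self.duration_s + 1e-9):
                raise ValueError(f"seizure interval ({lo}, {hi}) outside the recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass(frozen=True)
class Segment:
    """One windowed piece of a recording, possibly band-filtered."""

    signal: np.ndarray  # (channels, window_samples)
    label: str  # "seizure" | "seizure_free"
    band: str  # "broadband" or a key of BANDS
    start_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.label not in ("seizure", "seizure_free"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.band != "broadband" and self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")


def _read_annotation_csv(path: Path) -> tuple[tuple[float, float], ...]:
    intervals = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row.get("label", "seizure").strip().lower() == "seizure":
                intervals.append((float(row["start_s"]), float(row["end_s"])))
    return tuple(intervals)


def _check_edf_length(path: Path) -> None:
    """Reject files whose size contradicts the EDF header (truncation)."""
    size = path.stat().st_size
    if size < 256:
        raise OSError(f"{path} is too short to hold an EDF header")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
            n_signals = int(head[252:256].decode("ascii").strip())
            fh.seek(256 + 216 * n_signals)
            samples_per_record = sum(
                int(fh.read(8).decode("ascii").strip()) for _ in range(n_signals)
            )
        except (UnicodeDecodeError, ValueError) as exc:
            raise OSError(f"{path} has a malformed EDF header: {exc}") from exc
    expected = header_bytes + 2 * n_records * samples_per_record
    if n_records >= 0 and size < expected:
        raise OSError(
            f"{path} appears truncated: {size} bytes on disk, header promises {expected}"
        )


def read_edf(path: str | Path, annotations: str | Path | None = None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts).

    Channels come back in acquisition order.  Seizure intervals are read
    from ``annotations`` (CSV with header ``start_s,end_s,label``) when
    given; otherwise a sidecar ``<file>.csv`` next to the EDF is tried and
    the intervals are left empty when neither exists.  A sampling
    frequency other than 256 Hz is accepted with a warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_length(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed files
        raise OSError(f"could not parse {path} as EDF: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if abs(fs - 256.0) > 1e-6:
        warnings.warn(f"expected 256 Hz sampling, got {fs} Hz")
    data_uv = raw.get_data(units="uV")
    labels = tuple(raw.ch_names)

    sidecar = Path(annotations) if annotations is not None else path.with_suffix(".csv")
    intervals: tuple[tuple[float, float], ...] = ()
    if sidecar.exists():
        intervals = _read_annotation_csv(sidecar)
    return EEGRecord(
        signal=np.asarray(data_uv, dtype=float),
        fs=fs,
        channel_labels=labels,
        seizure_intervals=intervals,
    )


def write_edf(path: str | Path, record: EEGRecord) -> None:
    """Write an :class:`EEGRecord` as a minimal EDF file.

    One data record per second, 16-bit samples, physical units microvolts.
    Seizure intervals are written to a ``<file>.csv`` sidecar when present.
    The sampling frequency must be an integer for the 1 s record layout.
    """
    path = Path(path)
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9:
        raise ValueError("write_edf requires an integer sampling frequency")
    n_ch = record.n_channels
    n_records = record.signal.shape[1] // fs
    if n_records * fs != record.signal.shape[1]:
        raise ValueError("signal length must be a whole number of seconds")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    phys_min = np.floor(record.signal.min(axis=1))
    phys_max = np.ceil(record.signal.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic recording", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(lab, 16) for lab in record.channel_labels],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min[i]:g}", 8) for i in range(n_ch)],
        [pad(f"{phys_max[i]:g}", 8) for i in range(n_ch)],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(fs), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for rec in range(n_records):
            chunk = record.signal[:, rec * fs : (rec + 1) * fs]
            digital = np.round((chunk - phys_min[:, None]) / scale[:, None]) + dig_min
            fh.write(digital.astype("<i2").tobytes())
    if record.seizure_intervals:
        with open(path.with_suffix(".csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["start_s", "end_s", "label"])
            for lo, hi in record.seizure_intervals:
                writer.writerow([lo, hi, "seizure"])


def select_montage(record: EEGRecord, wanted: Sequence[str]) -> EEGRecord:
    """Reorder the record's channels to ``wanted``, dropping the rest."""
    index = {lab: i for i, lab in enumerate(record.channel_labels)}
    missing = [lab for lab in wanted if lab not in index]
    if missing:
        raise KeyError(f"channel {missing[0]} not found")
    rows = [index[lab] for lab in wanted]
    return replace(record, signal=record.signal[rows], channel_labels=tuple(wanted))


def _window_label(
    start_s: float, end_s: float, intervals: Sequence[tuple[float, float]]
) -> str | None:
    """Seizure iff fully inside an interval, seizure-free iff fully
    outside all of them, ``None`` (discard) for mixed windows."""
    for lo, hi in intervals:
        if lo <= start_s and end_s <= hi:
            return "seizure"
    for lo, hi in intervals:
        if start_s < hi and lo < end_s:  # overlap without containment
            return None
    return "seizure_free"


def segment(record: EEGRecord, window_s: float = 20.0, overlap_s: float = 15.0) -> list[Segment]:
    """Cut the record into sliding windows with the given overlap.

    Windows start at multiples of ``window_s - overlap_s`` and must lie
    fully inside the record, so a duration ``D`` yields
    ``floor((D - window_s)/stride) + 1`` candidate windows.  Windows that
    straddle a seizure boundary carry no clean label and are discarded.
    """
    if not 0 <= overlap_s < window_s:
        raise ValueError("need 0 <= overlap_s < window_s")
    if record.duration_s < window_s:
        raise ValueError(
            f"record of {record.duration_s:g} s is shorter than the {window_s:g} s window"
        )
    stride = window_s - overlap_s
    win = int(round(window_s * record.fs))
    hop = stride * record.fs
    segments = []
    k = 0
    while True:
        start = int(round(k * hop))
        if start + win > record.signal.shape[1]:
            break
        start_s = start / record.fs
        label = _window_label(start_s, start_s + window_s, record.seizure_intervals)
        if label is not None:
            segments.append(
                Segment(
                    signal=record.signal[:, start : start + win].copy(),
                    label=label,
                    band="broadband",
                    start_s=start_s,
                    fs=record.fs,
                )
            )
        k += 1
    return segments


@lru_cache(maxsize=32)
def _band_fir(band: str, fs: float, numtaps: int = FIR_ORDER + 1) -> np.ndarray:
    low, high = BANDS[band]
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz is not below Nyquist ({fs / 2} Hz)")
    if low <= 0:
        return sps.firwin(numtaps, high, window="hamming", fs=fs, pass_zero=True)
    return sps.firwin(numtaps, [low, high], window="hamming", fs=fs, pass_zero=False)


def _zero_phase(h: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis.

    Equivalent to ``scipy.signal.filtfilt(h, 1, x, padlen=len(h))`` --
    convolution with the (symmetric, zero-phase) autocorrelation kernel of
    ``h`` after odd-reflection edge padding -- but computed with FFT
    convolution, which is much faster for long kernels.
    """
    g = np.convolve(h, h[::-1])
    pad = len(h)
    if x.shape[-1] <= pad:
        raise ValueError("signal shorter than the filter padding")
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right], axis=-1)
    y = sps.fftconvolve(xp, g[np.newaxis, :] if x.ndim == 2 else g, mode="same", axes=-1)
    return y[..., pad:-pad]


def band_decompose(seg: Segment, band: str) -> Segment:
    """Filter a broadband segment into one clinical sub-band.

    Linear-phase windowed-sinc (Hamming) FIR of order 512 applied
    forward-backward, so the net phase is zero and the SODP geometry of
    the output is undistorted.  Delta is implemented as a low-pass at its
    upper edge.
    """
    if seg.band != "broadband":
        raise ValueError(f"segment is already band-filtered ({seg.band})")
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    h = _band_fir(band, seg.fs)
    sig = np.atleast_2d(np.asarray(seg.signal, dtype=float))
    return replace(seg, signal=_zero_phase(h, sig), band=band)


def reject_artifacts(segments: Sequence[Segment], threshold: float = 8.0) -> list[Segment]:
    """Drop segments whose peak amplitude exceeds ``threshold`` times the
    median absolute amplitude across all given segments.

    A crude stand-in for visual artifact screening; off by default in the
    pipeline (callers opt in).
    """
    if not segments:
        return []
    med = np.median([np.median(np.abs(s.signal)) for s in segments])
    if med == 0:
        return list(segments)
    return [s for s in segments if np.max(np.abs(s.signal)) <= threshold * med]
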