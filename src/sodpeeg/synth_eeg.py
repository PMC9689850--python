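"""Labeled synthetic multichannel EEG with seizure-like structure.

The generator emulates the statistical features the detection pipeline
relies on, so that every stage is testable without access to clinical
recordings:

* **Background (seizure-free)** segments are 1/f-shaped ("pink") noise
  plus band-limited Gaussian oscillations in the four clinical bands,
  shared across channels through a common source mixed with per-channel
  noise.  Scalp EEG background is approximated well by such a spectrum.
* **Seizure** segments add intermittent spike-wave discharge: trains of
  sharp biphasic transients, each followed by a slow wave, repeating at
  ``spike_rate`` (within the clinical 1.5-4 Hz spike-wave range) inside
  "on" periods that occupy ``burst_duty`` of the segment.  The overall
  RMS is ``amplitude_ratio`` times the background RMS -- the drastic
  amplitude increase characteristic of ictal EEG.

Segment-to-segment amplitude variability (log-normal, both for the
background level and for the seizure/background ratio) makes the two
classes overlap in any single amplitude-driven feature, as real data do.

What the generator does **not** model: physiological neural-mass
dynamics, eye-blink/EMG artifacts, electrode drift, inter-patient
variability.  Conclusions from synthetic benchmarks therefore speak to
the pipeline's mechanics, not to clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg_io import Segment

__all__ = ["SynthConfig", "gen_background", "gen_seizure", "gen_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults define the standard study conditions.

    ``band_powers`` are variances of the band-limited oscillation
    components relative to the 1/f component (variance 1 before overall
    scaling).  ``amplitude_sigma_log`` and ``ratio_sigma_log`` are the
    log-standard-deviations of the per-segment background-RMS and
    seizure-ratio jitter.
    """

    fs: float = 256.0
    n_channels: int = 23
    n_seizure: int = 100
    n_free: int = 100
    segment_s: float = 20.0
    background_rms: float = 10.0  # microvolts
    amplitude_ratio: float = 4.0  # seizure RMS / background RMS
    spike_rate: float = 2.5  # spike-wave complexes per second
    burst_duty: float = 0.6  # fraction of seizure time inside bursts
    band_powers: tuple[tuple[str, float], ...] = (
        ("delta", 0.8),
        ("theta", 0.5),
        ("alpha", 0.45),
        ("beta", 0.3),
    )
    channel_mixing: float = 0.7  # weight of the shared source per channel
    amplitude_sigma_log: float = 0.3
    ratio_sigma_log: float = 0.25
    mean_burst_s: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_ratio < 1.0:
            raise ValueError("amplitude_ratio must be >= 1")
        if self.spike_rate != 0 and not 1.5 <= self.spike_rate <= 4.0:
            raise ValueError("spike_rate must lie in the 1.5-4 Hz spike-wave range (or 0)")
        if not 0.0 < self.burst_duty <= 1.0:
            raise ValueError("burst_duty must lie in (0, 1]")
        if not 0.0 <= self.channel_mixing <= 1.0:
            raise ValueError("channel_mixing must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.segment_s * self.fs))


_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 15.0), "beta": (15.0, 30.0)}


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pink noise (power spectrum ~ 1/f above the lowest bin)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)  # normalized; shape only matters
    weight = np.zeros_like(f)
    weight[1:] = 1.0 / np.sqrt(np.maximum(f[1:], f[1]))
    x = np.fft.irfft(spec * weight, n)
    return x / x.std()


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to (lo, hi) Hz."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background_source(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """One unit-RMS background source: pink noise + band oscillations."""
    n = config.n_samples
    x = _pink_noise(n, rng)
    for band, power in config.band_powers:
        if power > 0:
            lo, hi = _BAND_EDGES[band]
            x = x + np.sqrt(power) * _band_noise(n, config.fs, lo, hi, rng)
    return x / np.sqrt(np.mean(x**2))


def _mix_channels(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Stack channels as shared source + independent noise, unit RMS each.

    ``ch = m * shared + sqrt(1 - m^2) * own`` keeps the per-channel
    variance at 1 while giving inter-channel correlation ``m^2``.
    """
    m = config.channel_mixing
    shared = _background_source(config, rng)
    chans = np.empty((config.n_channels, config.n_samples))
    for c in range(config.n_channels):
        own = _background_source(config, rng)
        chans[c] = m * shared + np.sqrt(1.0 - m * m) * own
    return chans


def gen_background(config: SynthConfig, rng: np.random.Generator) -> Segment:
    """One broadband seizure-free segment.

    Per-segment RMS is ``background_rms`` jittered log-normally
    (``amplitude_sigma_log``), mimicking slow drifts of overall EEG power.
    """
    level = config.background_rms * rng.lognormal(0.0, config.amplitude_sigma_log)
    sig = level * _mix_channels(config, rng)
    return Segment(signal=sig, label="seizure_free", band="broadband", start_s=0.0, fs=config.fs)


def _burst_gate(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """0/1 gating waveform with exponential on/off runs of duty burst_duty."""
    n = config.n_samples
    mean_on = config.mean_burst_s
    mean_off = mean_on * (1.0 - config.burst_duty) / config.burst_duty
    gate = np.zeros(n)
    t = 0
    on = rng.random() < config.burst_duty
    while t < n:
        mean = mean_on if on else mean_off
        length = int(round(max(0.2, rng.exponential(mean)) * config.fs))
        if on:
            gate[t : t + length] = 1.0
        t += length
        on = not on
    return gate


def _spike_wave_kernel(config: SynthConfig, width: float) -> np.ndarray:
    """One spike-wave complex: biphasic sharp transient + slow half-wave."""
    fs = config.fs
    period = int(round(fs / config.spike_rate))
    t = np.arange(period) / fs
    # Biphasic spike: derivative-of-Gaussian with the given width parameter.
    center = 3 * width
    spike = -(t - center) / width * np.exp(-((t - center) ** 2) / (2 * width**2))
    spike /= np.max(np.abs(spike))
    # Slow wave: half-sine occupying 60% of the complex period.
    wave = np.zeros(period)
    wlen = int(0.6 * period)
    wstart = int(round((center + 2 * width) * fs))
    wlen = min(wlen, period - wstart)
    wave[wstart : wstart + wlen] = 0.7 * np.sin(np.pi * np.arange(wlen) / wlen)
    return spike + wave


def _spike_train(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Gated spike-wave train, shared by all channels, arbitrary scale.

    Spike morphology (rise-time parameter, 5-25 ms) is drawn once per
    segment: spike-wave discharge is stereotyped within a run, with only
    mild complex-to-complex amplitude variation.
    """
    n = config.n_samples
    gate = _burst_gate(config, rng)
    train = np.zeros(n)
    period = config.fs / config.spike_rate
    width = rng.uniform(0.005, 0.025)
    t = rng.uniform(0, period)
    while t < n:
        start = int(t)
        if gate[min(start, n - 1)] > 0:
            kernel = _spike_wave_kernel(config, width) * rng.lognormal(0.0, 0.1)
            stop = min(start + kernel.size, n)
            train[start:stop] += kernel[: stop - start]
        t += period * rng.uniform(0.9, 1.1)
    return train


def gen_seizure(config: SynthConfig, rng: np.random.Generator) -> Segment:
    """One broadband seizure segment.

    Background plus an intermittent spike-wave train scaled so the total
    segment RMS is ``amplitude_ratio`` (log-normally jittered) times the
    configured background RMS.  With ``spike_rate = 0`` or
    ``amplitude_ratio = 1`` the output degenerates to background.
    """
    level = config.background_rms * rng.lognormal(0.0, config.amplitude_sigma_log)
    bg = level * _mix_channels(config, rng)
    ratio = config.amplitude_ratio * rng.lognormal(0.0, config.ratio_sigma_log)
    target_rms = max(ratio, 1.0) * level
    sig = bg
    if config.spike_rate > 0:
        train = _spike_train(config, rng)
        train_rms = np.sqrt(np.mean(train**2))
        bg_rms = np.sqrt(np.mean(bg**2))
        if train_rms > 0 and target_rms > bg_rms:
            k = np.sqrt(target_rms**2 - bg_rms**2) / train_rms
            m = config.channel_mixing
            chans = np.empty_like(bg)
            for c in range(config.n_channels):
                jitter = 1.0 + (1.0 - m) * rng.normal(0.0, 0.2)
                chans[c] = k * jitter * train
            sig = bg + chans
    return Segment(signal=sig, label="seizure", band="broadband", start_s=0.0, fs=config.fs)


def gen_dataset(config: SynthConfig) -> tuple[list[Segment], pd.DataFrame]:
    """Generate the full labeled segment collection plus a manifest.

    Returns ``n_seizure + n_free`` broadband segments in shuffled order
    and a manifest DataFrame (``segment_id``, ``label``), deterministic
    for a given ``config.seed``.
    """
    if config.n_seizure < 1 or config.n_free < 1:
        raise ValueError("need at least one segment of each class")
    rng = np.random.default_rng(config.seed)
    segments = [gen_seizure(config, rng) for _ in range(config.n_seizure)]
    segments += [gen_background(config, rng) for _ in range(config.n_free)]
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    manifest = pd.DataFrame(
        {"segment_id": np.arange(len(segments)), "label": [s.label for s in segments]}
    )
    return segments, manifest
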