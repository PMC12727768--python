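"""Synthetic test signals with known structure.

Two generators:

* :func:`make_triharmonic` — a three-tone signal plus optional Gaussian
  noise, the classic stress test for mode decomposition.
* :func:`make_synthetic_emg` — protocol-faithful multi-channel surrogate
  EMG.  Each motion class colors each channel with band-limited Gaussian
  noise (a band-pass-shaped white process, unit RMS, scaled by a per-channel
  gain) under a trapezoidal contraction envelope; rests carry low-amplitude
  broadband noise and are labelled class 0.  The default protocol is
  3 channels at 2000 Hz, 4 motion classes, 8 repetitions of 5-s contractions
  separated by 5-s rests.

The surrogate captures what the downstream features exploit — class-distinct
spectral coloring and amplitude modulation — not motor-unit physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import EmgRecording

__all__ = [
    "MotionProfile",
    "ProtocolSpec",
    "make_triharmonic",
    "make_synthetic_emg",
    "default_profiles",
]


@dataclass
class MotionProfile:
    """Spectral signature of one motion class: per-channel band centers,
    bandwidths (Hz) and amplitude gains."""

    class_id: int
    band_centers: tuple[float, ...]
    bandwidths: tuple[float, ...]
    gains: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.band_centers) == len(self.bandwidths) == len(self.gains)):
            raise ValueError("per-channel tuples must have equal length")
        if any(g <= 0 for g in self.gains):
            raise ValueError("gains must be positive")
        if any(not 10.0 < c < 450.0 for c in self.band_centers):
            raise ValueError("band centers must lie inside (10, 450) Hz")


@dataclass
class ProtocolSpec:
    """Acquisition protocol: 8 reps of 5-s contractions with 5-s rests on
    3 channels at 2000 Hz, 4 motions, unless overridden."""

    n_channels: int = 3
    fs: float = 2000.0
    n_motions: int = 4
    n_reps: int = 8
    contraction_s: float = 5.0
    rest_s: float = 5.0
    envelope_ramp_frac: float = 0.10
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_channels", "fs", "n_motions", "contraction_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 <= self.envelope_ramp_frac <= 0.5:
            raise ValueError("envelope_ramp_frac must lie in [0, 0.5]")


def make_triharmonic(
    fs: float,
    duration_s: float,
    freqs: tuple[float, float, float] = (10.0, 60.0, 200.0),
    amps: tuple[float, float, float] = (1.0, 0.5, 0.25),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum of three cosines plus seeded Gaussian noise."""
    if len(set(freqs)) != len(freqs):
        raise ValueError("frequencies must be distinct")
    if any(f >= fs / 2 for f in freqs):
        raise ValueError("frequencies must be below the Nyquist frequency")
    t = np.arange(int(round(fs * duration_s))) / fs
    x = np.zeros_like(t)
    for a, f in zip(amps, freqs):
        x += a * np.cos(2 * np.pi * f * t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sigma, size=t.size)
    return x


def default_profiles(protocol: ProtocolSpec) -> list[MotionProfile]:
    """Well-separated motion profiles: class band centers spread between
    40 and 320 Hz with per-channel offsets and distinct gains."""
    n_cls, n_ch = protocol.n_motions, protocol.n_channels
    base = np.linspace(40.0, 320.0, n_cls)
    profiles = []
    for c in range(n_cls):
        centers = tuple(float(base[c] + 12.0 * j) for j in range(n_ch))
        bands = tuple(20.0 for _ in range(n_ch))
        gains = tuple(1.0 + 0.4 * ((c + j) % n_ch) for j in range(n_ch))
        profiles.append(
            MotionProfile(
                class_id=c + 1, band_centers=centers, bandwidths=bands, gains=gains
            )
        )
    return profiles


def _trapezoid(n: int, ramp_frac: float) -> np.ndarray:
    env = np.ones(n)
    ramp = int(round(ramp_frac * n))
    if ramp > 0:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[n - ramp :] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    return env


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, center: float, bw: float
) -> np.ndarray:
    """Band-pass-shaped white noise, normalised to unit RMS."""
    low = max(center - bw / 2.0, 1.0)
    high = min(center + bw / 2.0, fs / 2.0 - 1.0)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not depress the window RMS
    pad = min(n, int(fs))
    x = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def make_synthetic_emg(
    protocol: ProtocolSpec, profiles: list[MotionProfile] | None = None
) -> EmgRecording:
    """Generate a labelled multi-channel surrogate recording.

    Trial order is repetition-major: within each repetition every motion is
    performed once (contraction then rest).  Labels are per-sample; the
    whole contraction including its ramps carries the class id, rests are 0.
    """
    if profiles is None:
        profiles = default_profiles(protocol)
    if len(profiles) != protocol.n_motions:
        raise ValueError("need one MotionProfile per motion class")
    for p in profiles:
        if len(p.band_centers) != protocol.n_channels:
            raise ValueError("profile channel count must match protocol")
        if any(c + b / 2 >= protocol.fs / 2 for c, b in zip(p.band_centers, p.bandwidths)):
            raise ValueError("profile band exceeds the Nyquist frequency")

    fs = protocol.fs
    n_con = int(round(protocol.contraction_s * fs))
    n_rest = int(round(protocol.rest_s * fs))
    total = protocol.n_reps * protocol.n_motions * (n_con + n_rest)

    rng = np.random.default_rng(protocol.seed)
    samples = np.zeros((protocol.n_channels, total))
    labels = np.zeros(total, dtype=int)
    env = _trapezoid(n_con, protocol.envelope_ramp_frac)

    # background/rest broadband noise everywhere
    for ch in range(protocol.n_channels):
        samples[ch] = rng.normal(0.0, protocol.noise_sigma, size=total)

    pos = 0
    for _rep in range(protocol.n_reps):
        for prof in profiles:
            for ch in range(protocol.n_channels):
                burst = _band_noise(
                    rng, n_con, fs, prof.band_centers[ch], prof.bandwidths[ch]
                )
                samples[ch, pos : pos + n_con] += prof.gains[ch] * env * burst
            labels[pos : pos + n_con] = prof.class_id
            pos += n_con + n_rest

    return EmgRecording(
        samples=samples, fs=fs, labels=labels, subject_id="synthetic"
    )
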