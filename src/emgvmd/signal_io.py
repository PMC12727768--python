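"""Multi-channel surface-EMG recordings: container, delimited-text I/O,
preprocessing filters and overlapping-window segmentation.

The preprocessing chain mirrors standard myoelectric-control practice: a
4th-order Butterworth band-pass (10-450 Hz) to isolate the EMG band, followed
by a 2nd-order 50 Hz IIR notch against power-line interference.  Both filters
are applied zero-phase (forward-backward) by default, with a causal single-pass
option for streaming parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("emgvmd")

__all__ = [
    "EmgRecording",
    "SegmentSet",
    "read_recording",
    "write_recording",
    "read_ninapro",
    "bandpass_filter",
    "notch_filter",
    "segment",
    "segment_labels",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EmgRecording:
    """A multi-channel EMG recording.

    Parameters
    ----------
    samples
        ``(n_channels, T)`` real matrix, one row per channel.
    fs
        Sampling rate in Hz.
    channel_names
        Optional channel names; defaults to ``ch0, ch1, ...``.
    labels
        Optional per-sample integer motion class (length ``T``); by
        convention 0 marks rest.
    subject_id
        Free-form identifier.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a channels x T matrix with T >= 1")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.samples.shape[1],):
                raise ValueError("labels length must equal number of samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SegmentSet:
    """Equal-length overlapping windows cut from a signal.

    ``segments`` is an ``(n_segments, window_samples)`` array; ``start_indices``
    are 0-based and half-open (a segment covers ``[s, s + window_samples)``).
    """

    segments: np.ndarray
    window_samples: int
    step_samples: int
    start_indices: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.start_indices = np.asarray(self.start_indices, dtype=int)
        if self.segments.shape[1] != self.window_samples:
            raise ValueError("every segment must have window_samples points")
        if len(self.start_indices) != self.segments.shape[0]:
            raise ValueError("one start index per segment required")
        if len(self.start_indices) > 1:
            steps = np.diff(self.start_indices)
            if not np.all(steps == self.step_samples):
                raise ValueError("start_indices must increase by step_samples")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    fs: float,
    has_labels: bool = False,
    delimiter: str = ",",
    subject_id: str = "",
) -> EmgRecording:
    """Read a delimited-text recording: one row per sample, one column per
    channel, optionally a final integer label column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(delimiter)
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row") from exc
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(vals)} != {width})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no samples")
    data = np.asarray(rows, dtype=float)
    labels = None
    if has_labels:
        if data.shape[1] < 2:
            raise ValueError("label column requested but file has a single column")
        labels = data[:, -1].astype(int)
        data = data[:, :-1]
    if data.shape[1] < 1:
        raise ValueError("fewer than 1 channel")
    return EmgRecording(samples=data.T, fs=fs, labels=labels, subject_id=subject_id)


def write_recording(rec: EmgRecording, path: str | Path, delimiter: str = ",") -> None:
    """Write a recording in the format read back by :func:`read_recording`.

    Samples are printed with 17 significant digits so a read-back reproduces
    them bit-identically.
    """
    cols: list[np.ndarray] = [rec.samples.T]
    fmt = ["%.17g"] * rec.n_channels
    if rec.labels is not None:
        cols.append(rec.labels[:, None].astype(float))
        fmt.append("%d")
    np.savetxt(path, np.hstack(cols), fmt=fmt, delimiter=delimiter)


def read_ninapro(path: str | Path, label_field: str = "restimulus") -> EmgRecording:
    """Optional reader for Ninapro-style MATLAB containers.

    Expects fields ``emg`` (T x channels) and ``stimulus``/``restimulus``
    (T x 1 labels) plus optionally ``frequency`` and ``subject``.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path), squeeze_me=True)
    if "emg" not in mat:
        raise ValueError("container has no 'emg' field")
    emg = np.atleast_2d(np.asarray(mat["emg"], dtype=float))  # stored T x channels
    labels = None
    for key in (label_field, "stimulus"):
        if key in mat:
            labels = np.asarray(mat[key]).ravel().astype(int)
            break
    fs = float(mat.get("frequency", 2000.0))
    return EmgRecording(
        samples=emg.T,
        fs=fs,
        labels=labels,
        subject_id=str(mat.get("subject", "")),
    )


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def _apply_sos(rec: EmgRecording, sos: np.ndarray, zero_phase: bool) -> EmgRecording:
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def bandpass_filter(
    rec: EmgRecording,
    low: float = 10.0,
    high: float = 450.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EmgRecording:
    """Butterworth band-pass, identical across channels.

    ``zero_phase=True`` applies the filter forward and backward (doubling the
    effective order, cancelling phase distortion); ``False`` is single-pass
    causal for streaming parity.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return _apply_sos(rec, sos, zero_phase)


def notch_filter(
    rec: EmgRecording,
    f0: float = 50.0,
    order: int = 2,
    bandwidth: float | None = None,
    q: float = 30.0,
    zero_phase: bool = True,
) -> EmgRecording:
    """IIR notch at ``f0`` (power-line rejection).

    The notch is the standard 2nd-order biquad; its width is set by the
    quality factor ``q`` (default 30), or by ``bandwidth`` in Hz via
    ``q = f0 / bandwidth``.
    """
    nyq = rec.fs / 2.0
    if not 0 < f0 < nyq:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, Nyquist={nyq} Hz)")
    if order != 2:
        raise ValueError("only the 2nd-order notch design is supported")
    if bandwidth is not None:
        q = f0 / bandwidth
    b, a = sps.iirnotch(f0, q, fs=rec.fs)
    sos = sps.tf2sos(b, a)
    return _apply_sos(rec, sos, zero_phase)


def filter_response(sos: np.ndarray, fs: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response |H(f)| of an SOS filter at the given frequencies."""
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs_hz, dtype=float) / fs)
    return np.abs(h)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
) -> SegmentSet:
    """Cut a signal into overlapping windows.

    Window length is ``round(window_ms * fs / 1000)`` samples; the step is
    ``round(window * (1 - overlap_frac))`` (so a 10 % overlap of a 500-sample
    window advances by 450 samples).  A trailing partial window is discarded.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    window = int(round(window_ms * fs / 1000.0))
    if window < 1:
        raise ValueError("window shorter than one sample")
    if x.size < window:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {window}-sample window"
        )
    step = int(round(window * (1.0 - overlap_frac)))
    step = max(step, 1)
    n_seg = (x.size - window) // step + 1
    starts = np.arange(n_seg) * step
    segs = np.lib.stride_tricks.sliding_window_view(x, window)[starts].copy()
    return SegmentSet(
        segments=segs, window_samples=window, step_samples=step, start_indices=starts
    )


def segment_labels(
    labels: np.ndarray, seg_set: SegmentSet, min_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Majority label per window.

    Returns ``(seg_labels, keep)`` where ``keep`` is False for windows in
    which no single class exceeds ``min_frac`` of the samples (windows
    straddling a class boundary).
    """
    labels = np.asarray(labels, dtype=int)
    out = np.empty(seg_set.n_segments, dtype=int)
    keep = np.ones(seg_set.n_segments, dtype=bool)
    w = seg_set.window_samples
    for i, s in enumerate(seg_set.start_indices):
        win = labels[s : s + w]
        vals, counts = np.unique(win, return_counts=True)
        j = int(np.argmax(counts))
        out[i] = vals[j]
        if counts[j] <= min_frac * w:
            keep[i] = False
    return out, keep
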