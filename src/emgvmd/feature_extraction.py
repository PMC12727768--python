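"""Per-segment feature vectors for myoelectric pattern recognition.

Five families are supported:

* ``TD8``      — eight time-domain descriptors per channel per window
                 (MAV, ZC, WL, RMS, SE, STD, VAR, SNR).
* ``VMD_SVD``  — decompose each channel into K variational modes, window
                 every mode, and reduce each window to its singular value.
* ``EMD_SVD``  — the same with intrinsic mode functions from EMD.
* ``LS4``/``LS9`` — compact descriptor sets from the open-source EMG
                 feature-library convention (MFL, MSR, WAMP, L-scale; and a
                 nine-feature superset).
* concatenations of the above via :func:`combine`.

For the decomposition sets the column count is channels x modes: every
(window, channel, mode) triple contributes exactly one scalar, the singular
value of the 1 x L window, i.e. its Euclidean norm (a reshaped-matrix
variant is available behind ``svd_mode='matrix'``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .emd_core import EmdConfig, emd_decompose
from .signal_io import EmgRecording, SegmentSet, segment, segment_labels
from .vmd_core import VmdConfig, vmd_decompose

__all__ = [
    "FeatureMatrix",
    "svd_singular_values",
    "segment_svd_feature",
    "td_features",
    "ls_features",
    "extract_td8",
    "extract_ls",
    "extract_vmd_svd",
    "extract_emd_svd",
    "combine",
    "TD8_NAMES",
    "LS4_NAMES",
    "LS9_NAMES",
]

TD8_NAMES = ("MAV", "ZC", "WL", "RMS", "SE", "STD", "VAR", "SNR")
LS4_NAMES = ("MFL", "MSR", "WAMP", "LS")
LS9_NAMES = ("MAV", "ZC", "SSC", "WL", "RMS", "IAV", "DASDV", "VAR", "LS")


@dataclass
class FeatureMatrix:
    """N windows x M features with labelled columns and per-row classes."""

    values: np.ndarray
    row_labels: np.ndarray | None
    col_names: list[str]
    feature_set_id: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.col_names) != self.values.shape[1]:
            raise ValueError("col_names length must equal number of columns")
        if self.row_labels is not None:
            self.row_labels = np.asarray(self.row_labels, dtype=int)
            if self.row_labels.shape != (self.values.shape[0],):
                raise ValueError("row_labels length must equal number of rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.col_names)
        if self.row_labels is not None:
            df["label"] = self.row_labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, feature_set_id: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(
            values=df.to_numpy(dtype=float),
            row_labels=labels,
            col_names=list(df.columns),
            feature_set_id=feature_set_id,
        )


# ---------------------------------------------------------------------------
# singular-value reduction
# ---------------------------------------------------------------------------

def svd_singular_values(X: np.ndarray) -> np.ndarray:
    """Singular values of a matrix, descending.

    Each equals the square root of an eigenvalue of X^T X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    return np.linalg.svd(X, compute_uv=False)


def segment_svd_feature(seg: np.ndarray, svd_mode: str = "vector") -> float:
    """Reduce a window to one scalar via SVD.

    ``'vector'`` (default): the window is a 1 x L matrix whose single
    singular value is its Euclidean norm.  ``'matrix'``: reshape the first
    r*c samples into an r x c matrix (r = floor(sqrt(L))) and return the
    leading singular value.
    """
    x = np.asarray(seg, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty segment")
    if svd_mode == "vector":
        return float(np.linalg.norm(x))
    if svd_mode == "matrix":
        r = int(np.floor(np.sqrt(x.size)))
        c = x.size // r
        return float(svd_singular_values(x[: r * c].reshape(r, c))[0])
    raise ValueError("svd_mode must be 'vector' or 'matrix'")


# ---------------------------------------------------------------------------
# scalar time-domain descriptors
# ---------------------------------------------------------------------------

def td_features(segment_: np.ndarray, zc_threshold: float = 0.0) -> np.ndarray:
    """MAV, ZC, WL, RMS, SE, STD, VAR, SNR of one window.

    ZC counts adjacent sign changes whose jump exceeds ``zc_threshold``.
    VAR is the n-1 sample variance; SE = STD / sqrt(n); SNR = MAV / STD
    (0 when STD is 0).
    """
    x = np.asarray(segment_, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    d = np.diff(x)
    mav = float(np.mean(np.abs(x)))
    zc = int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(d) > zc_threshold)))
    wl = float(np.sum(np.abs(d)))
    rms = float(np.sqrt(np.mean(x ** 2)))
    var = float(np.var(x, ddof=1))
    std = float(np.sqrt(var))
    se = std / np.sqrt(n)
    snr = mav / std if std > 0 else 0.0
    return np.array([mav, zc, wl, rms, se, std, var, snr])


def _l_scale(x: np.ndarray) -> float:
    """Second L-moment: a robust dispersion measure, 2*b1 - b0 with
    probability-weighted moments b0, b1 of the order statistics."""
    xs = np.sort(x)
    n = xs.size
    if n < 2:
        return 0.0
    b0 = xs.mean()
    b1 = float(np.sum(np.arange(n) * xs) / (n * (n - 1)))
    return 2.0 * b1 - b0


def ls_features(
    segment_: np.ndarray, which: str = "LS4", wamp_threshold: float = 0.05
) -> np.ndarray:
    """Compact descriptor sets.

    LS4: MFL (log10 of the waveform's RMS length, 0 for a flat window by
    convention), MSR, WAMP, L-scale.  LS9: MAV, ZC, SSC, WL, RMS, IAV,
    DASDV, VAR, L-scale.
    """
    x = np.asarray(segment_, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    d = np.diff(x)
    if which == "LS4":
        ssq = float(np.sum(d ** 2))
        mfl = float(np.log10(np.sqrt(ssq))) if ssq > 0 else 0.0
        msr = float(np.mean(np.sqrt(np.abs(x))))
        wamp = int(np.count_nonzero(np.abs(d) > wamp_threshold))
        return np.array([mfl, msr, wamp, _l_scale(x)])
    if which == "LS9":
        mav = float(np.mean(np.abs(x)))
        zc = int(np.count_nonzero(x[:-1] * x[1:] < 0))
        ssc = int(np.count_nonzero(d[:-1] * d[1:] < 0))
        wl = float(np.sum(np.abs(d)))
        rms = float(np.sqrt(np.mean(x ** 2)))
        iav = float(np.sum(np.abs(x)))
        dasdv = float(np.sqrt(np.mean(d ** 2)))
        var = float(np.var(x, ddof=1))
        return np.array([mav, zc, ssc, wl, rms, iav, dasdv, var, _l_scale(x)])
    raise ValueError("which must be 'LS4' or 'LS9'")


# ---------------------------------------------------------------------------
# recording-level extraction
# ---------------------------------------------------------------------------

def _segment_grid(
    rec: EmgRecording,
    window_ms: float,
    overlap_frac: float,
    include_rest: bool,
) -> tuple[SegmentSet, np.ndarray | None, np.ndarray]:
    """Common windowing grid plus per-window labels and the keep mask
    (majority-label rule; rest class 0 dropped unless ``include_rest``)."""
    base = segment(rec.samples[0], rec.fs, window_ms, overlap_frac)
    if rec.labels is None:
        return base, None, np.ones(base.n_segments, dtype=bool)
    labs, keep = segment_labels(rec.labels, base)
    if not include_rest:
        keep = keep & (labs != 0)
    return base, labs, keep

def _windows(x: np.ndarray, grid: SegmentSet) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(x, grid.window_samples)
    return view[grid.start_indices]


def _decomposition_features(
    rec: EmgRecording,
    components_per_channel: list[np.ndarray],
    comp_tag: str,
    n_components: int,
    grid: SegmentSet,
    labs: np.ndarray | None,
    keep: np.ndarray,
    set_id: str,
    svd_mode: str,
) -> FeatureMatrix:
    n_seg = grid.n_segments
    cols: list[np.ndarray] = []
    names: list[str] = []
    for ch, comps in enumerate(components_per_channel):
        for m in range(n_components):
            if m < comps.shape[0]:
                wins = _windows(comps[m], grid)
                if svd_mode == "vector":
                    vals = np.linalg.norm(wins, axis=1)
                else:
                    vals = np.array(
                        [segment_svd_feature(w, svd_mode) for w in wins]
                    )
            else:  # zero-fill components the decomposition did not produce
                vals = np.zeros(n_seg)
            cols.append(vals)
            names.append(f"{rec.channel_names[ch]}:{comp_tag}{m}:SV")
    values = np.column_stack(cols)[keep]
    row_labels = labs[keep] if labs is not None else None
    return FeatureMatrix(values, row_labels, names, set_id)


def extract_vmd_svd(
    rec: EmgRecording,
    K: int = 12,
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
    vmd_config: VmdConfig | None = None,
    svd_mode: str = "vector",
    include_rest: bool = False,
) -> FeatureMatrix:
    """VMD-SVD features: K modes per channel, one singular value per
    (window, channel, mode); M = channels x K columns, channel-major with
    modes in ascending center-frequency order."""
    if vmd_config is None:
        vmd_config = VmdConfig(K=K)
    elif vmd_config.K != K:
        raise ValueError("vmd_config.K must match K")
    grid, labs, keep = _segment_grid(rec, window_ms, overlap_frac, include_rest)
    comps = [vmd_decompose(ch, vmd_config).modes for ch in rec.samples]
    return _decomposition_features(
        rec, comps, "vmf", K, grid, labs, keep, "VMD_SVD", svd_mode
    )


def extract_emd_svd(
    rec: EmgRecording,
    n_imfs: int = 8,
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
    emd_config: EmdConfig | None = None,
    svd_mode: str = "vector",
    include_rest: bool = False,
) -> FeatureMatrix:
    """EMD-SVD baseline: as :func:`extract_vmd_svd` with IMFs.  Channels
    yielding fewer than ``n_imfs`` IMFs have the missing columns zero-filled
    so the matrix shape is stable across trials."""
    emd_config = emd_config or EmdConfig(max_imfs=n_imfs)
    grid, labs, keep = _segment_grid(rec, window_ms, overlap_frac, include_rest)
    comps = []
    for ch in rec.samples:
        res = emd_decompose(ch, emd_config)
        comps.append(
            np.array(res.imfs[:n_imfs]) if res.imfs else np.empty((0, ch.size))
        )
    return _decomposition_features(
        rec, comps, "imf", n_imfs, grid, labs, keep, "EMD_SVD", svd_mode
    )


def _scalar_set_features(
    rec: EmgRecording,
    names: tuple[str, ...],
    fn,
    set_id: str,
    window_ms: float,
    overlap_frac: float,
    include_rest: bool,
) -> FeatureMatrix:
    grid, labs, keep = _segment_grid(rec, window_ms, overlap_frac, include_rest)
    cols = []
    col_names = []
    for ch in range(rec.n_channels):
        wins = _windows(rec.samples[ch], grid)
        feats = np.array([fn(w) for w in wins])
        cols.append(feats)
        col_names.extend(f"{rec.channel_names[ch]}:{nm}" for nm in names)
    values = np.hstack(cols)[keep]
    row_labels = labs[keep] if labs is not None else None
    return FeatureMatrix(values, row_labels, col_names, set_id)


def extract_td8(
    rec: EmgRecording,
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
    zc_threshold: float = 0.0,
    include_rest: bool = False,
) -> FeatureMatrix:
    """Eight time-domain features per channel per window (M = channels x 8)."""
    return _scalar_set_features(
        rec,
        TD8_NAMES,
        lambda w: td_features(w, zc_threshold),
        "TD8",
        window_ms,
        overlap_frac,
        include_rest,
    )


def extract_ls(
    rec: EmgRecording,
    which: str = "LS4",
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
    wamp_threshold: float = 0.05,
    include_rest: bool = False,
) -> FeatureMatrix:
    """LS4 (M = channels x 4) or LS9 (M = channels x 9) descriptor sets."""
    names = LS4_NAMES if which == "LS4" else LS9_NAMES
    return _scalar_set_features(
        rec,
        names,
        lambda w: ls_features(w, which, wamp_threshold),
        which,
        window_ms,
        overlap_frac,
        include_rest,
    )


def combine(sets: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature sets sharing rows and labels."""
    if not sets:
        raise ValueError("no feature matrices to combine")
    if len(sets) == 1:
        return sets[0]
    first = sets[0]
    for fm in sets[1:]:
        if fm.n_rows != first.n_rows:
            raise ValueError("row count mismatch")
        if (first.row_labels is None) != (fm.row_labels is None):
            raise ValueError("label presence mismatch")
        if first.row_labels is not None and not np.array_equal(
            first.row_labels, fm.row_labels
        ):
            raise ValueError("row label mismatch")
    return FeatureMatrix(
        values=np.hstack([fm.values for fm in sets]),
        row_labels=first.row_labels,
        col_names=[nm for fm in sets for nm in fm.col_names],
        feature_set_id="+".join(fm.feature_set_id for fm in sets),
    )
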