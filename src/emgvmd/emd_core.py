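"""Empirical Mode Decomposition (EMD) by sifting.

EMD peels a signal into Intrinsic Mode Functions (IMFs): zero-local-mean
AM-FM components whose extrema and zero-crossing counts differ by at most
one.  Each IMF is obtained by repeatedly subtracting the midline of the
cubic-spline envelopes through the local maxima and minima (sifting); the
IMF is then removed from the running residue and the process repeats until
the residue is monotonic (or nearly so) or a cap is reached.  The residue is
defined as input minus the sum of IMFs, so reconstruction is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EmdConfig",
    "EmdResult",
    "CannotSiftError",
    "find_extrema",
    "envelope_mean",
    "sift_imf",
    "emd_decompose",
]


class CannotSiftError(ValueError):
    """Signal has too few extrema for envelope construction; the caller
    treats the current signal as the residue."""


@dataclass
class EmdConfig:
    """Sifting controls.

    max_imfs     cap on extracted IMFs.
    sift_sd_tol  Cauchy stopping threshold per sift:
                 sum((p_prev - p)^2) / sum(p_prev^2) < sift_sd_tol.
    max_sifts    cap on sifting iterations per IMF.
    boundary     extrema extension scheme ('mirror': reflect the two
                 outermost extrema at each end before spline fitting).
    """

    max_imfs: int = 10
    sift_sd_tol: float = 0.2
    max_sifts: int = 100
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if not self.sift_sd_tol > 0:
            raise ValueError("sift_sd_tol must be positive")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")


@dataclass
class EmdResult:
    """Ordered IMFs (fast to slow) plus the residue; summing them
    reproduces the input exactly."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residue: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for h in self.imfs:
            out += h
        return out


# ---------------------------------------------------------------------------
# extrema and envelopes
# ---------------------------------------------------------------------------

def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; a flat plateau between a
    rise and a fall counts once, at its midpoint sample."""
    x = np.asarray(x, dtype=float)
    diffs = np.diff(x)
    nz = np.flatnonzero(diffs)
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    signs = np.sign(diffs[nz])
    turns = np.flatnonzero(signs[:-1] != signs[1:])
    maxima, minima = [], []
    for j in turns:
        left = nz[j] + 1       # first sample after the run ends
        right = nz[j + 1]      # last sample of the plateau (inclusive)
        mid = (left + right) // 2
        if signs[j] > 0:
            maxima.append(mid)
        else:
            minima.append(mid)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _extend_extrema(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema across each end of the support so the spline
    is anchored outside [0, n-1] (suppresses end swings)."""
    left_i = [-i for i in idx[:2] if i > 0][::-1]
    left_v = [val[k] for k in range(min(2, idx.size)) if idx[k] > 0][::-1]
    last = n - 1
    right_i = [2 * last - i for i in idx[-2:][::-1] if i < last]
    right_v = [
        val[idx.size - 1 - k] for k in range(min(2, idx.size)) if idx[idx.size - 1 - k] < last
    ]
    ext_i = np.concatenate([left_i, idx, right_i])
    ext_v = np.concatenate([left_v, val, right_v])
    order = np.argsort(ext_i, kind="stable")
    ext_i, ext_v = ext_i[order], ext_v[order]
    uniq = np.concatenate([[True], np.diff(ext_i) > 0])
    return ext_i[uniq], ext_v[uniq]


def envelope_mean(signal: np.ndarray) -> np.ndarray:
    """Midline n(t) = (upper(t) + lower(t)) / 2 of the cubic-spline envelopes
    through the maxima and minima."""
    x = np.asarray(signal, dtype=float).ravel()
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise CannotSiftError(
            f"need >= 2 maxima and >= 2 minima (found {maxima.size}, {minima.size})"
        )
    t = np.arange(x.size)
    mi, mv = _extend_extrema(maxima, x[maxima], x.size)
    upper = CubicSpline(mi, mv)(t)
    ni, nv = _extend_extrema(minima, x[minima], x.size)
    lower = CubicSpline(ni, nv)(t)
    return (upper + lower) / 2.0


# ---------------------------------------------------------------------------
# sifting
# ---------------------------------------------------------------------------

def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def _is_imf(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _count_zero_crossings(x)) <= 1


def sift_imf(signal: np.ndarray, config: EmdConfig | None = None) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate by repeated envelope-midline subtraction.

    Stops when the per-sift relative change falls below ``sift_sd_tol`` and
    the extrema/zero-crossing property holds, or at ``max_sifts``.
    """
    config = config or EmdConfig()
    p = np.asarray(signal, dtype=float).ravel().copy()
    n_sifts = 0
    for _ in range(config.max_sifts):
        try:
            midline = envelope_mean(p)
        except CannotSiftError:
            if n_sifts == 0:
                raise
            break
        p_new = p - midline
        n_sifts += 1
        denom = float(np.sum(p ** 2))
        sd = float(np.sum((p - p_new) ** 2)) / denom if denom > 0 else 0.0
        p = p_new
        if sd < config.sift_sd_tol and _is_imf(p):
            break
    return p, n_sifts


def emd_decompose(signal: np.ndarray, config: EmdConfig | None = None) -> EmdResult:
    """Full decomposition: successive sifting of the residue.

    Stops when the residue becomes unsiftable (monotonic, constant, or with
    a single extremal pair) or ``max_imfs`` is reached.
    """
    config = config or EmdConfig()
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("signal too short to decompose (need >= 4 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < config.max_imfs:
        try:
            imf, _ = sift_imf(residue, config)
        except CannotSiftError:
            break
        imfs.append(imf)
        residue = residue - imf
    # re-derive the residue from the input so reconstruction is exact
    residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return EmdResult(imfs=imfs, residue=residue)
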