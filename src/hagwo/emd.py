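"""Empirical Mode Decomposition (EMD) and partial-reconstruction denoising.

EMD decomposes a uniformly sampled signal x(T) into a finite set of
intrinsic mode functions (IMFs) c_i(T) plus a monotone/trend residual r(T):

    x(T) = sum_i c_i(T) + r(T)

Each IMF is obtained by *sifting*: repeatedly subtracting the mean of the
cubic-spline envelopes through the local maxima and minima until the result
satisfies the IMF criterion (the numbers of extrema and zero crossings
differ by at most one) and the change between successive iterates is small.
High-frequency IMFs are dominated by broadband noise in EEG recordings, so
denoising keeps only the IMFs from some index K onward plus the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Signal",
    "IMFSet",
    "SiftConfig",
    "TrendError",
    "find_extrema",
    "envelope_mean",
    "sift",
    "decompose",
    "denoise",
    "default_first_kept",
]


class TrendError(ValueError):
    """Raised when a signal is monotone/trend-like (too few extrema to sift)."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled 1-D trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude values, length >= 8, all finite.
    sampling_rate : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 8:
            raise ValueError("signal must be 1-D with at least 8 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs plus the residual of a decomposition.

    Invariant: ``sum(imfs) + residual`` reconstructs the decomposed signal
    (exact up to floating-point rounding, since the residual is defined by
    successive subtraction).
    """

    imfs: tuple
    residual: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        object.__setattr__(self, "imfs", tuple(np.asarray(c, float) for c in self.imfs))
        object.__setattr__(self, "residual", np.asarray(self.residual, float))
        n = self.residual.size
        if any(c.size != n for c in self.imfs):
            raise ValueError("all IMFs must have the same length as the residual")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


@dataclass(frozen=True)
class SiftConfig:
    """Stopping controls for the sifting loop.

    sd_threshold is the classical Cauchy-type criterion
    SD = sum((h_prev - h)^2) / sum(h_prev^2); sifting stops once SD falls
    below it *and* the IMF count criterion holds, or after max_sifts passes.
    """

    sd_threshold: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 12
    boundary: str = "mirror"

    def __post_init__(self):
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")
        if self.boundary != "mirror":
            raise ValueError("only 'mirror' boundary handling is supported")


# ---------------------------------------------------------------------------
# Extrema and envelopes
# ---------------------------------------------------------------------------

def find_extrema(x) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima, in ascending order.

    Plateaus (runs of equal values flanked by opposite slopes) contribute
    their midpoint index. Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if nz.size < 2:
        empty = np.array([], dtype=int)
        return empty, empty
    s = np.sign(dx[nz])
    turn = np.flatnonzero(np.diff(s))
    # the extremum (possibly a plateau) spans samples nz[c]+1 .. nz[c+1]
    mids = (nz[turn] + 1 + nz[turn + 1]) // 2
    maxima = mids[s[turn] > 0]
    minima = mids[s[turn] < 0]
    return maxima.astype(int), minima.astype(int)


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _is_imf(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _count_zero_crossings(x)) <= 1


def _mirrored_spline(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through extrema, extended by mirroring the two nearest
    extrema across each end of the index range [0, n-1]."""
    idx = list(indices)
    val = list(values)
    k = min(2, len(idx))
    left_idx = [-i for i in idx[:k]][::-1]
    left_val = val[:k][::-1]
    right_idx = [2 * (n - 1) - i for i in idx[-k:]][::-1]
    right_val = val[-k:][::-1]
    xs = np.asarray(left_idx + idx + right_idx, dtype=float)
    ys = np.asarray(left_val + val + right_val, dtype=float)
    # mirroring can duplicate an index when an extremum sits at an endpoint
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    spline = CubicSpline(xs, ys)
    return spline(np.arange(n, dtype=float))


def envelope_mean(x, maxima, minima) -> np.ndarray:
    """Mean of the upper (through maxima) and lower (through minima)
    cubic-spline envelopes, M(T), over the full index range."""
    x = np.asarray(x, dtype=float)
    maxima = np.asarray(maxima, dtype=int)
    minima = np.asarray(minima, dtype=int)
    if maxima.size < 2 or minima.size < 2:
        raise TrendError("too few extrema to form envelopes (trend signal)")
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return (upper + lower) / 2.0


# ---------------------------------------------------------------------------
# Sifting and decomposition
# ---------------------------------------------------------------------------

def sift(signal, cfg: SiftConfig = SiftConfig()) -> np.ndarray:
    """Extract one IMF from a signal by iterated envelope-mean subtraction.

    Stops when the IMF count criterion holds and the normalized squared
    change SD between successive iterates falls below ``cfg.sd_threshold``,
    or after ``cfg.max_sifts`` iterations.
    """
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, float)
    h = x.astype(float).copy()
    maxima, minima = find_extrema(h)
    if maxima.size < 2 or minima.size < 2:
        raise TrendError("signal has too few extrema to sift")
    for _ in range(cfg.max_sifts):
        m = envelope_mean(h, maxima, minima)
        h_new = h - m
        if not np.all(np.isfinite(h_new)):
            raise ArithmeticError("sifting produced non-finite values")
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if _is_imf(h) and sd < cfg.sd_threshold:
            break
        maxima, minima = find_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
    return h


def decompose(signal: Signal, cfg: SiftConfig = SiftConfig()) -> IMFSet:
    """Full EMD: repeatedly sift and subtract until the running residual is
    monotone/trend-like or ``cfg.max_imfs`` IMFs have been extracted."""
    residual = signal.samples.astype(float).copy()
    total_energy = float(np.sum(residual * residual))
    imfs = []
    for _ in range(cfg.max_imfs):
        # numerically negligible residuals are treated as fully decomposed
        if float(np.sum(residual * residual)) <= 1e-6 * total_energy:
            break
        maxima, minima = find_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = sift(residual, cfg)
        if float(np.sum(imf * imf)) <= 1e-12 * max(float(np.sum(residual * residual)), 1e-30):
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=tuple(imfs), residual=residual, sampling_rate=signal.sampling_rate)


def denoise(imfset: IMFSet, first_kept: int) -> Signal:
    """Partial reconstruction keeping IMFs from index ``first_kept`` (1-based)
    onward plus the residual; the discarded leading IMFs carry the
    high-frequency noise."""
    n = imfset.n_imfs
    if not 1 <= first_kept <= n + 1:
        raise ValueError(f"first_kept must be in [1, {n + 1}], got {first_kept}")
    out = imfset.residual.copy()
    for c in imfset.imfs[first_kept - 1:]:
        out += c
    return Signal(samples=out, sampling_rate=imfset.sampling_rate)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return 1.0
    return float(np.dot(x[:-1], x[1:])) / denom


def default_first_kept(imfset: IMFSet) -> int:
    """Choose the first IMF to keep: the smallest K >= 2 whose IMF has lag-1
    autocorrelation >= 0.5 (noise IMFs are serially uncorrelated, smooth
    oscillations are not); falls back to 2, and to 1 when only one IMF
    exists, so at most the leading noise IMFs are ever discarded."""
    if imfset.n_imfs == 0:
        raise ValueError("empty decomposition")
    if imfset.n_imfs == 1:
        return 1
    for k in range(2, imfset.n_imfs + 1):
        if _lag1_autocorr(imfset.imfs[k - 1]) >= 0.5:
            return k
    return 2
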