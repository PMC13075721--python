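"""Per-signal EEG feature extraction and labeled feature tables.

Features per signal: four time-domain moments (mean, variance, skewness,
excess kurtosis), band power in each named frequency band of a
:class:`BandScheme`, spectral entropy of the normalized periodogram, and the
dominant frequency. Spectral quantities use a Hann-windowed one-sided
periodogram with the DC bin excluded from entropy and dominant frequency.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .emd import Signal

__all__ = [
    "BandScheme",
    "FeatureTable",
    "TimeFeatures",
    "time_features",
    "band_powers",
    "spectral_entropy",
    "dominant_frequency",
    "build_table",
]

TimeFeatures = namedtuple("TimeFeatures", ["mean", "variance", "skewness", "kurtosis"])

#: Conventional clinical EEG band edges (Hz).
DEFAULT_BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Named, non-overlapping, ascending frequency bands."""

    bands: tuple = DEFAULT_BANDS

    def __post_init__(self):
        bands = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.bands)
        object.__setattr__(self, "bands", bands)
        prev_hi = -np.inf
        for name, lo, hi in bands:
            if hi <= lo:
                raise ValueError(f"band {name!r}: high must exceed low")
            if lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps or is out of order")
            prev_hi = hi

    @property
    def names(self) -> list:
        return [b[0] for b in self.bands]

    def validate_nyquist(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for name, lo, hi in self.bands:
            if hi > nyq:
                raise ValueError(f"band {name!r} exceeds Nyquist ({nyq} Hz)")


@dataclass
class FeatureTable:
    """An n_samples x N numeric feature matrix with labels and column names.

    The CSV representation has one header row, one numeric column per
    feature, and a final integer column literally named ``label``.
    """

    values: np.ndarray
    feature_names: list
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("at least one feature required")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match the number of columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if "label" in self.feature_names:
            raise ValueError("'label' is reserved for the label column")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        labels = df["label"].to_numpy()
        feats = df.drop(columns=["label"])
        return cls(values=feats.to_numpy(dtype=float),
                   feature_names=list(feats.columns), labels=labels)


# ---------------------------------------------------------------------------
# Individual features
# ---------------------------------------------------------------------------

def time_features(signal: Signal) -> TimeFeatures:
    """Population moments: mean, variance, skewness, excess kurtosis.

    A zero-variance trace yields skewness and kurtosis of 0 with a warning
    (the moments are undefined there).
    """
    x = signal.samples
    mean = float(np.mean(x))
    var = float(np.var(x))
    if var <= 0:
        warnings.warn("zero-variance signal: skewness/kurtosis reported as 0")
        return TimeFeatures(mean, var, 0.0, 0.0)
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))  # excess kurtosis
    return TimeFeatures(mean, var, skew, kurt)


def _periodogram(signal: Signal):
    freqs, psd = sps.periodogram(signal.samples, fs=signal.sampling_rate,
                                 window="hann", scaling="density")
    return freqs, psd


def band_powers(signal: Signal, scheme: BandScheme = BandScheme()) -> dict:
    """Periodogram power integrated within each band, in amplitude^2 units."""
    scheme.validate_nyquist(signal.sampling_rate)
    freqs, psd = _periodogram(signal)
    df = freqs[1] - freqs[0]
    out = {}
    for name, lo, hi in scheme.bands:
        sel = (freqs >= lo) & (freqs < hi)
        if not np.any(sel):
            warnings.warn(f"band {name!r} is empty at this frequency resolution")
            out[name] = 0.0
        else:
            out[name] = float(np.sum(psd[sel]) * df)
    return out


def spectral_entropy(signal: Signal) -> float:
    """Shannon entropy of the normalized periodogram (DC excluded), divided
    by log(#bins) so a pure tone is near 0 and white noise near 1."""
    freqs, psd = _periodogram(signal)
    psd = psd[1:]  # drop DC
    total = float(np.sum(psd))
    if total <= 0:
        raise ValueError("spectral entropy undefined for a zero signal")
    p = psd / total
    p = p[p > 0]
    h = -float(np.sum(p * np.log(p)))
    return h / np.log(psd.size)


def dominant_frequency(signal: Signal) -> float:
    """Frequency (Hz) of the maximal periodogram bin, DC excluded; ties go
    to the lower frequency."""
    freqs, psd = _periodogram(signal)
    if float(np.sum(psd[1:])) <= 0:
        raise ValueError("dominant frequency undefined for a zero signal")
    return float(freqs[1:][np.argmax(psd[1:])])


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def feature_names(scheme: BandScheme = BandScheme()) -> list:
    names = ["mean", "variance", "skewness", "kurtosis"]
    names += [f"power_{b}" for b in scheme.names]
    names += ["spectral_entropy", "dominant_frequency"]
    return names


def build_table(signals, labels, scheme: BandScheme = BandScheme(),
                skip_bad: bool = False) -> FeatureTable:
    """One feature row per signal. Degenerate (zero-variance) signals abort
    the run unless ``skip_bad`` is set, in which case their rows are dropped."""
    signals = list(signals)
    labels = np.asarray(labels)
    if len(signals) != labels.size:
        raise ValueError("signals and labels must have equal counts")
    rows, kept = [], []
    for i, sig in enumerate(signals):
        if float(np.var(sig.samples)) <= 0:
            if skip_bad:
                warnings.warn(f"signal {i} is degenerate; row skipped")
                continue
            raise ValueError(f"signal {i} is degenerate (zero variance); "
                             "use skip_bad=True to drop such rows")
        tf = time_features(sig)
        bp = band_powers(sig, scheme)
        row = [tf.mean, tf.variance, tf.skewness, tf.kurtosis]
        row += [bp[b] for b in scheme.names]
        row += [spectral_entropy(sig), dominant_frequency(sig)]
        rows.append(row)
        kept.append(i)
    return FeatureTable(values=np.asarray(rows, dtype=float),
                        feature_names=feature_names(scheme),
                        labels=labels[kept])
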