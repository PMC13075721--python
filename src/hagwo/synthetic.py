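"""Synthetic signals and labeled feature tables with known ground truth.

Two generators make the rest of the package testable without any external
recordings: band-structured noisy tone signals (a stand-in for single-channel
EEG traces), and feature tables with a planted set of informative columns
whose class-conditional means differ by a chosen standardized effect size
(Cohen's d). A deterministic planted-subset fitness provides a cheap,
exactly optimizable objective for exercising the feature selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_features import FeatureTable
from .emd import Signal

__all__ = [
    "SignalSpec",
    "TableSpec",
    "PlantedOracle",
    "make_signal",
    "make_feature_table",
    "planted_fitness",
]


@dataclass(frozen=True)
class SignalSpec:
    """A sum of sinusoidal tones plus white Gaussian noise.

    tones: list of (frequency Hz, amplitude) pairs; the sampling rate must
    exceed twice the highest tone frequency (Nyquist).
    """

    duration: float
    sampling_rate: float
    tones: tuple
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "tones", tuple((float(f), float(a)) for f, a in self.tones))
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tones:
            f_max = max(f for f, _ in self.tones)
            if self.sampling_rate <= 2 * f_max:
                raise ValueError(
                    f"sampling_rate {self.sampling_rate} Hz violates Nyquist for a "
                    f"{f_max} Hz tone (need > {2 * f_max} Hz)")


@dataclass(frozen=True)
class TableSpec:
    """A two-class feature table with planted informative columns.

    Informative columns are unit-variance normal with the class-1 mean
    shifted by ``effect_size`` (so the between-class standardized mean
    difference equals Cohen's d = effect_size); the remaining columns are
    label-independent standard normal noise.
    """

    n_samples: int
    n_features: int
    n_informative: int
    effect_size: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("need 0 < n_informative <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.class_balance <= 1:
            raise ValueError("class_balance must be in [0, 1]")


@dataclass(frozen=True)
class PlantedOracle:
    """A known target subset; fitness is Hamming similarity to it."""

    n_features: int
    target: np.ndarray

    def __post_init__(self):
        target = np.asarray(self.target).astype(bool)
        object.__setattr__(self, "target", target)
        if target.shape != (self.n_features,):
            raise ValueError("target length must equal n_features")
        if not target.any():
            raise ValueError("target must have at least one set bit")


def make_signal(spec: SignalSpec) -> tuple[Signal, Signal]:
    """Return (clean, noisy): the tone mixture and the same plus white noise.

    Deterministic given ``spec.seed``; with ``noise_sd == 0`` the two are
    identical.
    """
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    clean = np.zeros(n)
    for f, a in spec.tones:
        clean = clean + a * np.sin(2 * np.pi * f * t)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=n)
    return (Signal(clean, spec.sampling_rate), Signal(noisy, spec.sampling_rate))


def make_feature_table(spec: TableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Generate a labeled table plus the boolean informative-column mask.

    The class-1 count is the rounded ``class_balance`` fraction of rows and
    label positions are a seeded permutation, so the realized balance is
    exact to rounding. Informative column positions are a seeded draw.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_pos = int(round(spec.class_balance * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    values = rng.standard_normal((n, p))
    informative = np.zeros(p, dtype=bool)
    informative[rng.choice(p, size=spec.n_informative, replace=False)] = True
    values[np.ix_(labels == 1, informative)] += spec.effect_size
    names = [f"f{i:03d}" for i in range(p)]
    return FeatureTable(values=values, feature_names=names, labels=labels), informative


def planted_fitness(oracle: PlantedOracle, subset) -> float:
    """1 - Hamming(subset, target)/n_features: the unique maximum 1.0 is
    attained exactly at the planted target subset."""
    subset = np.asarray(subset).astype(bool)
    if subset.shape != (oracle.n_features,):
        raise ValueError("subset length must equal the oracle's n_features")
    hamming = int(np.count_nonzero(subset != oracle.target))
    return 1.0 - hamming / oracle.n_features


def write_mask_csv(path, feature_names, mask) -> None:
    """Side-car CSV of (feature_name, informative in {0,1})."""
    pd.DataFrame({"feature_name": list(feature_names),
                  "informative": np.asarray(mask).astype(int)}).to_csv(path, index=False)
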