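"""Periodogram power-spectral-density baseline features.

The baseline feature set against which the connectivity estimators are
compared: each channel's one-sided periodogram

.. math:: \\hat p(f) = \\frac{\\Delta t}{N}\\Big|\\sum_{n=0}^{N-1} x_n e^{-j 2\\pi f \\Delta t n}\\Big|^2

(no taper — a plain rectangular-window periodogram), concatenated in
channel order.  The FFT length defaults to the next power of two at or
above the epoch length, which gives ``nfft/2 + 1`` one-sided bins per
channel; six 300-sample channels at nfft=512 yield the canonical 1542
features per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "periodogram",
    "psd_features",
    "PsdFeatureTable",
    "PeriodogramTransformer",
    "next_pow2",
]


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be positive")
    return 1 << (int(n) - 1).bit_length()


def periodogram(
    x: np.ndarray, fs: float, nfft: int | str = "next_pow2"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram of one signal.

    ``nfft`` is either an explicit FFT length or the default policy
    ``"next_pow2"`` (smallest power of two >= the signal length).  Returns
    ``(freqs, power)`` in density scaling, i.e. ``Δt/N |X(f)|²`` with
    interior bins doubled for the one-sided form.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D vector")
    if nfft == "next_pow2":
        nfft = next_pow2(x.size)
    nfft = int(nfft)
    if nfft < x.size:
        raise ValueError("nfft must be >= signal length")
    freqs, power = signal.periodogram(
        x, fs=fs, window="boxcar", nfft=nfft, detrend=False, scaling="density"
    )
    return freqs, power


@dataclass
class PsdFeatureTable:
    """Per-epoch PSD feature matrix: channel-ordered periodogram bins."""

    values: np.ndarray  # epoch x (k * (nfft/2 + 1))
    columns: list[str]
    bin_freqs: np.ndarray  # Hz per column
    labels: np.ndarray
    subjects: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "subject", self.subjects)
        df.insert(0, "label", self.labels)
        return df


def psd_features(epochs: EpochSet, nfft: int | None = None) -> PsdFeatureTable:
    """Concatenated per-channel periodograms of every epoch.

    With unequal epoch lengths across labels the shared FFT length is the
    next power of two covering the longest epoch (explicitly overridable via
    ``nfft``), so every epoch maps into the same feature space.
    """
    if nfft is None:
        nfft = next_pow2(max(x.shape[1] for x in epochs.data))
    rows = []
    bin_freqs_one = None
    for x in epochs.data:
        chans = []
        for c in range(x.shape[0]):
            f, p = periodogram(x[c], epochs.fs, nfft)
            chans.append(p)
            bin_freqs_one = f
        rows.append(np.concatenate(chans))
    columns = [
        f"{name}_psd_{f:g}Hz"
        for name in epochs.channel_names
        for f in bin_freqs_one
    ]
    return PsdFeatureTable(
        values=np.vstack(rows),
        columns=columns,
        bin_freqs=np.tile(bin_freqs_one, epochs.n_channels),
        labels=epochs.labels.copy(),
        subjects=epochs.subjects.copy(),
    )


class PeriodogramTransformer:
    """Scikit-learn style transformer: epoch tensor -> periodogram features."""

    def __init__(self, fs: float = 250.0, nfft: int | None = None):
        self.fs = fs
        self.nfft = nfft

    def get_params(self, deep: bool = True) -> dict:
        return {"fs": self.fs, "nfft": self.nfft}

    def set_params(self, **params) -> "PeriodogramTransformer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "PeriodogramTransformer":
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected an epoch x channel x sample array")
        nfft = self.nfft if self.nfft is not None else next_pow2(X.shape[2])
        rows = []
        for x in X:
            rows.append(
                np.concatenate(
                    [periodogram(x[c], self.fs, nfft)[1] for c in range(x.shape[0])]
                )
            )
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
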