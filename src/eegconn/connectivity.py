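"""Directed connectivity estimators on windowed MVAR fits.

Four directed-influence measures are computed from each window's MVAR
model, assembled into a ``source x target x frequency x window`` tensor:

* **GGC** (Granger–Geweke causality index, time domain):
  ``GCI(s -> t) = ln( var_t(model without channel s) / var_t(full model) )``,
  floored at zero and replicated across the frequency axis so every
  estimator shares the 4-D tensor shape.
* **DTF** (directed transfer function): from ``H(f) = A̅(f)^{-1}``,
  ``dtf(s -> t, f) = |H_ts(f)|² / Σ_m |H_tm(f)|²`` — normalised over all
  inflows into the target, so the tensor sums to one over the *source* axis.
* **PDC** (partial directed coherence): from the coefficient spectrum
  ``A̅(f) = I - Σ_r A(r) e^{-i 2π f r / fs}``,
  ``pdc(s -> t, f) = |A̅_ts(f)|² / Σ_m |A̅_ms(f)|²`` — normalised over all
  outflows of the source, so the tensor sums to one over the *target* axis.
* **GPDC** (generalised PDC): PDC with entries weighted by inverse
  innovation variances, ``(|A̅_ts|²/σ_t²) / Σ_m (|A̅_ms|²/σ_m²)``, robust to
  unequal innovation scales.

The squared-magnitude convention is used throughout so all spectral
estimators live on a comparable [0, 1] power-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .epochs import EpochSet
from .mvar import MVARModel, fit_mvar
from .preprocessing import WindowPlan, plan_windows

__all__ = [
    "ConnectivityTensor",
    "FeatureTable",
    "DEFAULT_FREQS",
    "coeff_fourier",
    "transfer_function",
    "spectral_measure",
    "dtf",
    "pdc",
    "gpdc",
    "ggc_index",
    "epoch_connectivity",
    "connectivity_features",
    "average_connectivity",
    "ConnectivityTransformer",
]

#: Analysis grid: integer frequencies 1..20 Hz.
DEFAULT_FREQS = np.arange(1.0, 21.0)

ESTIMATORS = ("ggc", "dtf", "pdc", "gpdc")


@dataclass
class ConnectivityTensor:
    """Estimator values indexed ``source x target x frequency x window``."""

    estimator: str
    values: np.ndarray  # (k, k, F, W)
    freqs: np.ndarray
    windows: WindowPlan | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        v = self.values
        if v.ndim != 4 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be (k, k, F, W)")
        if np.any(~np.isfinite(v)):
            raise ValueError("connectivity tensor contains non-finite values")
        if np.min(v) < -1e-9:
            raise ValueError("connectivity values must be non-negative")
        if self.estimator == "dtf":
            # Inflow normalisation: sum over sources for each target.
            if not np.allclose(v.sum(axis=0), 1.0, atol=tol):
                raise ValueError("DTF normalisation violated")
        elif self.estimator in ("pdc", "gpdc"):
            # Outflow normalisation: sum over targets for each source.
            if not np.allclose(v.sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"{self.estimator.upper()} normalisation violated")
        elif self.estimator == "ggc":
            if not np.allclose(v, v[:, :, :1, :]):
                raise ValueError("GGC must be constant across the frequency axis")
        else:
            raise ValueError(f"unknown estimator {self.estimator!r}")


def coeff_fourier(
    model_or_coeffs: MVARModel | np.ndarray,
    freqs: Sequence[float],
    fs: float,
) -> np.ndarray:
    """Coefficient spectrum ``A̅(f) = I - Σ_r A(r) exp(-i 2π f r / fs)``.

    Returns a complex ``frequency x k x k`` tensor.
    """
    coeffs = (
        model_or_coeffs.coeffs
        if isinstance(model_or_coeffs, MVARModel)
        else np.asarray(model_or_coeffs)
    )
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError("freqs must be non-empty")
    p, k, _ = coeffs.shape
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(f, lags) / fs)  # (F, p)
    return np.eye(k) - np.einsum("fp,pij->fij", phase, coeffs)


def transfer_function(abar: np.ndarray) -> np.ndarray:
    """Transfer matrix ``H(f) = A̅(f)^{-1}`` per frequency."""
    out = np.empty_like(abar)
    for i, a in enumerate(abar):
        try:
            out[i] = np.linalg.inv(a)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"A-bar singular at frequency index {i}"
            ) from exc
    return out


def spectral_measure(
    coeffs: np.ndarray,
    resid_cov: np.ndarray,
    freqs: Sequence[float],
    fs: float,
    kind: str,
) -> np.ndarray:
    """DTF/PDC/GPDC values from a coefficient tensor, as ``(k, k, F)``.

    Shared kernel for both the data-driven estimators (fitted coefficients)
    and the simulation oracle (true coefficients).
    """
    abar = coeff_fourier(coeffs, freqs, fs)  # (F, k, k)
    if kind == "dtf":
        h2 = np.abs(transfer_function(abar)) ** 2  # (F, t, s)
        denom = h2.sum(axis=2, keepdims=True)  # inflow power per target row
        vals = h2 / denom
    elif kind == "pdc":
        a2 = np.abs(abar) ** 2
        denom = a2.sum(axis=1, keepdims=True)  # column norm per source
        vals = a2 / denom
    elif kind == "gpdc":
        sigma2 = np.diag(resid_cov)
        if np.any(sigma2 <= 0):
            raise ValueError("GPDC requires positive residual variances")
        a2 = np.abs(abar) ** 2 / sigma2[None, :, None]
        denom = a2.sum(axis=1, keepdims=True)
        vals = a2 / denom
    else:
        raise ValueError(f"unknown spectral estimator {kind!r}")
    # abar[f, t, s]: row = target, column = source -> (source, target, F).
    return vals.transpose(2, 1, 0)


def _single_window(meas: np.ndarray, estimator: str, freqs: np.ndarray) -> ConnectivityTensor:
    return ConnectivityTensor(
        estimator=estimator, values=meas[..., None], freqs=freqs, windows=None
    )


def dtf(model: MVARModel, freqs: Sequence[float] = DEFAULT_FREQS, fs: float = 250.0) -> ConnectivityTensor:
    """Directed transfer function of one fitted window."""
    f = np.asarray(freqs, dtype=float)
    return _single_window(
        spectral_measure(model.coeffs, model.resid_cov, f, fs, "dtf"), "dtf", f
    )


def pdc(model: MVARModel, freqs: Sequence[float] = DEFAULT_FREQS, fs: float = 250.0) -> ConnectivityTensor:
    """Partial directed coherence (squared-magnitude) of one fitted window."""
    f = np.asarray(freqs, dtype=float)
    return _single_window(
        spectral_measure(model.coeffs, model.resid_cov, f, fs, "pdc"), "pdc", f
    )


def gpdc(model: MVARModel, freqs: Sequence[float] = DEFAULT_FREQS, fs: float = 250.0) -> ConnectivityTensor:
    """Generalised PDC of one fitted window."""
    f = np.asarray(freqs, dtype=float)
    return _single_window(
        spectral_measure(model.coeffs, model.resid_cov, f, fs, "gpdc"), "gpdc", f
    )


def ggc_index(window_data: np.ndarray, order: int) -> np.ndarray:
    """Granger–Geweke causality index matrix of one window.

    ``entry[s, t] = max(0, ln(var_t without s / var_t full))`` for ``s != t``;
    the reduced model drops the candidate source channel and keeps all
    others, so the index is conditional on the remaining channels.  The
    diagonal is zero and finite-sample negative estimates are floored at
    zero.
    """
    x = np.asarray(window_data, dtype=float)
    k = x.shape[0]
    full = fit_mvar(x, order)
    var_full = np.diag(full.resid_cov)
    out = np.zeros((k, k))
    for s in range(k):
        keep = [c for c in range(k) if c != s]
        reduced = fit_mvar(x[keep], order)
        var_red = np.diag(reduced.resid_cov)
        for pos, t in enumerate(keep):
            out[s, t] = max(0.0, np.log(var_red[pos] / var_full[t]))
    return out


def epoch_connectivity(
    x: np.ndarray,
    estimator: str,
    order: int = 5,
    freqs: Sequence[float] = DEFAULT_FREQS,
    fs: float = 250.0,
    plan: WindowPlan | None = None,
) -> ConnectivityTensor:
    """Windowed connectivity tensor ``(k, k, F, W)`` of one epoch."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    x = np.asarray(x, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if plan is None:
        plan = plan_windows(x.shape[1], fs)
    k = x.shape[0]
    vals = np.empty((k, k, f.size, plan.n_windows))
    for w, (a, b) in enumerate(plan.windows):
        win = x[:, a:b]
        if estimator == "ggc":
            gci = ggc_index(win, order)
            vals[:, :, :, w] = gci[:, :, None]
        else:
            model = fit_mvar(win, order, window=(a, b))
            vals[:, :, :, w] = spectral_measure(
                model.coeffs, model.resid_cov, f, fs, estimator
            )
    return ConnectivityTensor(estimator=estimator, values=vals, freqs=f, windows=plan)


@dataclass
class FeatureTable:
    """Per-epoch feature matrix with provenance.

    ``values`` is ``epoch x feature``; ``columns`` documents the flattening
    (``src_tgt_fHz_wIdx`` for connectivity features).
    """

    values: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subjects: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "subject", self.subjects)
        df.insert(0, "label", self.labels)
        return df


def _feature_columns(
    names: Sequence[str], freqs: np.ndarray, n_windows: int
) -> list[str]:
    # Flattening order: source-major, then target, frequency, window.
    return [
        f"{src}_{tgt}_{f:g}Hz_w{w}"
        for src in names
        for tgt in names
        for f in freqs
        for w in range(n_windows)
    ]


def connectivity_features(
    epochs: EpochSet,
    estimator: str = "pdc",
    order: int = 5,
    freqs: Sequence[float] = DEFAULT_FREQS,
    plan: WindowPlan | None = None,
    n_windows: int | None = None,
) -> FeatureTable:
    """Flattened connectivity tensors of every epoch as a feature table.

    Every epoch must yield the same window count; when labels have unequal
    epoch lengths pass ``n_windows`` to truncate all tensors to a common
    leading window range (the classifier needs one feature space).
    """
    f = np.asarray(freqs, dtype=float)
    rows = []
    counts = set()
    for x in epochs.data:
        p = plan if plan is not None else plan_windows(x.shape[1], epochs.fs)
        tensor = epoch_connectivity(x, estimator, order, f, epochs.fs, p)
        v = tensor.values
        if n_windows is not None:
            if n_windows > v.shape[3]:
                raise ValueError("n_windows exceeds available windows")
            v = v[:, :, :, :n_windows]
        counts.add(v.shape[3])
        rows.append(v.ravel())  # C order == source, target, freq, window
    if len(counts) != 1:
        raise ValueError(
            "mixed epoch lengths give differing window counts "
            f"({sorted(counts)}); pass n_windows to align"
        )
    w = counts.pop()
    return FeatureTable(
        values=np.vstack(rows),
        columns=_feature_columns(epochs.channel_names, f, w),
        labels=epochs.labels.copy(),
        subjects=epochs.subjects.copy(),
    )


def average_connectivity(
    tensors: Sequence[ConnectivityTensor | np.ndarray],
    window_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Mean ``k x k x frequency`` map over subjects and a window range.

    ``window_range`` is a half-open window-index interval; ``None`` averages
    over all windows.
    """
    arrays = [t.values if isinstance(t, ConnectivityTensor) else np.asarray(t) for t in tensors]
    if not arrays:
        raise ValueError("no tensors to average")
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValueError("tensor dimensions differ across subjects")
    stack = np.stack(arrays)  # (subject, k, k, F, W)
    if window_range is not None:
        a, b = window_range
        if not (0 <= a < b <= shape[3]):
            raise ValueError("window_range outside tensor bounds")
        stack = stack[..., a:b]
    return stack.mean(axis=(0, 4))


class ConnectivityTransformer:
    """Scikit-learn style transformer: epoch tensor -> connectivity features.

    ``transform`` accepts an ``epoch x channel x sample`` array (or an
    :class:`EpochSet`) and returns the flattened
    ``source x target x frequency x window`` tensor per epoch as a 2-D
    feature matrix, composable with sklearn pipelines.
    """

    def __init__(
        self,
        estimator: str = "pdc",
        order: int = 5,
        fs: float = 250.0,
        freqs: Sequence[float] = DEFAULT_FREQS,
        window_ms: float = 400.0,
        step_ms: float = 50.0,
        n_windows: int | None = None,
    ):
        self.estimator = estimator
        self.order = order
        self.fs = fs
        self.freqs = freqs
        self.window_ms = window_ms
        self.step_ms = step_ms
        self.n_windows = n_windows

    def get_params(self, deep: bool = True) -> dict:
        return {
            "estimator": self.estimator,
            "order": self.order,
            "fs": self.fs,
            "freqs": self.freqs,
            "window_ms": self.window_ms,
            "step_ms": self.step_ms,
            "n_windows": self.n_windows,
        }

    def set_params(self, **params) -> "ConnectivityTransformer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "ConnectivityTransformer":
        self.n_features_in_ = None  # stateless; kept for sklearn protocol
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, EpochSet):
            table = connectivity_features(
                X,
                estimator=self.estimator,
                order=self.order,
                freqs=self.freqs,
                n_windows=self.n_windows,
            )
            return table.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected an epoch x channel x sample array")
        f = np.asarray(self.freqs, dtype=float)
        plan = plan_windows(X.shape[2], self.fs, self.window_ms, self.step_ms)
        rows = []
        for x in X:
            v = epoch_connectivity(x, self.estimator, self.order, f, self.fs, plan).values
            if self.n_windows is not None:
                v = v[:, :, :, : self.n_windows]
            rows.append(v.ravel())
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
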