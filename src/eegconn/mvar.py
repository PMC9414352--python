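"""Windowed MVAR fitting and model-order selection.

Each analysis window is modeled as a zero-mean multivariate autoregression

.. math:: X(t) = \\sum_{j=1}^{p} A(j) X(t-j) + E(t)

fit by ordinary least squares on the stacked lagged regression (the window
mean is removed first — the windowed model assumes zero-mean signals).  The
order ``p`` is chosen from SBC/BIC, AIC, Hannan-Quinn or FPE curves averaged
over windows and epochs, read either at their minimum or at their "elbow"
(the point of maximal perpendicular distance from the chord joining the
curve's endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .epochs import EpochSet
from .preprocessing import WindowPlan

__all__ = [
    "MVARModel",
    "CriteriaCurves",
    "fit_mvar",
    "information_criteria",
    "select_order",
    "CRITERIA",
]

CRITERIA = ("sbc", "aic", "hq", "fpe")


@dataclass
class MVARModel:
    """Fitted MVAR coefficients for one analysis window.

    ``coeffs`` is indexed ``lag x target x source``; ``resid_cov`` is the
    unbiased residual covariance (divisor ``n_obs - k*order``), whose
    diagonal holds the per-channel innovation variances used by GPDC and the
    Granger index.
    """

    order: int
    coeffs: np.ndarray  # (order, k, k)
    resid_cov: np.ndarray  # (k, k)
    n_obs: int
    window: tuple[int, int] | None = None

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


def _lag_matrix(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Return response Y (k x n_obs) and stacked-lag regressors Z (k*p x n_obs)."""
    k, n = x.shape
    p = order
    y = x[:, p:]
    z = np.vstack([x[:, p - j : n - j] for j in range(1, p + 1)])
    return y, z


def fit_mvar(
    window_data: np.ndarray,
    order: int,
    *,
    demean: bool = True,
    window: tuple[int, int] | None = None,
) -> MVARModel:
    """Least-squares MVAR fit of one ``channel x sample`` window.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the stacked regressor matrix is rank-deficient; the message names
        the offending window when provenance was given.
    ValueError
        If the window is too short to identify ``order`` lags.
    """
    x = np.asarray(window_data, dtype=float)
    if x.ndim != 2:
        raise ValueError("window_data must be a channel x sample matrix")
    k, n = x.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    n_obs = n - order
    if n_obs <= k * order + k - order or n_obs <= k * order:
        raise ValueError(
            f"window of {n} samples cannot identify a VAR({order}) on {k} channels"
        )
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
    y, z = _lag_matrix(x, order)
    sol, _, rank, _ = np.linalg.lstsq(z.T, y.T, rcond=None)
    if rank < k * order:
        where = f" in window {window}" if window is not None else ""
        raise np.linalg.LinAlgError(f"singular regressor matrix{where}")
    b = sol.T  # (k, k*order)
    resid = y - b @ z
    dof = n_obs - k * order
    resid_cov = (resid @ resid.T) / dof
    coeffs = b.reshape(k, order, k).transpose(1, 0, 2)
    return MVARModel(
        order=order, coeffs=coeffs, resid_cov=resid_cov, n_obs=n_obs, window=window
    )


@dataclass
class CriteriaCurves:
    """Information-criterion curves over a model-order range.

    ``values`` maps each criterion name to its mean-over-windows-and-epochs
    curve; ``per_window`` keeps the raw per-window values
    (``window_instances x orders``) for inspection.
    """

    orders: np.ndarray
    values: dict[str, np.ndarray]
    per_window: dict[str, np.ndarray]


def _criterion_values(ld: float, det: float, n: int, p: int, k: int) -> dict[str, float]:
    # ld = log det of the ML residual covariance, det = its determinant.
    pen = p * k * k / n
    return {
        "sbc": ld + np.log(n) * pen,
        "aic": ld + 2.0 * pen,
        "hq": ld + 2.0 * np.log(np.log(n)) * pen,
        "fpe": det * ((n + p * k + 1) / (n - p * k - 1)) ** k,
    }


def information_criteria(
    epochs: EpochSet,
    plan: WindowPlan | None = None,
    p_range: Sequence[int] = range(1, 31),
) -> CriteriaCurves:
    """SBC/AIC/HQ/FPE curves for every window of every epoch.

    ``plan=None`` treats each whole epoch as a single window.  Criteria use
    the maximum-likelihood residual covariance (residual cross-product over
    ``n_obs``); ``n_obs = window_samples - p`` varies with the candidate
    order.
    """
    orders = np.asarray(list(p_range), dtype=int)
    if orders.size == 0:
        raise ValueError("empty order range")
    p_max = int(orders.max())
    rows = {name: [] for name in CRITERIA}
    for x in epochs.data:
        if plan is None:
            slices = [x]
        else:
            slices = [x[:, a:b] for a, b in plan.windows]
        for w in slices:
            k, n = w.shape
            if n - p_max <= k * p_max + k - p_max:
                raise ValueError(
                    f"p_max={p_max} too large for a {n}-sample window on {k} channels"
                )
            vals = {name: np.empty(orders.size) for name in CRITERIA}
            for idx, p in enumerate(orders):
                model = fit_mvar(w, int(p))
                # Rescale to the ML covariance for the criteria.
                v_ml = model.resid_cov * (model.n_obs - k * p) / model.n_obs
                sign, ld = np.linalg.slogdet(v_ml)
                if sign <= 0:
                    raise np.linalg.LinAlgError(
                        "non-positive residual covariance determinant"
                    )
                for name, val in _criterion_values(
                    ld, float(np.exp(ld)), model.n_obs, int(p), k
                ).items():
                    vals[name][idx] = val
            for name in CRITERIA:
                rows[name].append(vals[name])
    per_window = {name: np.vstack(rows[name]) for name in CRITERIA}
    values = {name: per_window[name].mean(axis=0) for name in CRITERIA}
    for name in CRITERIA:
        if not np.all(np.isfinite(values[name])):
            raise FloatingPointError(f"non-finite {name} curve")
    return CriteriaCurves(orders=orders, values=values, per_window=per_window)


def _elbow_index(curve: np.ndarray) -> int:
    """Index of maximal perpendicular distance to the endpoint chord.

    Only interior points are candidates; on a straight curve (all distances
    zero) the smallest interior index wins.  Curves with fewer than three
    points fall back to the first index.
    """
    m = curve.size
    if m < 3:
        return 0
    xs = np.arange(m, dtype=float)
    p0 = np.array([xs[0], curve[0]])
    p1 = np.array([xs[-1], curve[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    d = np.abs(
        chord[0] * (curve - p0[1]) - chord[1] * (xs - p0[0])
    ) / norm
    interior = d[1:-1]
    return 1 + int(np.argmax(interior))  # argmax takes the first (smallest p) tie


def select_order(
    curves: CriteriaCurves, criterion: str = "sbc", method: str = "elbow"
) -> int:
    """Pick the model order from a criterion's mean curve.

    ``method='min'`` returns the argmin (smallest order on ties);
    ``method='elbow'`` returns the interior point of maximal perpendicular
    distance from the chord joining the curve's first and last points.
    """
    if criterion not in curves.values:
        raise ValueError(f"unknown criterion {criterion!r}")
    curve = np.asarray(curves.values[criterion], dtype=float)
    if curve.size == 0:
        raise ValueError("empty criterion curve")
    if method == "min":
        return int(curves.orders[int(np.argmin(curve))])
    if method == "elbow":
        return int(curves.orders[_elbow_index(curve)])
    raise ValueError(f"unknown method {method!r}")
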