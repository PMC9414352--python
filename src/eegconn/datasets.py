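"""Ground-truth MVAR systems and synthetic condition-labeled epoch sets.

The study's real recordings are third-party data, so validation of the
connectivity pipeline rests on simulated stationary multivariate
autoregressive (MVAR) systems with *known* directed coupling graphs:

.. math:: X(t) = \\sum_{j=1}^{p} A(j)\\,X(t-j) + E(t)

with multivariate Gaussian innovations :math:`E(t)`.  The generator exposes
the true coefficient tensor, so closed-form spectral connectivity (DTF, PDC,
GPDC) evaluated on the true coefficients serves as an oracle for the
estimates recovered from simulated data.

The default two-condition fixture mirrors the study geometry: six
components at 250 Hz, 1200 ms epochs for the non-distracted condition and
1600 ms for the distracted one, with the distracted system carrying a denser
directed-coupling graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .epochs import CONDITIONS, DEFAULT_CHANNELS, EpochSet

__all__ = [
    "GroundTruthSystem",
    "make_var_system",
    "simulate_epochs",
    "true_spectral_connectivity",
    "default_condition_systems",
    "make_condition_dataset",
]


@dataclass
class GroundTruthSystem:
    """A stable MVAR(p) generator with an explicit directed-coupling graph.

    ``coeffs`` is indexed ``lag x target x source`` so that
    ``coeffs[j-1] @ x(t-j)`` is lag ``j``'s contribution.  ``edges`` holds
    every ordered ``(source, target)`` channel pair (0-based) with a nonzero
    off-diagonal coefficient at any lag.
    """

    n_channels: int
    order: int
    coeffs: np.ndarray  # (order, k, k)
    noise_cov: np.ndarray  # (k, k)
    edges: frozenset = field(default_factory=frozenset)
    fs: float = 250.0
    shrink_factor: float = 1.0  # applied stabilisation shrinkage (1 = none)

    def companion(self) -> np.ndarray:
        """Companion matrix of the VAR(p) process (stacked VAR(1) form)."""
        k, p = self.n_channels, self.order
        top = np.hstack([self.coeffs[j] for j in range(p)])
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = top
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def validate(self) -> None:
        k, p = self.n_channels, self.order
        if self.coeffs.shape != (p, k, k):
            raise ValueError("coeffs must have shape (order, k, k)")
        if self.spectral_radius() >= 1.0:
            raise ValueError("system is not stationary (companion radius >= 1)")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise covariance must be positive definite")
        implied = frozenset(
            (s, t)
            for j in range(p)
            for t in range(k)
            for s in range(k)
            if s != t and self.coeffs[j, t, s] != 0.0
        )
        if implied != self.edges:
            raise ValueError("edges set inconsistent with nonzero coefficients")


def make_var_system(
    n_channels: int = 6,
    order: int = 5,
    edges: Sequence[tuple] = (),
    diag_strength: float = 0.5,
    noise_scale: float = 1.0,
    seed: int | None = None,
    *,
    fs: float = 250.0,
    diag_profile: Sequence[float] | None = None,
    noise_cov: np.ndarray | None = None,
) -> GroundTruthSystem:
    """Build a stable MVAR system from a directed edge list.

    Parameters
    ----------
    edges
        Directed couplings as ``(source, target, strength)`` or
        ``(source, target, strength, lag)`` tuples (channels 0-based,
        lags 1-based, default lag 1).  Self-loops are rejected; the channel's
        own dynamics come from ``diag_strength`` / ``diag_profile``.
    diag_strength
        Lag-1 self-coefficient shared by every channel (ignored when
        ``diag_profile`` is given).
    diag_profile
        Per-lag self-coefficients (length <= ``order``); lets the generator
        place genuine high-lag dynamics, e.g. for order-selection studies.
    noise_scale
        Innovation standard deviation; ``noise_cov`` defaults to
        ``noise_scale**2 * I``.
    seed
        Accepted for signature symmetry with the stochastic generators; the
        construction itself is deterministic.

    If the requested coefficients give a companion spectral radius >= 1 they
    are uniformly shrunk (all lags, same factor) until stable; the applied
    factor is reported as ``shrink_factor``.
    """
    del seed  # deterministic construction
    if n_channels < 2:
        raise ValueError("need at least two channels")
    if order < 1:
        raise ValueError("order must be >= 1")
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")

    k = n_channels
    coeffs = np.zeros((order, k, k))
    if diag_profile is not None:
        if len(diag_profile) > order:
            raise ValueError("diag_profile longer than the model order")
        for j, a in enumerate(diag_profile):
            coeffs[j] += float(a) * np.eye(k)
    else:
        coeffs[0] += float(diag_strength) * np.eye(k)

    edge_set = set()
    for e in edges:
        if len(e) == 3:
            s, t, w = e
            lag = 1
        elif len(e) == 4:
            s, t, w, lag = e
        else:
            raise ValueError("edges are (source, target, strength[, lag]) tuples")
        s, t, lag = int(s), int(t), int(lag)
        if s == t:
            raise ValueError("self-loops are not allowed in edges")
        if not (0 <= s < k and 0 <= t < k):
            raise ValueError(f"edge ({s}, {t}) outside channel range")
        if not (1 <= lag <= order):
            raise ValueError(f"edge lag {lag} outside 1..{order}")
        coeffs[lag - 1, t, s] += float(w)
        edge_set.add((s, t))

    if noise_cov is None:
        noise_cov = noise_scale**2 * np.eye(k)
    noise_cov = np.asarray(noise_cov, dtype=float)

    system = GroundTruthSystem(
        n_channels=k,
        order=order,
        coeffs=coeffs,
        noise_cov=noise_cov,
        edges=frozenset(edge_set),
        fs=float(fs),
    )
    # Uniform shrinkage until comfortably inside the unit circle.
    factor = 1.0
    if system.spectral_radius() >= 1.0:
        while system.spectral_radius() > 0.98:
            system.coeffs *= 0.95
            factor *= 0.95
        system.shrink_factor = factor
    system.validate()
    return system


def simulate_epochs(
    system: GroundTruthSystem,
    n_epochs: int,
    epoch_ms: float,
    label: str,
    burn_in: int = 500,
    seed: int | None = None,
    subject: str = "s00",
) -> EpochSet:
    """Draw independent epochs by iterating the MVAR recursion.

    Each epoch starts from a zero state, runs ``burn_in`` discarded samples
    to wash out the transient (default 500, far beyond the default order's
    memory), then records ``epoch_ms`` worth of samples at ``system.fs``.
    Identical seeds give bit-identical output.
    """
    if label not in CONDITIONS:
        raise ValueError(f"label must be one of {CONDITIONS}")
    n_samples_f = epoch_ms * system.fs / 1000.0
    n_samples = int(round(n_samples_f))
    if abs(n_samples_f - n_samples) > 1e-9:
        raise ValueError("epoch_ms * fs / 1000 must be an integer sample count")
    if n_samples < system.order + 1:
        raise ValueError("epoch shorter than order + 1 samples")

    k, p = system.n_channels, system.order
    rng = np.random.default_rng(seed)
    # PSD-safe innovation square root (allows the zero-noise limit).
    w, v = np.linalg.eigh(system.noise_cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    total = burn_in + n_samples
    data = []
    for _ in range(n_epochs):
        innov = root @ rng.standard_normal((k, total))
        x = np.zeros((k, total + p))
        for t in range(total):
            acc = innov[:, t].copy()
            for j in range(p):
                acc += system.coeffs[j] @ x[:, p + t - 1 - j]
            x[:, p + t] = acc
        data.append(x[:, p + burn_in :])

    names = (
        DEFAULT_CHANNELS
        if k == len(DEFAULT_CHANNELS)
        else tuple(f"ch{i}" for i in range(k))
    )
    return EpochSet(
        data=data,
        fs=system.fs,
        labels=np.asarray([label] * n_epochs, dtype=object),
        subjects=np.asarray([subject] * n_epochs, dtype=object),
        channel_names=names,
    )


def true_spectral_connectivity(
    system: GroundTruthSystem,
    freqs: Sequence[float],
    estimator: str,
):
    """Closed-form DTF/PDC/GPDC evaluated on the TRUE coefficients.

    This is the simulation oracle: it never touches data, only the system's
    coefficient tensor and innovation covariance.  Returns a single-window
    :class:`~eegconn.connectivity.ConnectivityTensor`.
    """
    from .connectivity import ConnectivityTensor, spectral_measure

    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    if np.any(freqs <= 0) or np.any(freqs >= system.fs / 2):
        raise ValueError("freqs must lie strictly inside (0, fs/2)")
    if estimator not in ("dtf", "pdc", "gpdc"):
        raise ValueError(f"unknown estimator {estimator!r}")
    vals = spectral_measure(
        system.coeffs, system.noise_cov, freqs, system.fs, estimator
    )
    return ConnectivityTensor(
        estimator=estimator, values=vals[..., None], freqs=freqs, windows=None
    )


# ---------------------------------------------------------------------------
# Default two-condition contrast fixture
# ---------------------------------------------------------------------------

def stationary_covariance(system: GroundTruthSystem) -> np.ndarray:
    """Closed-form stationary covariance of the MVAR process.

    Solves the discrete Lyapunov equation of the companion (stacked VAR(1))
    form and returns its leading ``k x k`` block.
    """
    from scipy.linalg import solve_discrete_lyapunov

    k, p = system.n_channels, system.order
    q = np.zeros((k * p, k * p))
    q[:k, :k] = system.noise_cov
    s = solve_discrete_lyapunov(system.companion(), q)
    return s[:k, :k]


def _match_channel_power(
    system: GroundTruthSystem, target_var: np.ndarray, n_iter: int = 30
) -> GroundTruthSystem:
    """Rescale per-channel innovation variances so the process's stationary
    per-channel variances hit ``target_var`` (fixed-point iteration on the
    diagonal of the Lyapunov solution)."""
    q = np.diag(system.noise_cov).astype(float).copy()
    for _ in range(n_iter):
        system = GroundTruthSystem(
            n_channels=system.n_channels,
            order=system.order,
            coeffs=system.coeffs,
            noise_cov=np.diag(q),
            edges=system.edges,
            fs=system.fs,
            shrink_factor=system.shrink_factor,
        )
        var = np.diag(stationary_covariance(system))
        q *= target_var / var
    system.validate()
    return system


#: Damped-oscillation self-dynamics shared by both condition systems.
_DIAG_PROFILE = (0.55, -0.25, 0.15, -0.10, 0.05)

#: Non-distracted graph: a directed ring over the six components.
NONDISTRACTED_EDGES = tuple(
    (i, (i + 1) % 6, 0.35) for i in range(6)
)

#: Distracted graph: the ring reversed, plus two extra chords (denser).
#: Reversing the ring flips every directed influence while leaving each
#: channel's marginal dynamics unchanged by symmetry, so the condition
#: contrast is carried by coupling direction and density rather than by
#: per-channel power.
DISTRACTED_EDGES = tuple(
    ((i + 1) % 6, i, 0.35) for i in range(6)
) + (
    (1, 4, 0.25),  # central -> left motor chord
    (2, 5, 0.25),  # parietal -> right motor chord
)


def default_condition_systems(
    coupling_scale: float = 1.0, noise_scale: float = 1.0
) -> tuple[GroundTruthSystem, GroundTruthSystem]:
    """The two ground-truth systems behind the default contrast fixture.

    Both share six channels, order 5 and the same self-dynamics.  The
    non-distracted graph is a directed ring; the distracted graph is the
    ring reversed plus two extra chords, so it is denser (emulating the
    qualitative finding that brain networks densify under distraction)
    and, crucially, differs mainly in coupling *direction*.  The distracted
    system's innovation variances are additionally rescaled so both
    conditions share identical stationary per-channel power: the contrast
    is carried by directed structure, which is what connectivity
    estimators measure and raw spectra cannot see.
    """
    scale = lambda edges: [(s, t, w * coupling_scale) for s, t, w in edges]
    ring = make_var_system(
        n_channels=6,
        order=5,
        edges=scale(NONDISTRACTED_EDGES),
        diag_profile=_DIAG_PROFILE,
        noise_scale=noise_scale,
    )
    dense = make_var_system(
        n_channels=6,
        order=5,
        edges=scale(DISTRACTED_EDGES),
        diag_profile=_DIAG_PROFILE,
        noise_scale=noise_scale,
    )
    dense = _match_channel_power(
        dense, np.diag(stationary_covariance(ring))
    )
    return ring, dense


def make_condition_dataset(
    n_subjects: int = 4,
    epochs_per_class: int = 5,
    seed: int | None = None,
    coupling_scale: float = 1.0,
    noise_scale: float = 1.0,
    nondistracted_ms: float = 1200.0,
    distracted_ms: float = 1600.0,
) -> EpochSet:
    """Two-condition epoch set with the study geometry.

    ``epochs_per_class`` epochs per subject per condition: non-distracted
    epochs of 1200 ms drawn from the sparse system, distracted epochs of
    1600 ms from the dense one, all at 250 Hz.  Subjects share the systems
    but have independent noise realisations.
    """
    sparse, dense = default_condition_systems(coupling_scale, noise_scale)
    rng = np.random.default_rng(seed)
    parts = []
    for s in range(n_subjects):
        sid = f"s{s:02d}"
        parts.append(
            simulate_epochs(
                sparse,
                epochs_per_class,
                nondistracted_ms,
                "non_distracted",
                seed=int(rng.integers(2**31)),
                subject=sid,
            )
        )
        parts.append(
            simulate_epochs(
                dense,
                epochs_per_class,
                distracted_ms,
                "distracted",
                seed=int(rng.integers(2**31)),
                subject=sid,
            )
        )
    return EpochSet.concat(parts)
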