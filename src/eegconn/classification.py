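"""RBF-SVM condition classification with sequential model-based tuning.

The classifier is a Gaussian-kernel SVM, ``K(x1, x2) =
exp(-||x1 - x2||² / (2σ²))``, trained on standardized features.  Its two
hyperparameters — the box constraint C and the kernel scale σ — are tuned
by Bayesian optimisation (Gaussian-process surrogate, expected-improvement
acquisition) of the stratified five-fold cross-validation loss, with a
fixed budget of objective evaluations over log-uniform ranges
``[1e-3, 1e3]²``.  Splitting into train/test halves is stratified within
each (subject, condition) cell, and all standardisation statistics and
hyperparameters depend on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassificationResult",
    "split_train_test",
    "BayesTunedRBFSVM",
    "train_svm_rbf",
    "evaluate",
    "window_scan",
]


@dataclass
class ClassificationResult:
    """Outcome of one train/evaluate run."""

    accuracy: float
    box_constraint: float
    kernel_scale: float
    cv_loss: float
    confusion: np.ndarray  # 2x2 counts, rows = true, cols = predicted
    n_train: int
    n_test: int
    seed: int | None = None


def split_train_test(
    labels: Sequence,
    subjects: Sequence,
    ratio: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified epoch split within each (subject, label) cell.

    Each cell contributes ``ceil(n * ratio)`` epochs to training (odd counts
    favour training), drawn at random by ``seed``; the pooled training rows
    are then shuffled so subjects are mixed in order.  Returns
    ``(train_idx, test_idx)`` into the epoch axis.
    """
    labels = np.asarray(labels, dtype=object)
    subjects = np.asarray(subjects, dtype=object)
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    strata = sorted({(s, l) for s, l in zip(subjects, labels)})
    for s, l in strata:
        idx = np.flatnonzero((subjects == s) & (labels == l))
        if idx.size < 2:
            raise ValueError(f"stratum (subject={s!r}, label={l!r}) too small")
        perm = rng.permutation(idx)
        n_tr = int(np.ceil(idx.size * ratio))
        train.extend(perm[:n_tr])
        test.extend(perm[n_tr:])
    train = np.asarray(train, dtype=int)
    test = np.asarray(test, dtype=int)
    rng.shuffle(train)
    return train, np.sort(test)


def _expected_improvement(mu, sigma, best):
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


class BayesTunedRBFSVM:
    """RBF SVM with GP-EI hyperparameter search, sklearn estimator protocol.

    Parameters
    ----------
    n_evals
        Total objective evaluations (default 30): ``n_init`` space-filling
        draws followed by expected-improvement picks.
    cv_folds
        Stratified CV folds for the loss (default 5; silently reduced when
        a class has fewer members than folds).
    c_bounds, sigma_bounds
        Log-uniform search ranges for the box constraint and kernel scale.

    Fitted attributes: ``best_box_constraint_``, ``best_kernel_scale_``,
    ``cv_loss_``, ``pipeline_`` (scaler + SVC refit on all training data),
    ``classes_``, ``eval_history_``.
    """

    def __init__(
        self,
        n_evals: int = 30,
        cv_folds: int = 5,
        c_bounds: tuple[float, float] = (1e-3, 1e3),
        sigma_bounds: tuple[float, float] = (1e-3, 1e3),
        n_init: int = 8,
        random_state: int | None = None,
    ):
        self.n_evals = n_evals
        self.cv_folds = cv_folds
        self.c_bounds = c_bounds
        self.sigma_bounds = sigma_bounds
        self.n_init = n_init
        self.random_state = random_state

    # -- sklearn protocol -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_evals": self.n_evals,
            "cv_folds": self.cv_folds,
            "c_bounds": self.c_bounds,
            "sigma_bounds": self.sigma_bounds,
            "n_init": self.n_init,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "BayesTunedRBFSVM":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- internals --------------------------------------------------------
    def _make_pipeline(self, c: float, sigma: float) -> Pipeline:
        gamma = 1.0 / (2.0 * sigma**2)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(C=c, kernel="rbf", gamma=gamma)),
            ]
        )

    def _cv_loss(self, X, y, c, sigma, folds, rs) -> float:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        scores = cross_val_score(self._make_pipeline(c, sigma), X, y, cv=cv)
        return 1.0 - float(scores.mean())

    def fit(self, X, y) -> "BayesTunedRBFSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise ValueError("training set contains a single class")
        folds = int(min(self.cv_folds, counts.min()))
        if folds < 2:
            raise ValueError("too few epochs per class for cross-validation")
        rng = np.random.default_rng(self.random_state)
        rs = int(rng.integers(2**31))  # fixed fold assignment across evals

        lo = np.log10([self.c_bounds[0], self.sigma_bounds[0]])
        hi = np.log10([self.c_bounds[1], self.sigma_bounds[1]])
        n_evals = int(self.n_evals)
        n_init = int(min(self.n_init, n_evals))

        pts: list[np.ndarray] = []
        losses: list[float] = []

        def objective(z: np.ndarray) -> float:
            c, sigma = 10.0 ** z
            loss = self._cv_loss(X, y, c, sigma, folds, rs)
            pts.append(z)
            losses.append(loss)
            return loss

        for _ in range(n_init):
            objective(rng.uniform(lo, hi))

        kernel = ConstantKernel(1.0) * Matern(length_scale=[1.0, 1.0], nu=2.5)
        for _ in range(n_evals - n_init):
            gp = GaussianProcessRegressor(
                kernel=kernel,
                alpha=1e-6,
                normalize_y=True,
                n_restarts_optimizer=1,
                random_state=rs,
            )
            import warnings

            from sklearn.exceptions import ConvergenceWarning

            with warnings.catch_warnings():
                # Flat CV-loss surfaces push the surrogate's length scale to
                # its bound; harmless for an acquisition-only model.
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.vstack(pts), np.asarray(losses))
            cand = rng.uniform(lo, hi, size=(256, 2))
            mu, sd = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sd, min(losses))
            objective(cand[int(np.argmax(ei))])

        best = int(np.argmin(losses))
        self.best_box_constraint_, self.best_kernel_scale_ = 10.0 ** pts[best]
        self.cv_loss_ = float(losses[best])
        self.eval_history_ = (np.vstack(pts), np.asarray(losses))
        self.pipeline_ = self._make_pipeline(
            self.best_box_constraint_, self.best_kernel_scale_
        )
        self.pipeline_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_svm_rbf(
    X_train: np.ndarray,
    y_train: Sequence,
    n_evals: int = 30,
    cv_folds: int = 5,
    seed: int | None = None,
) -> tuple[BayesTunedRBFSVM, ClassificationResult]:
    """Tune and fit the RBF SVM; the result carries the train-side metrics."""
    model = BayesTunedRBFSVM(n_evals=n_evals, cv_folds=cv_folds, random_state=seed)
    model.fit(X_train, y_train)
    y_hat = model.predict(X_train)
    cm = confusion_matrix(y_train, y_hat, labels=model.classes_)
    result = ClassificationResult(
        accuracy=float(np.mean(y_hat == np.asarray(y_train))),
        box_constraint=model.best_box_constraint_,
        kernel_scale=model.best_kernel_scale_,
        cv_loss=model.cv_loss_,
        confusion=cm,
        n_train=len(y_train),
        n_test=0,
        seed=seed,
    )
    return model, result


def evaluate(
    model: BayesTunedRBFSVM, X_test: np.ndarray, y_test: Sequence
) -> ClassificationResult:
    """Held-out accuracy and confusion counts.

    Test features are standardized inside the model's pipeline with the
    statistics learned on training rows.
    """
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension {X_test.shape[1]} != fitted {model.n_features_in_}"
        )
    y_hat = model.predict(X_test)
    cm = confusion_matrix(y_test, y_hat, labels=model.classes_)
    return ClassificationResult(
        accuracy=float(np.mean(y_hat == np.asarray(y_test))),
        box_constraint=model.best_box_constraint_,
        kernel_scale=model.best_kernel_scale_,
        cv_loss=model.cv_loss_,
        confusion=cm,
        n_train=0,
        n_test=len(y_test),
        seed=model.random_state,
    )


def window_scan(
    tensors: np.ndarray,
    labels: Sequence,
    subjects: Sequence,
    ratio: float = 0.5,
    n_evals: int = 30,
    cv_folds: int = 5,
    seed: int | None = None,
) -> list[ClassificationResult]:
    """Per-window classification accuracy scan.

    ``tensors`` is ``epoch x source x target x frequency x window`` (already
    aligned to the window indices shared by both conditions).  One split is
    drawn from ``seed`` and reused for every window; each window's
    ``source x target x frequency`` block is classified independently.
    """
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim != 5:
        raise ValueError("tensors must be epoch x src x tgt x freq x window")
    labels = np.asarray(labels, dtype=object)
    n_windows = tensors.shape[4]
    if n_windows < 1:
        raise ValueError("no common window index across conditions")
    train_idx, test_idx = split_train_test(labels, subjects, ratio, seed)
    results = []
    for w in range(n_windows):
        X = tensors[:, :, :, :, w].reshape(tensors.shape[0], -1)
        model, _ = train_svm_rbf(
            X[train_idx], labels[train_idx], n_evals, cv_folds, seed
        )
        res = evaluate(model, X[test_idx], labels[test_idx])
        res.n_train = train_idx.size
        res.seed = seed
        results.append(res)
    return results
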