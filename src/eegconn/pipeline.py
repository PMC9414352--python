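"""End-to-end experiment helpers: simulate, featurize, classify.

Convenience layer tying the modules together the way the study's analysis
ran: build a two-condition epoch set, extract either connectivity-tensor or
periodogram features, split 50:50 within each (subject, condition) cell,
tune the RBF SVM on the training half and report held-out accuracy.
"""

from __future__ import annotations

import numpy as np

from .classification import (
    ClassificationResult,
    evaluate,
    split_train_test,
    train_svm_rbf,
)
from .connectivity import DEFAULT_FREQS, connectivity_features
from .datasets import make_condition_dataset
from .epochs import EpochSet
from .preprocessing import plan_windows
from .psd import psd_features

__all__ = ["extract_features", "classify_conditions", "contrast_experiment"]


def extract_features(
    epochs: EpochSet,
    feature: str = "pdc",
    order: int = 5,
    freqs=DEFAULT_FREQS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix + labels + subjects for one feature family.

    ``feature`` is one of the connectivity estimators (``ggc``, ``dtf``,
    ``pdc``, ``gpdc``) or ``psd``.  Connectivity tensors are truncated to
    the window count shared by both conditions so epochs of different
    durations map into one feature space.
    """
    if feature == "psd":
        table = psd_features(epochs)
        return table.values, table.labels, table.subjects
    n_common = min(
        plan_windows(x.shape[1], epochs.fs).n_windows for x in epochs.data
    )
    table = connectivity_features(
        epochs, estimator=feature, order=order, freqs=freqs, n_windows=n_common
    )
    return table.values, table.labels, table.subjects


def classify_conditions(
    epochs: EpochSet,
    feature: str = "pdc",
    order: int = 5,
    ratio: float = 0.5,
    n_evals: int = 30,
    cv_folds: int = 5,
    seed: int | None = None,
    shuffle_labels: bool = False,
) -> ClassificationResult:
    """Full split/tune/evaluate run on one feature family.

    ``shuffle_labels=True`` permutes the condition labels before splitting —
    the chance-level control.
    """
    X, labels, subjects = extract_features(epochs, feature, order)
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        labels = labels[rng.permutation(len(labels))]
    train_idx, test_idx = split_train_test(labels, subjects, ratio, seed)
    model, _ = train_svm_rbf(X[train_idx], labels[train_idx], n_evals, cv_folds, seed)
    result = evaluate(model, X[test_idx], labels[test_idx])
    result.n_train = train_idx.size
    result.seed = seed
    return result


def contrast_experiment(
    feature: str = "pdc",
    n_subjects: int = 4,
    epochs_per_class: int = 5,
    seed: int | None = None,
    n_evals: int = 30,
    coupling_scale: float = 1.0,
    shuffle_labels: bool = False,
) -> ClassificationResult:
    """Simulate the default contrast fixture and classify it end to end."""
    epochs = make_condition_dataset(
        n_subjects=n_subjects,
        epochs_per_class=epochs_per_class,
        seed=seed,
        coupling_scale=coupling_scale,
    )
    return classify_conditions(
        epochs, feature=feature, n_evals=n_evals, seed=seed,
        shuffle_labels=shuffle_labels,
    )
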