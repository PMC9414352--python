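"""Labeled multichannel epoch container and its on-disk format.

An :class:`EpochSet` is the pipeline's universal currency: a collection of
fixed-rate multichannel epochs, each tagged with a condition label and a
subject identifier.  Because the two experimental conditions use different
epoch durations (1200 ms for non-distracted, 1600 ms for distracted driving
at 250 Hz), epochs are stored as a list of ``(n_channels, n_samples)``
arrays; :meth:`EpochSet.stack` returns the per-label 3-D tensor view
``epoch x channel x sample``.

On disk an epoch set is a directory with a JSON manifest (sampling rate,
channel names, labels, subjects, epoch file list) and one delimited text
matrix per epoch (rows = samples, columns = channels, header = channel
names).  Values are written with 17 significant digits so float64 data
round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Canonical component names, in tensor order.
DEFAULT_CHANNELS = (
    "frontal",
    "central",
    "parietal",
    "occipital",
    "left_motor",
    "right_motor",
)

#: The two-condition label vocabulary.
CONDITIONS = ("non_distracted", "distracted")

_MANIFEST = "manifest.json"


@dataclass
class EpochSet:
    """Collection of condition-labeled multichannel epochs at one sampling rate.

    Parameters
    ----------
    data
        List of ``(n_channels, n_samples)`` float arrays, one per epoch.
        Epochs sharing a label must share a sample count; lengths may differ
        across labels.
    fs
        Sampling rate in Hz.
    labels
        Per-epoch condition tag, drawn from :data:`CONDITIONS`.
    subjects
        Per-epoch subject identifier.
    channel_names
        Ordered component names; length must equal the channel dimension.
    """

    data: list[np.ndarray]
    fs: float
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.data = [np.asarray(x, dtype=float) for x in self.data]
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.channel_names = tuple(self.channel_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.data)
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects length must match epoch count")
        k = len(self.channel_names)
        lengths: dict[str, int] = {}
        for i, x in enumerate(self.data):
            if x.ndim != 2 or x.shape[0] != k:
                raise ValueError(
                    f"epoch {i} has shape {x.shape}; expected ({k}, n_samples)"
                )
            if not np.all(np.isfinite(x)):
                raise ValueError(f"epoch {i} contains non-finite samples")
            lab = self.labels[i]
            if lab not in CONDITIONS:
                raise ValueError(f"unknown condition label {lab!r}")
            if lab in lengths and lengths[lab] != x.shape[1]:
                raise ValueError(
                    f"epochs labeled {lab!r} have inconsistent sample counts"
                )
            lengths[lab] = x.shape[1]

    # -- basic accessors --------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def epoch_samples(self, label: str) -> int:
        """Sample count shared by all epochs of ``label``."""
        for x, lab in zip(self.data, self.labels):
            if lab == label:
                return x.shape[1]
        raise KeyError(f"no epochs labeled {label!r}")

    def stack(self, label: str | None = None) -> np.ndarray:
        """Return the ``epoch x channel x sample`` tensor.

        Restricting to one ``label`` is required when the labels have
        different epoch lengths.
        """
        if label is None:
            sel = self.data
        else:
            sel = [x for x, lab in zip(self.data, self.labels) if lab == label]
        if not sel:
            raise KeyError(f"no epochs labeled {label!r}")
        return np.stack(sel)

    def select(self, indices: Iterable[int]) -> "EpochSet":
        idx = list(indices)
        return EpochSet(
            data=[self.data[i] for i in idx],
            fs=self.fs,
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            channel_names=self.channel_names,
        )

    @classmethod
    def concat(cls, parts: Sequence["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.fs != first.fs or p.channel_names != first.channel_names:
                raise ValueError("epoch sets differ in fs or channel names")
        return cls(
            data=[x for p in parts for x in p.data],
            fs=first.fs,
            labels=np.concatenate([p.labels for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            channel_names=first.channel_names,
        )

    # -- on-disk container ------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write the manifest + per-epoch delimited text matrices."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = []
        header = "\t".join(self.channel_names)
        for i, x in enumerate(self.data):
            name = f"epoch_{i:05d}.tsv"
            np.savetxt(
                directory / name,
                x.T,  # rows = samples, columns = channels
                fmt="%.17g",
                delimiter="\t",
                header=header,
                comments="",
            )
            files.append(name)
        manifest = {
            "fs": self.fs,
            "channel_names": list(self.channel_names),
            "labels": list(self.labels),
            "subjects": list(self.subjects),
            "epochs": files,
            "sample_indexing": "0-based; analysis windows are half-open [start, end)",
        }
        with open(directory / _MANIFEST, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        with open(directory / _MANIFEST) as fh:
            manifest = json.load(fh)
        data = [
            np.loadtxt(directory / name, delimiter="\t", skiprows=1, ndmin=2).T
            for name in manifest["epochs"]
        ]
        return cls(
            data=data,
            fs=manifest["fs"],
            labels=np.asarray(manifest["labels"], dtype=object),
            subjects=np.asarray(manifest["subjects"], dtype=object),
            channel_names=tuple(manifest["channel_names"]),
        )


def read_edf(
    path: str | Path,
    label: str,
    subject: str = "s00",
    channels: Sequence[str] | None = None,
) -> EpochSet:
    """Read a raw multichannel EDF recording as a single-epoch :class:`EpochSet`.

    Intended for feeding continuous recordings into the filtering/resampling
    stage; epoching of event-locked segments is left to the caller.  Requires
    the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    return EpochSet(
        data=[raw.get_data()],
        fs=float(raw.info["sfreq"]),
        labels=np.asarray([label], dtype=object),
        subjects=np.asarray([subject], dtype=object),
        channel_names=tuple(raw.ch_names),
    )
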