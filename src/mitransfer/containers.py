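"""In-memory containers shared across the pipeline.

The package operates on two levels of data: continuous multi-channel
recordings (:class:`RawRecording`) and epoched, labeled trial tensors
(:class:`EpochSet`).  An :class:`EpochSet` is the common currency between
preprocessing, feature extraction and classification.  Labels follow the
motor-imagery convention ``1`` = left hand, ``2`` = right hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_LABELS = (1, 2)


@dataclass
class RawRecording:
    """A continuous EEG recording with cue events.

    Parameters
    ----------
    data
        Signal matrix, shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One name per channel (e.g. ``"C3"``).
    channel_kinds
        One of ``"EEG"`` / ``"EOG"`` per channel.
    events
        ``(cue_sample_index, class_label)`` pairs, sorted by sample index.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_kinds: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_kinds) != n_ch:
            raise ValueError(
                "channel_labels/channel_kinds length must match channel count"
            )
        bad = set(self.channel_kinds) - {"EEG", "EOG"}
        if bad:
            raise ValueError(f"unknown channel kinds: {sorted(bad)}")
        samples = [int(s) for s, _ in self.events]
        if samples != sorted(samples):
            raise ValueError("events must be sorted by sample index")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Labeled trial tensor: ``(n_trials, n_channels, n_samples)``.

    ``window`` records the epoch extent in seconds relative to the cue, so
    downstream code can tell an already-windowed set from raw slices.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must match trial count")
        if self.labels.size and not np.isin(self.labels, VALID_LABELS).all():
            raise ValueError(
                f"labels must take values in {VALID_LABELS}, "
                f"got {sorted(set(self.labels.tolist()))}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, index: Sequence[int] | np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            self.data[index], self.labels[index], self.fs,
            list(self.channel_labels), self.window,
        )


def concatenate_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack trial sets that share montage, sampling rate and window."""
    if not sets:
        raise ValueError("need at least one EpochSet")
    first = sets[0]
    for es in sets[1:]:
        if es.fs != first.fs:
            raise ValueError("sampling rates differ")
        if es.n_channels != first.n_channels or es.n_samples != first.n_samples:
            raise ValueError("epoch shapes differ")
    return EpochSet(
        np.concatenate([es.data for es in sets], axis=0),
        np.concatenate([es.labels for es in sets], axis=0),
        first.fs,
        list(first.channel_labels),
        first.window,
    )
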