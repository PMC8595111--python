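"""Core in-memory containers shared across the pipeline.

All voltages are microvolts (µV); epoch-relative times are milliseconds with
0 at stimulus onset; file-level event onsets are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Channel labels of the 3 x 3 epidural grid, row-major from frontal to
#: posterior: frontal/mid/posterior x centre/left/right.
CHANNELS = ("FC", "FL", "FR", "MC", "ML", "MR", "PC", "PL", "PR")

STANDARD = "standard"
DEVIANT = "deviant"


class ConstraintError(ValueError):
    """A requested configuration violates a structural constraint."""


@dataclass(frozen=True)
class StimulusSequence:
    """An oddball stimulus train: labels plus strictly increasing onsets.

    Invariants: no two consecutive deviants; onsets spaced by ``isi_s``.
    """

    labels: tuple[str, ...]
    onsets_s: np.ndarray
    isi_s: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        object.__setattr__(self, "onsets_s", onsets)
        if len(self.labels) != onsets.size:
            raise ConstraintError("labels and onsets differ in length")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ConstraintError("onsets must be strictly increasing")
        for a, b in zip(self.labels, self.labels[1:]):
            if a == DEVIANT and b == DEVIANT:
                raise ConstraintError("two successive deviants are not allowed")

    @property
    def n_standard(self) -> int:
        return sum(1 for l in self.labels if l == STANDARD)

    @property
    def n_deviant(self) -> int:
        return sum(1 for l in self.labels if l == DEVIANT)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ContinuousRecording:
    """Multichannel continuous µV signal with stimulus events."""

    channels: tuple[str, ...]
    fs_hz: float
    data: np.ndarray  # (n_channels, n_samples), µV
    events: StimulusSequence
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels={len(self.channels)}, n_samples), "
                f"got {self.data.shape}"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        duration = self.data.shape[1] / self.fs_hz
        if self.events.onsets_s.size and self.events.onsets_s[-1] > duration:
            raise ValueError("events extend beyond the record duration")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_hz


@dataclass
class EpochSet:
    """Stimulus-locked trials: (n_trials, n_channels, n_samples) in µV.

    ``retained`` is a per-(trial, channel) boolean mask; artifact rejection
    clears entries rather than dropping rows so that trial bookkeeping stays
    aligned with the stimulus sequence.
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs_hz: float
    trial_class: np.ndarray  # per-trial 'standard' | 'deviant'
    channels: tuple[str, ...]
    retained: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.trial_class = np.asarray(self.trial_class)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if self.time_ms.size != n_samp:
            raise ValueError("time axis does not match sample axis")
        if self.trial_class.size != n_trials:
            raise ValueError("trial_class does not match trial axis")
        if self.retained is None:
            self.retained = np.ones((n_trials, n_ch), dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if self.retained.shape != (n_trials, n_ch):
                raise ValueError("retained mask must be (n_trials, n_channels)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label) if isinstance(self.channels, list) \
                else list(self.channels).index(label)
        except ValueError as exc:
            raise KeyError(f"unknown channel {label!r}") from exc

    def class_mask(self, stimulus_class: str) -> np.ndarray:
        return self.trial_class == stimulus_class

    def copy_with(self, **updates: Any) -> "EpochSet":
        fields = dict(
            data=self.data,
            time_ms=self.time_ms,
            fs_hz=self.fs_hz,
            trial_class=self.trial_class,
            channels=self.channels,
            retained=self.retained,
            meta=dict(self.meta),
        )
        fields.update(updates)
        return EpochSet(**fields)
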