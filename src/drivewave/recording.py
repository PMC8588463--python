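"""In-memory containers for raw and epoched multichannel recordings."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class Annotation:
    """A labelled, contiguous segment of a recording.

    Times are seconds from the start of the recording; amplitude data are
    microvolts throughout the package.
    """

    start_s: float
    duration_s: float
    state: str
    subject: str

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class Recording:
    """Uniformly sampled multichannel time series with channel roles.

    ``channels`` is an ordered list of ``(name, role)`` pairs with role in
    {"eeg", "eog", "emg"}; ``data`` has shape ``(n_channels, n_samples)``
    in microvolts.
    """

    channels: list[tuple[str, str]]
    fs: float
    data: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.start_s < -1e-9 or ann.end_s > dur + 1e-6:
                raise ValueError(
                    f"annotation [{ann.start_s}, {ann.end_s}]s outside "
                    f"recording of {dur}s"
                )
        spans = sorted((a.start_s, a.end_s) for a in self.annotations)
        for (s0, e0), (s1, _) in zip(spans[:-1], spans[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("annotations overlap")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}")

    def indices_by_role(self, role: str) -> list[int]:
        return [i for i, (_, r) in enumerate(self.channels) if r == role]

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy(self) -> "Recording":
        return replace(
            self,
            channels=list(self.channels),
            data=self.data.copy(),
            annotations=list(self.annotations),
        )


@dataclass
class Epochs:
    """Fixed-width, non-overlapping epochs cut from annotated segments.

    ``data`` has shape ``(n_epochs, n_channels, n_samples)``; ``state`` and
    ``subject`` label each epoch.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    state: np.ndarray
    subject: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.state = np.asarray(self.state)
        self.subject = np.asarray(self.subject)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        n = self.data.shape[0]
        if len(self.state) != n or len(self.subject) != n:
            raise ValueError("state/subject labels must match epoch count")
        if np.isnan(self.data).any():
            raise ValueError("epochs contain NaNs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_s(self) -> float:
        return self.data.shape[2] / self.fs
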