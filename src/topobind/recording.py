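"""Multichannel EEG recording container.

The recording is the common currency of the preprocessing chain: a
channels-by-samples array in microvolts, a sampling rate, channel labels
(Muse layout: TP9, AF7, AF8, TP10), and a sparse list of event markers
expressed as ``(sample_index, label)`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MUSE_CHANNELS = ("TP9", "AF7", "AF8", "TP10")


@dataclass
class EEGRecording:
    """A raw or preprocessed multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Unique channel labels, one per row of ``data``.
    events : list of (int, str)
        Marker positions as sample indices into ``data`` with a label.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = MUSE_CHANNELS
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names not unique: {self.channel_names}")
        for idx, label in self.events:
            if not 0 <= idx < self.n_samples:
                raise ValueError(
                    f"event {label!r} at sample {idx} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            row = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present (have {self.channel_names})"
            ) from None
        return self.data[row]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with replaced samples (same metadata)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)
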