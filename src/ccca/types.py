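"""Core container for multi-channel time-series recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiChannelRecording:
    """A multi-channel recording: a (channels x samples) matrix plus sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Real-valued amplitudes (microvolt-scale, arbitrary units).
    fs : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str, optional
        One label per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if self.data.shape[1] < 2:
            raise ValueError("recording needs at least two samples")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel_mean(self) -> np.ndarray:
        """Average signal across channels (length n_samples)."""
        return self.data.mean(axis=0)
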