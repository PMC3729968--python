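"""Epoched multichannel recordings and epoch arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EpochedRecording:
    """Sensor-level data as channels x samples x epochs.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, epoch_samples, n_epochs)``.
    fs
        Sampling frequency in Hz.
    channel_ids
        Optional channel identifiers, one per channel.
    """

    data: np.ndarray
    fs: float
    channel_ids: tuple[str, ...] | None = None
    subject_id: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, epoch_samples, n_epochs)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_ids is not None:
            self.channel_ids = tuple(self.channel_ids)
            if len(self.channel_ids) != self.data.shape[0]:
                raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Duration of one epoch in seconds."""
        return epoch_duration(self.epoch_samples, self.fs)

    def concatenated(self) -> np.ndarray:
        """Epochs joined in time: shape (n_channels, epoch_samples * n_epochs)."""
        # epochs are the trailing axis; time-major concatenation
        return self.data.transpose(0, 2, 1).reshape(self.n_channels, -1)


def epoch_duration(epoch_samples: int, fs: float) -> float:
    """Length of an epoch in seconds (e.g. 4096 samples at 625 Hz -> 6.5536 s)."""
    if epoch_samples <= 0 or fs <= 0:
        raise ValueError("epoch_samples and fs must be positive")
    return epoch_samples / fs


def n_nonoverlapping_epochs(duration_s: float, epoch_samples: int, fs: float) -> int:
    """How many non-overlapping epochs fit in a recording of given duration.

    A five-minute recording at 625 Hz holds exactly 45 epochs of 4096 samples.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    return int(np.floor(duration_s * fs / epoch_samples))
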