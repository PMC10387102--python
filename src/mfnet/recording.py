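"""In-memory containers for multichannel extracellular recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawRecording:
    """Multichannel voltage traces in microvolts.

    ``traces`` has shape (n_channels, n_samples); all channels share the
    sampling rate and length.
    """

    traces: np.ndarray  # (n_channels, n_samples), uV
    sampling_rate: float  # Hz
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.traces.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.traces.shape[0]} trace rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids are not unique")
        self._index = {c: i for i, c in enumerate(self.channel_ids)}

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            return self.traces[self._index[channel_id]]
        except KeyError:
            raise KeyError(f"unknown channel {channel_id!r}") from None

    def has_channel(self, channel_id: str) -> bool:
        return channel_id in self._index


@dataclass
class FilteredRecording(RawRecording):
    """Preprocessed recording plus the provenance needed to reproduce it."""

    provenance: dict = field(default_factory=dict)
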