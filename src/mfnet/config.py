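"""Analysis configuration: every stage parameter with its standard default."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Flat parameter set that, with the inputs and seed, fully determines
    the pipeline outputs."""

    # preprocessing
    low_hz: float = 200.0
    high_hz: float = 3500.0
    order: int = 4
    zero_phase: bool = False
    # detection
    k_mad: float = 5.0
    dead_time_ms: float = 3.0
    settle_ms: float = 100.0
    mad_statistic: str = "median"
    mad_scale: str = "normal"
    min_rate_hz: float = 0.1
    # bursts
    max_isi_ms: float = 100.0
    min_spikes: int = 2
    # correlation
    bin_ms: float = 5.0
    max_lag_bins: int = 5
    n_surrogates: int = 1000
    jitter_ms: float = 50.0
    alpha: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat key-value YAML/JSON text file."""
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
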