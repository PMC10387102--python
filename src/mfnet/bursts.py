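"""Burst detection by the interspike-interval rule and burst statistics.

A burst on one electrode is a maximal run of consecutive spikes whose
interspike intervals are all at most ``max_isi`` (100 ms by default, bound
inclusive), with at least ``min_spikes`` spikes (2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detection import SpikeTrainSet

logger = logging.getLogger(__name__)

#: relative slack applied at the ISI ceiling so exact multiples of the bound
#: survive float subtraction
_ISI_RTOL = 1e-9


@dataclass(frozen=True)
class Burst:
    start: float  # s
    end: float  # s
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass
class BurstSet:
    bursts: dict[str, list[Burst]]
    duration: float  # recording length, s
    max_isi_ms: float
    min_spikes: int

    def __post_init__(self) -> None:
        tol = self.max_isi_ms / 1000.0 * (1 + _ISI_RTOL)
        for eid, bs in self.bursts.items():
            prev_end = -np.inf
            for b in bs:
                if b.end < b.start or b.n_spikes < self.min_spikes:
                    raise ValueError(f"electrode {eid}: invalid burst {b}")
                if b.start - prev_end <= tol and prev_end > -np.inf:
                    raise ValueError(f"electrode {eid}: bursts not separated by > max_isi")
                prev_end = b.end

    def count(self, eid: str) -> int:
        return len(self.bursts.get(eid, []))


def _runs(times: np.ndarray, max_isi_s: float) -> list[np.ndarray]:
    """Maximal runs of consecutive spikes with ISI <= max_isi_s (inclusive)."""
    if len(times) == 0:
        return []
    gaps = np.diff(times) > max_isi_s * (1 + _ISI_RTOL)
    breaks = np.flatnonzero(gaps) + 1
    return np.split(times, breaks)


def detect_bursts(
    trains: SpikeTrainSet, max_isi_ms: float = 100.0, min_spikes: int = 2
) -> BurstSet:
    """Group each electrode's spikes into bursts by the ISI ceiling."""
    if max_isi_ms <= 0:
        raise ValueError("max_isi_ms must be > 0")
    if min_spikes < 2:
        raise ValueError("min_spikes must be >= 2")
    max_isi_s = max_isi_ms / 1000.0
    out: dict[str, list[Burst]] = {}
    for eid, t in trains.trains.items():
        out[eid] = [
            Burst(start=float(run[0]), end=float(run[-1]), n_spikes=len(run))
            for run in _runs(t, max_isi_s)
            if len(run) >= min_spikes
        ]
    return BurstSet(
        bursts=out, duration=trains.duration, max_isi_ms=max_isi_ms, min_spikes=min_spikes
    )


@dataclass
class BurstSummary:
    """Burst statistics per electrode and averaged over the active set.

    ``mean_burst_rate_hz`` is bursts per second.  Because that reading of
    "burst rate" is ambiguous, the intra-burst spike rate (spikes in bursts
    per total burst time) is reported as well.
    """

    per_electrode_rate: dict[str, float]  # bursts/s
    per_electrode_duration_ms: dict[str, float]  # mean over bursts; NaN if none
    mean_burst_rate_hz: float | None
    mean_burst_duration_ms: float | None
    intra_burst_spike_rate_hz: float | None
    n_electrodes_with_bursts: int = 0
    extras: dict = field(default_factory=dict)


def burst_stats(bursts: BurstSet, active: set[str], duration: float | None = None) -> BurstSummary:
    """Average burst rate and duration over the active electrode set.

    Burst-less electrodes contribute rate 0 and are excluded from the
    duration average (logged).
    """
    dur = duration if duration is not None else bursts.duration
    unknown = set(active) - set(bursts.bursts)
    if unknown:
        raise KeyError(f"active electrodes without burst data: {sorted(unknown)}")
    rates: dict[str, float] = {}
    durations: dict[str, float] = {}
    spikes_in_bursts = 0
    total_burst_time = 0.0
    n_with = 0
    for eid in sorted(active):
        bs = bursts.bursts[eid]
        rates[eid] = len(bs) / dur
        if bs:
            durations[eid] = float(np.mean([b.duration_ms for b in bs]))
            spikes_in_bursts += sum(b.n_spikes for b in bs)
            total_burst_time += sum(b.end - b.start for b in bs)
            n_with += 1
        else:
            durations[eid] = float("nan")
            logger.info("electrode %s: no bursts, excluded from duration average", eid)
    if not active:
        return BurstSummary(rates, durations, None, None, None, 0)
    with_bursts = [durations[e] for e in sorted(active) if not np.isnan(durations[e])]
    return BurstSummary(
        per_electrode_rate=rates,
        per_electrode_duration_ms=durations,
        mean_burst_rate_hz=float(np.mean(list(rates.values()))),
        mean_burst_duration_ms=float(np.mean(with_bursts)) if with_bursts else None,
        intra_burst_spike_rate_hz=(
            spikes_in_bursts / total_burst_time if total_burst_time > 0 else None
        ),
        n_electrodes_with_bursts=n_with,
    )
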