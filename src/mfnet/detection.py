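"""Spike detection by robust amplitude thresholding.

Per electrode, a threshold of +/- k times the trace's MAD is set (k = 5 by
default, MAD computed over the whole recording).  The threshold polarity is
the sign of whichever threshold the signal crosses first (the first phase
of the spike waveform); timestamps are the threshold-crossing samples, with
a post-spike dead time (3 ms) suppressing further crossings.

The MAD here is the normal-consistent median absolute deviation
(median|x - median| / 0.6745), i.e. a robust estimate of the noise standard
deviation; ``scale="raw"`` gives the unscaled deviation and
``statistic="mean"`` switches to the mean absolute deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .recording import FilteredRecording

logger = logging.getLogger(__name__)

#: E[|X|] for standard normal X is sqrt(2/pi); Phi^-1(0.75) for the median form.
_MAD_NORMAL = 0.6744897501960817
_MEANAD_NORMAL = 0.7978845608028654


def mad(x: np.ndarray, statistic: str = "median", scale: str = "normal") -> float:
    """Median (or mean) absolute deviation of ``x``.

    ``scale="normal"`` rescales to be consistent for the standard deviation
    of Gaussian noise; ``scale="raw"`` returns the plain deviation.
    """
    x = np.asarray(x, dtype=float)
    if statistic == "median":
        v = float(np.median(np.abs(x - np.median(x))))
        return v / _MAD_NORMAL if scale == "normal" else v
    if statistic == "mean":
        v = float(np.mean(np.abs(x - np.mean(x))))
        return v / _MEANAD_NORMAL if scale == "normal" else v
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps with detection metadata."""

    trains: dict[str, np.ndarray]  # electrode id -> strictly increasing times (s)
    duration: float  # s
    thresholds: dict[str, float] = field(default_factory=dict)  # signed, uV
    polarities: dict[str, int] = field(default_factory=dict)  # -1 or +1
    degenerate: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trains = {e: np.asarray(t, dtype=float) for e, t in self.trains.items()}
        self.validate()

    def validate(self) -> None:
        dead = self.params.get("dead_time_ms")
        for eid, t in self.trains.items():
            if len(t) == 0:
                continue
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError(f"electrode {eid}: timestamps outside [0, duration]")
            isis = np.diff(t)
            if np.any(isis <= 0):
                raise ValueError(f"electrode {eid}: timestamps not strictly increasing")
            if dead is not None and len(isis) and isis.min() < dead / 1000.0 * (1 - 1e-9):
                raise ValueError(
                    f"electrode {eid}: ISI {isis.min() * 1e3:.4f} ms violates "
                    f"the {dead} ms dead time"
                )

    @property
    def electrode_ids(self) -> list[str]:
        return list(self.trains)

    def counts(self) -> dict[str, int]:
        return {e: len(t) for e, t in self.trains.items()}

    def rate(self, eid: str) -> float:
        return len(self.trains[eid]) / self.duration


def _detect_channel(
    x: np.ndarray,
    sampling_rate: float,
    k_mad: float,
    dead_time_ms: float,
    settle_samples: int,
    mad_statistic: str,
    mad_scale: str,
) -> tuple[np.ndarray, float, int, bool]:
    """Detect on one trace; returns (times_s, signed threshold, polarity, degenerate)."""
    seg = x[settle_samples:]
    m = mad(seg, statistic=mad_statistic, scale=mad_scale)
    if m == 0.0:
        return np.empty(0), 0.0, -1, True
    thr = k_mad * m

    above = seg > thr
    below = seg < -thr
    pos_idx = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    neg_idx = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))

    first_pos = pos_idx[0] if len(pos_idx) else np.inf
    first_neg = neg_idx[0] if len(neg_idx) else np.inf
    if np.isinf(first_pos) and np.isinf(first_neg):
        return np.empty(0), -thr, -1, False  # fallback polarity: negative
    polarity = 1 if first_pos < first_neg else -1
    crossings = pos_idx if polarity == 1 else neg_idx

    dead = int(round(dead_time_ms / 1000.0 * sampling_rate))
    accepted: list[int] = []
    last = -dead - 1
    for i in crossings:
        if i - last >= dead:
            accepted.append(i)
            last = i
    times = (np.asarray(accepted, dtype=float) + settle_samples) / sampling_rate
    return times, polarity * thr, polarity, False


def detect_spikes(
    rec: FilteredRecording,
    k_mad: float = 5.0,
    dead_time_ms: float = 3.0,
    settle_ms: float = 100.0,
    mad_statistic: str = "median",
    mad_scale: str = "normal",
) -> SpikeTrainSet:
    """Convert filtered traces to spike trains by +/- k MAD thresholding.

    ``settle_ms`` discards an initial window from both the MAD estimate and
    detection, so filter onset transients cannot trigger.  Electrodes with
    zero MAD are flagged degenerate (no spikes, no exception).
    """
    if k_mad <= 0 or dead_time_ms <= 0:
        raise ValueError("k_mad and dead_time_ms must be > 0")
    settle = int(round(settle_ms / 1000.0 * rec.sampling_rate))
    if settle >= rec.n_samples:
        raise ValueError("settle window longer than recording")

    trains, thresholds, polarities, degenerate = {}, {}, {}, set()
    for eid, row in zip(rec.channel_ids, rec.traces):
        t, thr, pol, bad = _detect_channel(
            np.asarray(row, dtype=float), rec.sampling_rate,
            k_mad, dead_time_ms, settle, mad_statistic, mad_scale,
        )
        trains[eid] = t
        thresholds[eid] = thr
        polarities[eid] = pol
        if bad:
            degenerate.add(eid)
            logger.warning("electrode %s: zero MAD, flagged degenerate", eid)
    return SpikeTrainSet(
        trains=trains,
        duration=rec.duration,
        thresholds=thresholds,
        polarities=polarities,
        degenerate=degenerate,
        params={
            "k_mad": k_mad,
            "dead_time_ms": dead_time_ms,
            "settle_ms": settle_ms,
            "mad_statistic": mad_statistic,
            "mad_scale": mad_scale,
        },
    )


def active_electrodes(trains: SpikeTrainSet, min_rate: float = 0.1) -> set[str]:
    """Electrodes whose mean firing rate is at least ``min_rate`` Hz (inclusive)."""
    if min_rate < 0:
        raise ValueError("min_rate must be >= 0")
    return {
        e for e in trains.electrode_ids
        if e not in trains.degenerate and trains.rate(e) >= min_rate
    }


def mean_firing_rate(
    trains: SpikeTrainSet, subset: set[str] | None = None
) -> tuple[dict[str, float], float | None]:
    """Per-electrode firing rate (Hz) and the mean over ``subset``.

    An empty subset yields mean ``None`` with a warning rather than zero.
    """
    ids = trains.electrode_ids if subset is None else sorted(subset)
    unknown = set(ids) - set(trains.electrode_ids)
    if unknown:
        raise KeyError(f"electrodes not in spike-train set: {sorted(unknown)}")
    rates = {e: trains.rate(e) for e in ids}
    if not rates:
        logger.warning("mean_firing_rate: empty electrode subset, mean undefined")
        return rates, None
    return rates, float(np.mean(list(rates.values())))


@dataclass
class WaveformCutouts:
    """Fixed-length waveform windows around detections, with summaries."""

    cutouts: dict[str, np.ndarray]  # electrode -> (n_spikes_kept, n_samples)
    clipped: dict[str, int]  # spikes dropped at trace boundaries
    pre_ms: float
    post_ms: float
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)

    def amplitude_cv(self, eid: str) -> float:
        """Coefficient of variation of peak amplitude; 0 for a single spike."""
        a = np.abs(self.amplitudes[eid])
        if len(a) == 0:
            return float("nan")
        if len(a) == 1 or a.mean() == 0:
            return 0.0
        return float(a.std() / a.mean())

    def shape_dispersion(self, eid: str) -> float:
        """RMS deviation from the mean waveform, relative to its RMS."""
        w = self.cutouts[eid]
        if len(w) <= 1:
            return 0.0
        mean_w = w.mean(axis=0)
        denom = float(np.sqrt(np.mean(mean_w**2)))
        if denom == 0:
            return 0.0
        return float(np.sqrt(np.mean((w - mean_w) ** 2)) / denom)


def extract_cutouts(
    rec: FilteredRecording,
    trains: SpikeTrainSet,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> WaveformCutouts:
    """Extract aligned waveform windows around every detected spike.

    Windows that would extend past the trace boundary are counted in
    ``clipped`` and excluded from the summary statistics.  The per-electrode
    amplitude coefficient of variation quantifies waveform constancy
    (low in axonal microchannels, high near somas).
    """
    if pre_ms <= 0 or post_ms <= 0:
        raise ValueError("pre_ms and post_ms must be > 0")
    fs = rec.sampling_rate
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    cutouts, clipped, amplitudes = {}, {}, {}
    for eid in trains.electrode_ids:
        if not rec.has_channel(eid):
            continue
        x = rec.channel(eid)
        pol = trains.polarities.get(eid, -1)
        windows, n_clip = [], 0
        for t in trains.trains[eid]:
            i = int(round(t * fs))
            if i - n_pre < 0 or i + n_post > len(x):
                n_clip += 1
                continue
            windows.append(x[i - n_pre : i + n_post])
        w = np.asarray(windows) if windows else np.empty((0, n_pre + n_post))
        cutouts[eid] = w
        clipped[eid] = n_clip
        amplitudes[eid] = (
            (w.min(axis=1) if pol < 0 else w.max(axis=1)) if len(w) else np.empty(0)
        )
    return WaveformCutouts(
        cutouts=cutouts, clipped=clipped, pre_ms=pre_ms, post_ms=post_ms,
        amplitudes=amplitudes,
    )
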