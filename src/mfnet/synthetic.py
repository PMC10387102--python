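"""Synthetic MEA recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: compartmentalized spike sources firing as a Poisson background
superposed with burst trains, directional propagation of events to other
electrodes with millisecond delays, compartment-dependent spike amplitudes
(microchannel sealing amplification), biphasic negative-leading waveforms,
and i.i.d. Gaussian noise per channel.

Randomness is keyed per source / per edge / per channel from the top-level
seed, so a simulation is reproducible and *linear*: with zero noise, the
sum of single-source simulations reproduces the multi-source trace exactly.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import ElectrodeLayout, build_default_layout
from .recording import RawRecording

_NOISE_KEY = 0x4E6F6973  # namespace tags for per-stream seeding
_SOURCE_KEY = 0x53726300
_EDGE_KEY = 0x45646700


def _id_key(s: str) -> int:
    return zlib.crc32(s.encode())


@dataclass
class SourceSpec:
    """One spike source homed at an electrode.

    The event process is a homogeneous Poisson background at
    ``baseline_rate`` superposed with burst trains: burst onsets are Poisson
    at ``burst_rate``; each burst carries ``2 + Poisson(spikes_per_burst-2)``
    spikes separated by ``intra_burst_isi_ms`` with relative jitter
    ``isi_jitter``.  ``peak_uv`` is the signed template peak at the home
    electrode; per-event amplitudes get relative s.d. ``amplitude_jitter``.
    """

    source_id: str
    home_electrode: str
    baseline_rate: float  # Hz
    burst_rate: float = 0.0  # bursts/s
    spikes_per_burst: float = 7.0  # mean count, >= 2
    intra_burst_isi_ms: float = 35.0
    isi_jitter: float = 0.1
    peak_uv: float = -35.0
    width_ms: float = 1.0
    amplitude_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.burst_rate < 0:
            raise ValueError(f"source {self.source_id}: rates must be >= 0")


@dataclass
class PropagationEdge:
    """Propagation of a source's events to another electrode."""

    from_source: str
    to_electrode: str
    delay_ms: float
    transmission_prob: float = 1.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("delay must be >= 0")
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Complete event-level truth of a simulated recording."""

    duration: float
    source_events: dict[str, np.ndarray] = field(default_factory=dict)
    #: electrode id -> (times_s, amplitudes_uV, source ids) of every deposited event
    electrode_events: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = field(
        default_factory=dict
    )
    edges: list[PropagationEdge] = field(default_factory=list)
    sources: list[SourceSpec] = field(default_factory=list)
    #: per-source burst onset times
    burst_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    #: per-source, per-burst (start, end, n_spikes)
    bursts: dict[str, list[tuple[float, float, int]]] = field(default_factory=dict)

    def electrode_times(self, eid: str) -> np.ndarray:
        if eid not in self.electrode_events:
            return np.empty(0)
        return self.electrode_events[eid][0]

    def firing_rate(self, eid: str) -> float:
        return len(self.electrode_times(eid)) / self.duration

    def _electrode_delays(self) -> dict[str, list[tuple[str, float]]]:
        """Per source: electrodes it reaches with their propagation delay."""
        home = {s.source_id: s.home_electrode for s in self.sources}
        reach: dict[str, list[tuple[str, float]]] = {
            sid: [(eid, 0.0)] for sid, eid in home.items()
        }
        for e in self.edges:
            reach[e.from_source].append((e.to_electrode, e.delay_ms))
        return reach

    def directed_pairs(self, min_delay_ms: float, max_delay_ms: float) -> dict[tuple[str, str], float]:
        """True directed electrode pairs (a leads b) whose relative delay
        falls in [min_delay_ms, max_delay_ms], with that delay."""
        out: dict[tuple[str, str], float] = {}
        for reach in self._electrode_delays().values():
            for ea, da in reach:
                for eb, db in reach:
                    d = db - da
                    if ea != eb and min_delay_ms <= d <= max_delay_ms:
                        key = (ea, eb)
                        out[key] = min(out.get(key, np.inf), d)
        return out

    def synchronous_pairs(self, max_delay_ms: float) -> set[tuple[str, str]]:
        """Unordered electrode pairs co-driven within ``max_delay_ms``."""
        out: set[tuple[str, str]] = set()
        for reach in self._electrode_delays().values():
            for ea, da in reach:
                for eb, db in reach:
                    if ea < eb and abs(db - da) <= max_delay_ms:
                        out.add((ea, eb))
        return out

    def connected_pairs(self) -> set[tuple[str, str]]:
        """All unordered pairs sharing any source (any relative delay)."""
        out: set[tuple[str, str]] = set()
        for reach in self._electrode_delays().values():
            ids = sorted({e for e, _ in reach})
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    out.add((a, b))
        return out


# ---------------------------------------------------------------------------
# waveform template

def _template_shape(tt: np.ndarray, w: float) -> np.ndarray:
    s1, s2, d, r = 0.12 * w, 0.28 * w, 0.45 * w, 0.45
    return -(np.exp(-(tt**2) / (2 * s1**2)) - r * np.exp(-((tt - d) ** 2) / (2 * s2**2)))


@lru_cache(maxsize=64)
def _template_norm(width_ms: float) -> float:
    w = width_ms / 1000.0
    tt = np.linspace(-1.5 * w, 2.5 * w, 4001)
    return float(-_template_shape(tt, w).min())


def spike_template(width_ms: float, sampling_rate: float, phase: float = 0.0) -> tuple[np.ndarray, int]:
    """Biphasic negative-leading template sampled at ``sampling_rate``.

    Difference of two Gaussians: a sharp negative lobe at t=0 followed by a
    broader positive rebound.  Normalized so the continuous-time negative
    peak is -1; ``phase`` in [0, 1) is the sub-sample offset of the peak.
    Returns (samples, index offset of the t=0 sample).
    """
    w = width_ms / 1000.0
    dt = 1.0 / sampling_rate
    n0 = int(np.ceil(1.5 * w / dt))
    n1 = int(np.ceil(2.5 * w / dt))
    t = (np.arange(-n0, n1 + 1) - phase) * dt
    return _template_shape(t, w) / _template_norm(width_ms), n0


# ---------------------------------------------------------------------------
# event processes

def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _source_events(
    spec: SourceSpec, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, int]]]:
    """Event times and ground-truth burst intervals for one source."""
    times = [_poisson_times(rng, spec.baseline_rate, duration)]
    onsets = _poisson_times(rng, spec.burst_rate, duration)
    bursts: list[tuple[float, float, int]] = []
    isi = spec.intra_burst_isi_ms / 1000.0
    for onset in onsets:
        n = 2 + rng.poisson(max(spec.spikes_per_burst - 2.0, 0.0))
        isis = isi * np.clip(1.0 + spec.isi_jitter * rng.standard_normal(n - 1), 0.2, None)
        t = onset + np.concatenate([[0.0], np.cumsum(isis)])
        t = t[t < duration]
        if len(t) >= 2:
            bursts.append((float(t[0]), float(t[-1]), len(t)))
        times.append(t)
    all_t = np.sort(np.concatenate(times))
    return all_t, onsets, bursts


# ---------------------------------------------------------------------------
# simulation

def simulate_recording(
    layout: ElectrodeLayout,
    sources: list[SourceSpec],
    edges: list[PropagationEdge],
    noise_sd: float = 2.0,
    duration: float = 50.0,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
    include_references: bool = True,
) -> tuple[RawRecording, GroundTruth]:
    """Render noise plus superposed spike templates; return traces and truth.

    Source events appear at the source's home electrode; each
    :class:`PropagationEdge` deposits delayed, thinned, rescaled copies at
    its target electrode.  Reference channels (noise only) are appended when
    ``include_references`` is true.  Identical seed implies identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    source_by_id = {s.source_id: s for s in sources}
    if len(source_by_id) != len(sources):
        raise ValueError("source ids are not unique")
    for e in edges:
        if e.from_source not in source_by_id:
            raise ValueError(f"edge references unknown source {e.from_source!r}")
        layout.electrode(e.to_electrode)  # raises KeyError for unknown targets
    for s in sources:
        layout.electrode(s.home_electrode)
        if s.width_ms * s.baseline_rate / 1000.0 > 0.5 or (
            s.burst_rate > 0 and s.intra_burst_isi_ms < s.width_ms
        ):
            warnings.warn(
                f"source {s.source_id}: template width {s.width_ms} ms is wide "
                "relative to its event rate; rendered waveforms will overlap",
                stacklevel=2,
            )

    channel_ids = list(layout.electrode_ids)
    if include_references:
        channel_ids += layout.reference_ids
    n_samples = int(round(duration * sampling_rate))
    traces = np.zeros((len(channel_ids), n_samples))
    ch_index = {c: i for i, c in enumerate(channel_ids)}

    # per-channel noise, keyed by channel id so streams are layout-stable
    if noise_sd > 0:
        for cid in channel_ids:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _NOISE_KEY, _id_key(cid)])
            )
            traces[ch_index[cid]] += noise_sd * rng.standard_normal(n_samples)

    gt = GroundTruth(duration=duration, edges=list(edges), sources=list(sources))
    deposits: dict[str, list[tuple[np.ndarray, np.ndarray, str]]] = {}

    for spec in sources:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, _SOURCE_KEY, _id_key(spec.source_id)])
        )
        t_src, onsets, bursts = _source_events(spec, duration, rng)
        amp = spec.peak_uv * (1.0 + spec.amplitude_jitter * rng.standard_normal(len(t_src)))
        gt.source_events[spec.source_id] = t_src
        gt.burst_onsets[spec.source_id] = onsets
        gt.bursts[spec.source_id] = bursts
        deposits.setdefault(spec.home_electrode, []).append((t_src, amp, spec.source_id))

        for k, e in enumerate(edg for edg in edges if edg.from_source == spec.source_id):
            erng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, _EDGE_KEY, _id_key(spec.source_id), _id_key(e.to_electrode), k]
                )
            )
            keep = erng.uniform(size=len(t_src)) < e.transmission_prob
            t_prop = t_src[keep] + e.delay_ms / 1000.0
            a_prop = amp[keep] * e.amplitude_scale
            inside = t_prop < duration
            deposits.setdefault(e.to_electrode, []).append(
                (t_prop[inside], a_prop[inside], spec.source_id)
            )

    # render: one pass per (electrode, source contribution), deterministic order
    for eid in sorted(deposits):
        row = traces[ch_index[eid]]
        times_all, amps_all, src_all = [], [], []
        for t_ev, a_ev, sid in deposits[eid]:
            width = source_by_id[sid].width_ms
            for t, a in zip(t_ev, a_ev):
                idx = t * sampling_rate
                i = int(np.floor(idx))
                tmpl, n0 = spike_template(width, sampling_rate, phase=idx - i)
                lo, hi = i - n0, i - n0 + len(tmpl)
                s0, s1 = max(lo, 0), min(hi, n_samples)
                if s1 > s0:
                    # tmpl extremum is -1, so gain -a gives a signed peak of exactly a
                    row[s0:s1] += (-a) * tmpl[s0 - lo : s1 - lo]
            times_all.append(t_ev)
            amps_all.append(a_ev)
            src_all += [sid] * len(t_ev)
        t_cat = np.concatenate(times_all) if times_all else np.empty(0)
        a_cat = np.concatenate(amps_all) if amps_all else np.empty(0)
        order = np.argsort(t_cat, kind="stable")
        gt.electrode_events[eid] = (
            t_cat[order],
            a_cat[order],
            [src_all[j] for j in order],
        )

    rec = RawRecording(traces=traces, sampling_rate=sampling_rate, channel_ids=channel_ids)
    return rec, gt


# ---------------------------------------------------------------------------
# canned scenario

def scenario_dual_compartment(
    seed: int,
    duration: float = 50.0,
    sampling_rate: float = 10_000.0,
    noise_sd: float = 2.0,
    layout: ElectrodeLayout | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Dual-compartment scenario on the default layout.

    A somatic source (electrode 14) drives a feed-forward chain through a
    short microchannel (34), the synaptic chamber (44) and a long
    microchannel (64) with cumulative delays 6/12/18 ms (the efferent node).
    Three long-microchannel sources feed back onto somatic electrodes 22,
    25, 27 with delays 8/11/14 ms (the afferent nodes).  A synaptic-chamber
    source co-drives two neighbours at ~1 ms (short-term synchrony), and six
    unconnected control sources span all compartments.  All true propagation
    delays lie in [1, 25] ms; somatic firing rates lie in 0.9-2.5 Hz.
    """
    lay = layout if layout is not None else build_default_layout()

    sources = [
        # feed-forward chain: efferent somatic node
        SourceSpec("chain", "14", baseline_rate=1.2, burst_rate=0.12, peak_uv=-35.0),
        # afferent feeders homed in long microchannels
        SourceSpec("aff1", "62", baseline_rate=1.2, burst_rate=0.08, peak_uv=-100.0),
        SourceSpec("aff2", "75", baseline_rate=1.5, burst_rate=0.08, peak_uv=-100.0),
        SourceSpec("aff3", "67", baseline_rate=1.8, burst_rate=0.08, peak_uv=-100.0),
        # zero-delay common drive in the synaptic chamber
        SourceSpec("sync", "46", baseline_rate=2.0, burst_rate=0.10, peak_uv=-60.0),
        # unconnected controls
        SourceSpec("ctl_e1", "83", baseline_rate=1.8, peak_uv=-80.0),
        SourceSpec("ctl_e2", "86", baseline_rate=2.2, burst_rate=0.05, peak_uv=-80.0),
        SourceSpec("ctl_s1", "16", baseline_rate=1.0, burst_rate=0.05, peak_uv=-35.0),
        SourceSpec("ctl_s2", "23", baseline_rate=1.4, peak_uv=-35.0),
        SourceSpec("ctl_y1", "52", baseline_rate=2.0, burst_rate=0.05, peak_uv=-60.0),
        SourceSpec("ctl_m1", "37", baseline_rate=2.5, peak_uv=-90.0),
    ]
    edges = [
        PropagationEdge("chain", "34", delay_ms=6.0, transmission_prob=0.95, amplitude_scale=3.0),
        PropagationEdge("chain", "44", delay_ms=12.0, transmission_prob=0.95, amplitude_scale=1.7),
        PropagationEdge("chain", "64", delay_ms=18.0, transmission_prob=0.95, amplitude_scale=3.0),
        PropagationEdge("aff1", "22", delay_ms=8.0, transmission_prob=0.9, amplitude_scale=0.35),
        PropagationEdge("aff2", "25", delay_ms=11.0, transmission_prob=0.9, amplitude_scale=0.35),
        PropagationEdge("aff3", "27", delay_ms=14.0, transmission_prob=0.9, amplitude_scale=0.35),
        PropagationEdge("sync", "56", delay_ms=1.0, transmission_prob=0.95, amplitude_scale=1.0),
        PropagationEdge("sync", "47", delay_ms=1.5, transmission_prob=0.95, amplitude_scale=1.0),
    ]
    return simulate_recording(
        lay, sources, edges,
        noise_sd=noise_sd, duration=duration, sampling_rate=sampling_rate, seed=seed,
    )
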