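"""Readers and writers for every pipeline artifact.

Formats: recording HDF5 (/traces channels x samples float32 uV,
/sampling_rate, /channel_ids), spike-train CSV (electrode_id, t_s), burst
CSV, cross-correlation CSV (a, b, c0, cmax, delay_ms, p), GraphML via
networkx, layout and report JSON.  Every writer round-trips with its
reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .bursts import Burst, BurstSet
from .correlation import CorrelationResult, PairCorrelation
from .detection import SpikeTrainSet
from .geometry import ElectrodeLayout, build_default_layout
from .recording import RawRecording


class FormatError(ValueError):
    """Raised for malformed artifact files, with file context."""


# -- recording HDF5 ---------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces.astype(np.float32))
        f.create_dataset("sampling_rate", data=float(rec.sampling_rate))
        f.create_dataset("channel_ids", data=[c.encode() for c in rec.channel_ids])


def read_recording(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        for key in ("traces", "sampling_rate", "channel_ids"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset /{key}")
        return RawRecording(
            traces=f["traces"][...].astype(np.float64),
            sampling_rate=float(f["sampling_rate"][()]),
            channel_ids=[c.decode() for c in f["channel_ids"][...]],
        )


# -- spike trains -----------------------------------------------------------

def write_spike_trains(trains: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        {"electrode_id": eid, "t_s": t}
        for eid in trains.electrode_ids
        for t in trains.trains[eid]
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "t_s"])
    df.to_csv(path, index=False, float_format="%.9f")
    meta = {
        "duration": trains.duration,
        "params": trains.params,
        "thresholds": trains.thresholds,
        "polarities": trains.polarities,
        "degenerate": sorted(trains.degenerate),
        "electrode_ids": trains.electrode_ids,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_spike_trains(path: str | Path) -> SpikeTrainSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error context
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != ["electrode_id", "t_s"]:
        raise FormatError(f"{path}: expected columns electrode_id,t_s, got {list(df.columns)}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ids = meta.get("electrode_ids", sorted(df["electrode_id"].astype(str).unique()))
    trains = {eid: np.empty(0) for eid in ids}
    for eid, grp in df.groupby("electrode_id"):
        trains[str(eid)] = np.sort(grp["t_s"].to_numpy(dtype=float))
    duration = float(meta.get("duration", max((t[-1] for t in trains.values() if len(t)), default=0.0)))
    return SpikeTrainSet(
        trains=trains,
        duration=duration,
        thresholds=meta.get("thresholds", {}),
        polarities={k: int(v) for k, v in meta.get("polarities", {}).items()},
        degenerate=set(meta.get("degenerate", [])),
        params=meta.get("params", {}),
    )


# -- bursts -----------------------------------------------------------------

def write_bursts(bursts: BurstSet, path: str | Path) -> None:
    rows = [
        {
            "electrode_id": eid,
            "t_start_s": b.start,
            "t_end_s": b.end,
            "n_spikes": b.n_spikes,
            "duration_ms": b.duration_ms,
        }
        for eid in sorted(bursts.bursts)
        for b in bursts.bursts[eid]
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "t_start_s", "t_end_s", "n_spikes", "duration_ms"])
    df.to_csv(path, index=False, float_format="%.9f")


def read_bursts(path: str | Path, duration: float, max_isi_ms: float = 100.0, min_spikes: int = 2) -> BurstSet:
    df = pd.read_csv(path)
    out: dict[str, list[Burst]] = {}
    for eid, grp in df.groupby("electrode_id"):
        out[str(eid)] = [
            Burst(start=float(r.t_start_s), end=float(r.t_end_s), n_spikes=int(r.n_spikes))
            for r in grp.itertuples()
        ]
    return BurstSet(bursts=out, duration=duration, max_isi_ms=max_isi_ms, min_spikes=min_spikes)


# -- cross-correlation ------------------------------------------------------

def write_correlations(cc: CorrelationResult, path: str | Path) -> None:
    rows = [
        {
            "a": a, "b": b,
            "c0": pc.c0, "cmax": pc.c_max,
            "delay_ms": pc.delay_ms, "p": pc.p_value,
            "degenerate": int(pc.degenerate),
        }
        for (a, b), pc in sorted(cc.pairs.items())
    ]
    df = pd.DataFrame(rows, columns=["a", "b", "c0", "cmax", "delay_ms", "p", "degenerate"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_correlations(path: str | Path, bin_ms: float = 5.0, max_lag_bins: int = 5) -> CorrelationResult:
    df = pd.read_csv(path)
    pairs = {}
    for r in df.itertuples():
        a, b = str(r.a), str(r.b)
        pairs[(a, b)] = PairCorrelation(
            a=a, b=b, c0=float(r.c0), c_max=float(r.cmax),
            lag_bins=int(round(float(r.delay_ms) / bin_ms)),
            delay_ms=float(r.delay_ms), degenerate=bool(r.degenerate),
            p_value=float(r.p),
        )
    return CorrelationResult(pairs=pairs, bin_ms=bin_ms, max_lag_bins=max_lag_bins)


# -- graphs and layout ------------------------------------------------------

def write_graphml(graph: "nx.Graph", path: str | Path) -> None:
    # GraphML cannot carry NaN edge attributes portably; stringify them
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, float) and np.isnan(v):
                data[k] = "nan"
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> "nx.Graph":
    return nx.read_graphml(str(path))


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    Path(path).write_text(layout.to_json())


def read_layout(path: str | Path) -> ElectrodeLayout:
    try:
        return build_default_layout(json.loads(Path(path).read_text()))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc


# -- reports ----------------------------------------------------------------

def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
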