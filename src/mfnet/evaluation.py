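"""Ground-truth evaluation utilities for simulated recordings.

Used to score detection (event matching at a time tolerance) and network
inference (directed-edge recovery and spurious-edge rates) against the
generator's :class:`~mfnet.synthetic.GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ConnectivityEdge
from .synthetic import GroundTruth


def match_events(
    true_times: np.ndarray, detected_times: np.ndarray, tol_s: float = 1e-3
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of sorted event times within ``tol_s``.

    Both inputs must be sorted; each event participates in at most one
    match.  Returns (true index, detected index) pairs.
    """
    t = np.asarray(true_times, dtype=float)
    d = np.asarray(detected_times, dtype=float)
    i = j = 0
    matches: list[tuple[int, int]] = []
    while i < len(t) and j < len(d):
        diff = d[j] - t[i]
        if abs(diff) <= tol_s:
            matches.append((i, j))
            i += 1
            j += 1
        elif diff < 0:
            j += 1
        else:
            i += 1
    return matches


@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float


def score_detection(
    gt: GroundTruth,
    trains: dict[str, np.ndarray],
    tol_s: float = 1e-3,
    min_amplitude_uv: dict[str, float] | None = None,
) -> DetectionScore:
    """Recall/precision of detected trains against ground-truth events.

    Recall is computed over qualifying true events (those with
    |amplitude| >= the per-electrode ``min_amplitude_uv``, when given);
    precision over all detections, with matching against all true events.
    """
    n_true = n_det = n_matched_q = n_matched_all = 0
    for eid, det in trains.items():
        tt, amps, _ = gt.electrode_events.get(eid, (np.empty(0), np.empty(0), []))
        matches = match_events(tt, det, tol_s)
        matched_true = {i for i, _ in matches}
        if min_amplitude_uv and eid in min_amplitude_uv:
            qualifying = np.flatnonzero(np.abs(amps) >= min_amplitude_uv[eid])
        else:
            qualifying = np.arange(len(tt))
        n_true += len(qualifying)
        n_matched_q += len(matched_true & set(qualifying.tolist()))
        n_matched_all += len(matches)
        n_det += len(det)
    return DetectionScore(
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched_q,
        recall=n_matched_q / n_true if n_true else float("nan"),
        precision=n_matched_all / n_det if n_det else float("nan"),
    )


@dataclass
class EdgeScore:
    n_true: int
    n_recovered: int  # true directed pairs found with correct orientation
    n_edges: int  # edges in the inferred graph
    n_spurious: int  # inferred edges between unconnected electrode pairs
    n_null_pairs: int  # tested pairs that share no source
    recall: float
    spurious_rate: float


def score_delayed_edges(
    gt: GroundTruth,
    edges: list[ConnectivityEdge],
    tested_pairs: list[tuple[str, str]],
    min_delay_ms: float = 5.0,
    max_delay_ms: float = 25.0,
) -> EdgeScore:
    """Directed-edge recovery against the ground-truth propagation closure.

    True pairs are electrode pairs sharing a source with relative delay in
    [min_delay_ms, max_delay_ms]; an edge counts as recovered when its
    orientation matches the true lead/lag order.  Spurious edges connect
    pairs that share no source at all; the rate is per tested null pair.
    """
    true_directed = gt.directed_pairs(min_delay_ms, max_delay_ms)
    connected = gt.connected_pairs()
    inferred = {(e.from_electrode, e.to_electrode) for e in edges}
    n_recovered = sum(1 for pair in true_directed if pair in inferred)
    null_pairs = [p for p in tested_pairs if tuple(sorted(p)) not in connected]
    n_spurious = sum(
        1 for a, b in inferred if tuple(sorted((a, b))) not in connected
    )
    return EdgeScore(
        n_true=len(true_directed),
        n_recovered=n_recovered,
        n_edges=len(edges),
        n_spurious=n_spurious,
        n_null_pairs=len(null_pairs),
        recall=n_recovered / len(true_directed) if true_directed else float("nan"),
        spurious_rate=n_spurious / len(null_pairs) if null_pairs else float("nan"),
    )


def score_short_term_edges(
    gt: GroundTruth,
    edges: list[ConnectivityEdge],
    max_delay_ms: float = 2.5,
) -> tuple[int, int, float]:
    """(n_true, n_recovered, recall) for zero-delay common-drive pairs."""
    true_pairs = gt.synchronous_pairs(max_delay_ms)
    inferred = {tuple(sorted((e.from_electrode, e.to_electrode))) for e in edges}
    n_rec = sum(1 for p in true_pairs if p in inferred)
    return len(true_pairs), n_rec, n_rec / len(true_pairs) if true_pairs else float("nan")
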