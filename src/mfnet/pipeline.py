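"""End-to-end analysis pipeline: preprocess -> detect -> bursts ->
correlate -> graphs, with stage logging and reproducible reports."""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__, io
from .bursts import burst_stats, detect_bursts
from .config import AnalysisConfig
from .correlation import attach_significance, bin_trains, compute_pair_correlations
from .detection import active_electrodes, detect_spikes, mean_firing_rate
from .geometry import ElectrodeLayout
from .graph import classify_edges, delayed_graph, node_roles, short_term_graph, to_networkx
from .preprocess import preprocess
from .recording import RawRecording

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    rec: RawRecording,
    layout: ElectrodeLayout,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return a deterministic report dictionary.

    All randomness (surrogate nulls) is seeded from the configuration, so
    identical inputs and config produce byte-identical serialized reports.
    When ``outdir`` is given, every intermediate artifact is written there;
    on stage failure, partial outputs are retained next to a
    ``FAILED_<stage>`` marker file.
    """
    cfg = config if config is not None else AnalysisConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "preprocess"
    try:
        filt = preprocess(
            rec, layout, low=cfg.low_hz, high=cfg.high_hz,
            order=cfg.order, zero_phase=cfg.zero_phase,
        )
        logger.info("preprocess: %d channels re-referenced and filtered", filt.n_channels)

        stage = "detect"
        trains = detect_spikes(
            filt, k_mad=cfg.k_mad, dead_time_ms=cfg.dead_time_ms,
            settle_ms=cfg.settle_ms, mad_statistic=cfg.mad_statistic,
            mad_scale=cfg.mad_scale,
        )
        active = active_electrodes(trains, min_rate=cfg.min_rate_hz)
        rates, mean_rate = mean_firing_rate(trains, active)
        logger.info("detect: %d/%d electrodes active", len(active), len(trains.electrode_ids))
        if out is not None:
            io.write_spike_trains(trains, out / "spikes.csv")

        stage = "bursts"
        bursts = detect_bursts(trains, max_isi_ms=cfg.max_isi_ms, min_spikes=cfg.min_spikes)
        bsummary = burst_stats(bursts, active)
        if out is not None:
            io.write_bursts(bursts, out / "bursts.csv")

        stage = "correlate"
        binned = bin_trains(trains, bin_ms=cfg.bin_ms)
        cc = compute_pair_correlations(binned, subset=sorted(active), max_lag_bins=cfg.max_lag_bins)
        attach_significance(
            cc, trains, n_surrogates=cfg.n_surrogates,
            jitter_ms=cfg.jitter_ms, seed=cfg.seed,
        )
        cc.alpha = cfg.alpha
        n_sig = sum(1 for pc in cc.pairs.values() if pc.p_value < cfg.alpha)
        logger.info("correlate: %d pairs, %d significant at alpha=%g",
                    len(cc.pairs), n_sig, cfg.alpha)
        if out is not None:
            io.write_correlations(cc, out / "cc.csv")

        stage = "graph"
        short_edges = short_term_graph(cc, layout, alpha=cfg.alpha)
        delayed_edges = delayed_graph(cc, layout, alpha=cfg.alpha)
        short_summary = classify_edges(short_edges, layout, electrodes=active)
        delayed_summary = classify_edges(delayed_edges, layout, electrodes=active)
        roles = node_roles(delayed_edges, layout, electrodes=active)
        if out is not None:
            io.write_graphml(to_networkx(short_edges, layout, directed=False), out / "short_term.graphml")
            io.write_graphml(to_networkx(delayed_edges, layout, directed=True), out / "delayed.graphml")
    except Exception as exc:
        if out is not None:
            (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "n_channels": rec.n_channels,
        "duration_s": rec.duration,
        "n_active": len(active),
        "active_electrodes": sorted(active),
        "degenerate_electrodes": sorted(trains.degenerate),
        "spike_counts": {e: int(n) for e, n in sorted(trains.counts().items())},
        "mean_rate_hz_active": mean_rate,
        "per_electrode_rate_hz": {e: rates[e] for e in sorted(rates)},
        "bursts": {
            "mean_burst_rate_hz": bsummary.mean_burst_rate_hz,
            "mean_burst_duration_ms": bsummary.mean_burst_duration_ms,
            "intra_burst_spike_rate_hz": bsummary.intra_burst_spike_rate_hz,
            "n_electrodes_with_bursts": bsummary.n_electrodes_with_bursts,
        },
        "correlation": {
            "n_pairs_tested": len(cc.pairs),
            "n_significant": n_sig,
            "alpha": cfg.alpha,
        },
        "short_term_graph": {
            "n_edges": short_summary.n_edges,
            "counts_by_class": short_summary.counts_by_class,
        },
        "delayed_graph": {
            "n_edges": delayed_summary.n_edges,
            "counts_by_class": delayed_summary.counts_by_class,
            "edges": [
                {
                    "from": e.from_electrode, "to": e.to_electrode,
                    "delay_ms": e.delay_ms, "strength": e.strength,
                    "class": e.edge_class.value,
                }
                for e in delayed_edges
            ],
        },
        "node_roles": {
            eid: {
                "role": r.role.value if r.role is not None else None,
                "in_degree": r.in_degree,
                "out_degree": r.out_degree,
            }
            for eid, r in sorted(roles.items())
        },
    }
    if out is not None:
        io.write_report(report, out / "report.json")
        cfg.to_file(out / "config.yaml")
    return report
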