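"""Preprocessing: column-group re-referencing and Bessel bandpass filtering.

Raw traces are first re-referenced against their layout-assigned reference
channel (columns 1-4 against R1, columns 5-8 against R2 in the default
layout) to remove shared artifacts, then bandpass filtered with a 4th-order
Bessel filter (200-3500 Hz).  The default filter pass is single and causal
so that inter-electrode delays used for directionality are not smeared
acausally; a zero-phase option is available.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .geometry import ElectrodeLayout
from .recording import FilteredRecording, RawRecording


def rereference(rec: RawRecording, layout: ElectrodeLayout) -> RawRecording:
    """Subtract each electrode's reference channel, sample-wise.

    Output contains the analysis electrodes only (reference channels are
    dropped).  Raises ``KeyError`` naming the first missing reference
    channel.
    """
    out = np.empty((len(layout.electrode_ids), rec.n_samples), dtype=rec.traces.dtype)
    for i, eid in enumerate(layout.electrode_ids):
        ref = layout.reference_map[eid]
        if not rec.has_channel(ref):
            raise KeyError(
                f"reference channel {ref!r} for electrode {eid!r} is missing from the recording"
            )
        out[i] = rec.channel(eid) - rec.channel(ref)
    return RawRecording(
        traces=out, sampling_rate=rec.sampling_rate, channel_ids=list(layout.electrode_ids)
    )


def bessel_bandpass_sos(
    low: float, high: float, order: int, sampling_rate: float
) -> np.ndarray:
    """Digital Bessel bandpass (bilinear transform, pre-warped cutoffs)."""
    nyq = sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz >= Nyquist {nyq} Hz: raise the sampling rate "
            "or lower the cutoff"
        )
    return signal.bessel(
        order, [low, high], btype="bandpass", output="sos", fs=sampling_rate, norm="phase"
    )


def bandpass(
    rec: RawRecording,
    low: float = 200.0,
    high: float = 3500.0,
    order: int = 4,
    zero_phase: bool = False,
) -> FilteredRecording:
    """Bandpass-filter every channel; records filter provenance.

    Linear per channel; rejects DC.  ``zero_phase`` applies the filter
    forward and backward (no group delay, but acausal).
    """
    sos = bessel_bandpass_sos(low, high, order, rec.sampling_rate)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.traces, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.traces, axis=1)
    return FilteredRecording(
        traces=filtered,
        sampling_rate=rec.sampling_rate,
        channel_ids=list(rec.channel_ids),
        provenance={
            "filter": {
                "type": "bessel",
                "order": order,
                "low_hz": low,
                "high_hz": high,
                "zero_phase": zero_phase,
            }
        },
    )


def preprocess(
    rec: RawRecording,
    layout: ElectrodeLayout,
    low: float = 200.0,
    high: float = 3500.0,
    order: int = 4,
    zero_phase: bool = False,
) -> FilteredRecording:
    """Re-reference then bandpass (in that order; they do not commute)."""
    reref = rereference(rec, layout)
    out = bandpass(reref, low=low, high=high, order=order, zero_phase=zero_phase)
    out.provenance["reference_map"] = dict(layout.reference_map)
    return out
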