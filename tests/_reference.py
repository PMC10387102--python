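"""Independent brute-force reference implementations used as test oracles.

Deliberately written as per-sample / per-spike scans with no shared code
paths with the package internals.
"""

from __future__ import annotations

import numpy as np


def ref_mad(x, statistic="median", scale="normal"):
    x = np.asarray(x, dtype=float)
    if statistic == "median":
        center = np.median(x)
        v = np.median(np.abs(x - center))
        return v / 0.6744897501960817 if scale == "normal" else v
    center = np.mean(x)
    v = np.mean(np.abs(x - center))
    return v / 0.7978845608028654 if scale == "normal" else v


def ref_detect(x, sampling_rate, k_mad=5.0, dead_time_ms=3.0,
               statistic="median", scale="normal"):
    """Exhaustive per-sample spike detection following the stated rule.

    Returns (times list, signed threshold, polarity).
    """
    x = np.asarray(x, dtype=float)
    m = ref_mad(x, statistic, scale)
    if m == 0.0:
        return [], 0.0, -1
    thr = k_mad * m

    # polarity: sign of the first sample beyond either threshold coming
    # from inside the band (or starting beyond it)
    polarity = None
    for i in range(len(x)):
        beyond_pos = x[i] > thr
        beyond_neg = x[i] < -thr
        prev_pos = i > 0 and x[i - 1] > thr
        prev_neg = i > 0 and x[i - 1] < -thr
        if beyond_pos and not prev_pos:
            polarity = 1
            break
        if beyond_neg and not prev_neg:
            polarity = -1
            break
    if polarity is None:
        return [], -thr, -1

    dead = int(round(dead_time_ms / 1000.0 * sampling_rate))
    times = []
    last = None
    for i in range(len(x)):
        beyond = x[i] > thr if polarity == 1 else x[i] < -thr
        prev = (x[i - 1] > thr if polarity == 1 else x[i - 1] < -thr) if i > 0 else False
        if beyond and not prev:
            if last is None or i - last >= dead:
                times.append(i / sampling_rate)
                last = i
    return times, polarity * thr, polarity


def ref_bursts(times, max_isi_ms=100.0, min_spikes=2):
    """Quadratic burst grouper: for each spike scan forward while the gap
    stays within the ceiling.  Returns (start, end, count) tuples."""
    times = list(map(float, times))
    ceiling = max_isi_ms / 1000.0 * (1 + 1e-9)
    bursts = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and (times[j + 1] - times[j]) <= ceiling:
            j += 1
        if j - i + 1 >= min_spikes:
            bursts.append((times[i], times[j], j - i + 1))
        i = j + 1
    return bursts


def ref_xcorr(x, y, max_lag):
    """Per-lag Pearson correlation via numpy.corrcoef on explicit slices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    out = {}
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if len(xs) < 2 or np.std(xs) == 0 or np.std(ys) == 0:
            out[lag] = 0.0
        else:
            out[lag] = float(np.corrcoef(xs, ys)[0, 1])
    return out
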