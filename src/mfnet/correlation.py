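"""Binned cross-correlation of spike trains and surrogate significance.

Spike trains are binned in 5 ms intervals; for each electrode pair the
Pearson correlation of the binned counts is computed at every lag within
+/- ``max_lag_bins`` bins.  Both the central-bin coefficient (zero lag) and
the maximum-bin coefficient with its delay are extracted; a positive delay
for pair (a, b) means a leads b.  Significance replaces visual inspection
with a spike-time jittering surrogate null that preserves firing rates but
destroys fine timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import SpikeTrainSet
from .geometry import ElectrodeLayout

#: relative slack on bin-index computation so spikes at exact bin edges land
#: in the later (half-open) bin despite float division error
_BIN_EPS = 1e-9


# ---------------------------------------------------------------------------
# binning

@dataclass
class BinnedTrains:
    """Per-electrode spike counts in half-open bins [k*bin, (k+1)*bin)."""

    counts: np.ndarray  # (n_electrodes, n_bins) float
    electrode_ids: list[str]
    bin_ms: float
    duration: float

    def __post_init__(self) -> None:
        self._index = {e: i for i, e in enumerate(self.electrode_ids)}

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def vector(self, eid: str) -> np.ndarray:
        return self.counts[self._index[eid]]


def _n_bins(duration: float, bin_s: float) -> int:
    return int(np.ceil(duration / bin_s - _BIN_EPS))


def _bin_times(times: np.ndarray, n_bins: int, bin_s: float) -> np.ndarray:
    idx = np.floor(np.asarray(times) / bin_s + _BIN_EPS).astype(np.int64)
    # a spike at exactly t = duration is kept in the last bin so that the
    # count sum always equals the spike count
    np.clip(idx, 0, n_bins - 1, out=idx)
    return np.bincount(idx, minlength=n_bins).astype(float)


def bin_trains(trains: SpikeTrainSet, bin_ms: float = 5.0) -> BinnedTrains:
    """Bin every electrode's spike train at ``bin_ms`` resolution."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    bin_s = bin_ms / 1000.0
    n_bins = _n_bins(trains.duration, bin_s)
    ids = trains.electrode_ids
    counts = np.empty((len(ids), n_bins))
    for i, eid in enumerate(ids):
        counts[i] = _bin_times(trains.trains[eid], n_bins, bin_s)
    return BinnedTrains(counts=counts, electrode_ids=ids, bin_ms=bin_ms, duration=trains.duration)


# ---------------------------------------------------------------------------
# lagged Pearson correlation

@dataclass
class LagCorrelation:
    """Pearson coefficient of (x, lag-shifted y) per lag in bins."""

    lags: np.ndarray  # bins, [-max_lag .. +max_lag]
    coefs: np.ndarray
    valid: np.ndarray  # False where a slice had zero variance (coef set to 0)


def _pearson(xs: np.ndarray, ys: np.ndarray) -> tuple[float, bool]:
    n = len(xs)
    if n < 2:
        return 0.0, False
    sx = xs.sum()
    sy = ys.sum()
    vx = n * (xs**2).sum() - sx * sx
    vy = n * (ys**2).sum() - sy * sy
    if vx <= 0 or vy <= 0:
        return 0.0, False
    num = n * (xs @ ys) - sx * sy
    return float(num / np.sqrt(vx * vy)), True


def cross_correlate(x: np.ndarray, y: np.ndarray, max_lag_bins: int) -> LagCorrelation:
    """Lagged Pearson correlation with overlapping-region normalization.

    ``coefs[j]`` is the correlation of x[i] with y[i + lags[j]] over the
    overlapping samples; a positive lag of the maximum means x leads y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"binned vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if max_lag_bins < 0:
        raise ValueError("max_lag_bins must be >= 0")
    n = len(x)
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    coefs = np.zeros(len(lags))
    valid = np.zeros(len(lags), dtype=bool)
    for j, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        coefs[j], valid[j] = _pearson(xs, ys)
    return LagCorrelation(lags=lags, coefs=coefs, valid=valid)


def _lag_preference(max_lag_bins: int) -> np.ndarray:
    """Tie-break order for the maximum bin: smallest |lag| first, then negative."""
    order = [0]
    for lag in range(1, max_lag_bins + 1):
        order += [-lag, lag]
    return np.asarray(order)


@dataclass
class PairCorrelation:
    """Central-bin and maximum-bin statistics for one ordered pair (a, b)."""

    a: str
    b: str
    c0: float
    c_max: float
    lag_bins: int  # lag of the maximum; positive: a leads b
    delay_ms: float
    degenerate: bool = False
    p_value: float = float("nan")

    def swapped(self) -> "PairCorrelation":
        """The same pair viewed as (b, a): coefficients symmetric, delay negated."""
        return PairCorrelation(
            a=self.b, b=self.a, c0=self.c0, c_max=self.c_max,
            lag_bins=-self.lag_bins, delay_ms=-self.delay_ms,
            degenerate=self.degenerate, p_value=self.p_value,
        )


def _extract_pair(lc: LagCorrelation, bin_ms: float, a: str, b: str) -> PairCorrelation:
    max_lag = (len(lc.lags) - 1) // 2
    pref = _lag_preference(max_lag)
    pos = {int(l): j for j, l in enumerate(lc.lags)}
    coefs_pref = np.array([lc.coefs[pos[int(l)]] for l in pref])
    best = int(pref[int(np.argmax(coefs_pref))])
    return PairCorrelation(
        a=a, b=b,
        c0=float(lc.coefs[pos[0]]),
        c_max=float(coefs_pref.max()),
        lag_bins=best,
        delay_ms=best * bin_ms,
        degenerate=not lc.valid.any(),
    )


def pair_correlation(
    x: np.ndarray, y: np.ndarray, bin_ms: float, max_lag_bins: int, a: str = "a", b: str = "b"
) -> PairCorrelation:
    """Central-bin and maximum-bin coefficients for one binned pair.

    Ties in the maximum are broken toward the smallest |lag|, then toward
    the negative lag.
    """
    return _extract_pair(cross_correlate(x, y, max_lag_bins), bin_ms, a, b)


@dataclass
class CorrelationResult:
    """Pairwise correlation statistics over an electrode set.

    Stores one :class:`PairCorrelation` per unordered pair under the key
    (a, b) with a < b; :meth:`get` serves both orders (delay antisymmetric).
    """

    pairs: dict[tuple[str, str], PairCorrelation]
    bin_ms: float
    max_lag_bins: int
    alpha: float | None = None

    def get(self, a: str, b: str) -> PairCorrelation:
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]
        return self.pairs[(b, a)].swapped()

    def ordered_keys(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)


def compute_pair_correlations(
    binned: BinnedTrains,
    subset: list[str] | None = None,
    max_lag_bins: int = 5,
) -> CorrelationResult:
    """All unordered pairwise correlations over ``subset`` (default: all)."""
    ids = sorted(subset) if subset is not None else sorted(binned.electrode_ids)
    pairs: dict[tuple[str, str], PairCorrelation] = {}
    for i, a in enumerate(ids):
        xa = binned.vector(a)
        for b in ids[i + 1:]:
            pairs[(a, b)] = pair_correlation(
                xa, binned.vector(b), binned.bin_ms, max_lag_bins, a, b
            )
    return CorrelationResult(pairs=pairs, bin_ms=binned.bin_ms, max_lag_bins=max_lag_bins)


# ---------------------------------------------------------------------------
# correlation matrix

@dataclass
class CorrelationMatrix:
    """Symmetric matrix of central-bin coefficients in compartment order."""

    electrode_ids: list[str]
    matrix: np.ndarray
    degenerate: set[str] = field(default_factory=set)


def correlation_matrix(
    binned: BinnedTrains,
    subset: list[str] | None = None,
    layout: ElectrodeLayout | None = None,
) -> CorrelationMatrix:
    """Lag-0 correlation matrix; rows ordered by the layout's compartment
    color-bar order when a layout is given.

    Zero-variance (silent) electrodes get zero rows/columns and are flagged;
    the diagonal is 1 for electrodes with nonzero variance.
    """
    ids = list(subset) if subset is not None else list(binned.electrode_ids)
    if not ids:
        raise ValueError("electrode subset is empty")
    if layout is not None:
        ids = layout.matrix_order(ids)
    counts = np.stack([binned.vector(e) for e in ids])
    sd = counts.std(axis=1)
    ok = sd > 0
    mat = np.zeros((len(ids), len(ids)))
    if ok.sum() >= 1:
        sub = np.atleast_2d(np.corrcoef(counts[ok])) if ok.sum() > 1 else np.ones((1, 1))
        mat[np.ix_(ok, ok)] = sub
    degenerate = {e for e, good in zip(ids, ok) if not good}
    return CorrelationMatrix(electrode_ids=ids, matrix=mat, degenerate=degenerate)


# ---------------------------------------------------------------------------
# surrogate significance

@dataclass
class SurrogateTest:
    """Jitter-surrogate p-values for one pair's statistics."""

    p_cmax: float
    p_c0: float
    n_surrogates: int
    observed: PairCorrelation
    defined: bool = True


def _surrogate_coef_max(
    x: np.ndarray,
    y_times: np.ndarray,
    duration: float,
    bin_s: float,
    max_lag: int,
    n_surrogates: int,
    jitter_s: float,
    rng: np.random.Generator,
    block: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-lag and lag-0 coefficients for jittered copies of y versus x.

    Vectorized over surrogates (processed in blocks); jittered times wrap
    around the recording so rates are preserved exactly.
    """
    n_bins = len(x)
    lags = np.arange(-max_lag, max_lag + 1)
    # per-lag slice bounds and x-side moments
    xparts = []
    for lag in lags:
        if lag >= 0:
            xs = x[: n_bins - lag]
            ya, yb = lag, n_bins
        else:
            xs = x[-lag:]
            ya, yb = 0, n_bins + lag
        xparts.append((xs, ya, yb, xs.sum(), (xs**2).sum(), len(xs)))

    cmax = np.empty(n_surrogates)
    c0 = np.empty(n_surrogates)
    done = 0
    while done < n_surrogates:
        nb = min(block, n_surrogates - done)
        jit = rng.uniform(-jitter_s, jitter_s, size=(nb, len(y_times)))
        t = np.mod(y_times[None, :] + jit, duration)
        idx = np.floor(t / bin_s + _BIN_EPS).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        flat = idx + (np.arange(nb) * n_bins)[:, None]
        Y = np.bincount(flat.ravel(), minlength=nb * n_bins).reshape(nb, n_bins).astype(float)
        cs = np.cumsum(Y, axis=1)
        cs2 = np.cumsum(Y * Y, axis=1)

        coefs = np.zeros((nb, len(lags)))
        for j, (xs, ya, yb, sx, sx2, n_ov) in enumerate(xparts):
            if n_ov < 2:
                continue
            sy = cs[:, yb - 1] - (cs[:, ya - 1] if ya > 0 else 0.0)
            sy2 = cs2[:, yb - 1] - (cs2[:, ya - 1] if ya > 0 else 0.0)
            vx = n_ov * sx2 - sx * sx
            vy = n_ov * sy2 - sy * sy
            num = n_ov * (Y[:, ya:yb] @ xs) - sx * sy
            good = (vx > 0) & (vy > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(good, num / np.sqrt(vx * vy), 0.0)
            coefs[:, j] = r
        cmax[done : done + nb] = coefs.max(axis=1)
        c0[done : done + nb] = coefs[:, max_lag]
        done += nb
    return cmax, c0


def significance_by_surrogates(
    x_times: np.ndarray,
    y_times: np.ndarray,
    duration: float,
    bin_ms: float = 5.0,
    max_lag_bins: int = 5,
    n_surrogates: int = 1000,
    jitter_ms: float = 50.0,
    seed: int = 0,
) -> SurrogateTest:
    """p-values for the observed pair statistics against a jitter null.

    The null jitters every spike of the second train uniformly within
    +/- ``jitter_ms`` (wrapped at the recording boundaries), preserving the
    rate but destroying fine timing; p = (1 + #{surrogate >= observed}) /
    (n_surrogates + 1).  Pairs with fewer than 2 spikes on either train get
    NaN p-values with ``defined=False``.
    """
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be >= 100")
    bin_s = bin_ms / 1000.0
    n_bins = _n_bins(duration, bin_s)
    x = _bin_times(np.asarray(x_times, dtype=float), n_bins, bin_s)
    y = _bin_times(np.asarray(y_times, dtype=float), n_bins, bin_s)
    observed = pair_correlation(x, y, bin_ms, max_lag_bins)
    if len(x_times) < 2 or len(y_times) < 2:
        return SurrogateTest(
            p_cmax=float("nan"), p_c0=float("nan"),
            n_surrogates=n_surrogates, observed=observed, defined=False,
        )
    rng = np.random.default_rng(seed)
    cmax_s, c0_s = _surrogate_coef_max(
        x, np.asarray(y_times, dtype=float), duration, bin_s,
        max_lag_bins, n_surrogates, jitter_ms / 1000.0, rng,
    )
    p_cmax = (1.0 + np.count_nonzero(cmax_s >= observed.c_max)) / (n_surrogates + 1.0)
    p_c0 = (1.0 + np.count_nonzero(c0_s >= observed.c0)) / (n_surrogates + 1.0)
    return SurrogateTest(
        p_cmax=float(p_cmax), p_c0=float(p_c0),
        n_surrogates=n_surrogates, observed=observed,
    )


def attach_significance(
    result: CorrelationResult,
    trains: SpikeTrainSet,
    n_surrogates: int = 1000,
    jitter_ms: float = 50.0,
    seed: int = 0,
) -> CorrelationResult:
    """Fill ``p_value`` (of c_max) for every stored pair, seeded per pair."""
    import zlib

    for (a, b), pc in sorted(result.pairs.items()):
        pair_seed = np.random.SeedSequence(
            [seed, zlib.crc32(a.encode()), zlib.crc32(b.encode())]
        ).generate_state(1)[0] % (2**31)
        test = significance_by_surrogates(
            trains.trains[a], trains.trains[b], trains.duration,
            bin_ms=result.bin_ms, max_lag_bins=result.max_lag_bins,
            n_surrogates=n_surrogates, jitter_ms=jitter_ms, seed=int(pair_seed),
        )
        pc.p_value = test.p_cmax
    return result
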