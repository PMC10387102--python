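import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfnet.correlation import (
    LagCorrelation,
    _extract_pair,
    bin_trains,
    correlation_matrix,
    compute_pair_correlations,
    cross_correlate,
    pair_correlation,
    significance_by_surrogates,
)
from mfnet.detection import SpikeTrainSet

from _reference import ref_xcorr


def binned_of(times_by_electrode, duration, bin_ms=5.0):
    trains = SpikeTrainSet(
        trains={k: np.asarray(v, dtype=float) for k, v in times_by_electrode.items()},
        duration=duration,
    )
    return bin_trains(trains, bin_ms=bin_ms)


class TestBinning:
    def test_forced_counts(self):
        b = binned_of({"e": [0.001, 0.004, 0.009]}, duration=0.010)
        np.testing.assert_array_equal(b.vector("e"), [2, 1])

    def test_empty_train_all_zero(self):
        b = binned_of({"e": []}, duration=0.050)
        assert b.vector("e").sum() == 0 and b.n_bins == 10

    def test_boundary_spike_in_later_bin(self):
        b = binned_of({"e": [0.005]}, duration=0.020)
        np.testing.assert_array_equal(b.vector("e"), [0, 1, 0, 0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_count_sum_preserved(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10.0, size=rng.integers(0, 200)))
        b = binned_of({"e": t}, duration=10.0)
        assert b.vector("e").sum() == len(t)
        assert b.n_bins == 2000


class TestCrossCorrelate:
    def test_identity_pair_unit_at_lag_zero(self):
        x = np.random.default_rng(0).poisson(1.0, size=500).astype(float)
        lc = cross_correlate(x, x, 5)
        assert lc.coefs[5] == pytest.approx(1.0)

    def test_shifted_copy_max_at_shift(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(2.0, size=1000).astype(float)
        y = np.roll(x, 2)
        pc = pair_correlation(x, y, bin_ms=5.0, max_lag_bins=5)
        assert pc.lag_bins == 2
        assert pc.delay_ms == 10.0
        assert pc.c_max > 0.99

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlate(np.zeros(10), np.zeros(11), 2)

    def test_degenerate_variance_flagged_zero(self):
        lc = cross_correlate(np.ones(100), np.random.default_rng(2).poisson(1.0, 100), 3)
        assert np.all(lc.coefs == 0.0)
        assert not lc.valid.any()

    def test_matches_bruteforce_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(50, 1000)
            x = rng.poisson(rng.uniform(0.2, 3.0), size=n).astype(float)
            y = rng.poisson(rng.uniform(0.2, 3.0), size=n).astype(float)
            lc = cross_correlate(x, y, 5)
            want = ref_xcorr(x, y, 5)
            for lag, coef in zip(lc.lags, lc.coefs):
                assert coef == pytest.approx(want[int(lag)], rel=1e-12, abs=1e-12)

    def test_cmax_never_below_central_bin(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.poisson(1.0, 400).astype(float)
            y = rng.poisson(1.0, 400).astype(float)
            pc = pair_correlation(x, y, 5.0, 5)
            assert pc.c_max >= pc.c0
            assert -1.0 <= pc.c0 <= 1.0 and -1.0 <= pc.c_max <= 1.0

    def test_tie_breaks_toward_small_then_negative_lag(self):
        lags = np.arange(-2, 3)
        coefs = np.array([0.9, 0.5, 0.3, 0.5, 0.9])
        lc = LagCorrelation(lags=lags, coefs=coefs, valid=np.ones(5, bool))
        assert _extract_pair(lc, 5.0, "a", "b").lag_bins == -2
        coefs2 = np.array([0.9, 0.9, 0.3, 0.9, 0.9])
        lc2 = LagCorrelation(lags=lags, coefs=coefs2, valid=np.ones(5, bool))
        assert _extract_pair(lc2, 5.0, "a", "b").lag_bins == -1


class TestPairwise:
    def test_antisymmetry_of_delay_and_symmetry_of_coefficients(self):
        rng = np.random.default_rng(5)
        t1 = np.sort(rng.uniform(0, 20, 60))
        t2 = np.sort(t1[:40] + 0.012)
        binned = binned_of({"a": t1, "b": t2}, duration=20.0)
        cc = compute_pair_correlations(binned, max_lag_bins=5)
        ab, ba = cc.get("a", "b"), cc.get("b", "a")
        assert ab.delay_ms == -ba.delay_ms
        assert ab.lag_bins == -ba.lag_bins
        assert ab.c0 == ba.c0 and ab.c_max == ba.c_max
        assert ab.lag_bins > 0  # a leads b

    def test_matrix_identical_trains(self):
        t = np.sort(np.random.default_rng(6).uniform(0, 20, 100))
        binned = binned_of({"a": t, "b": t, "s": []}, duration=20.0)
        cm = correlation_matrix(binned)
        i, j = cm.electrode_ids.index("a"), cm.electrode_ids.index("b")
        assert cm.matrix[i, j] == pytest.approx(1.0)
        assert cm.matrix[i, i] == pytest.approx(1.0)
        np.testing.assert_allclose(cm.matrix, cm.matrix.T)

    def test_silent_electrode_zero_row_flagged(self):
        t = np.sort(np.random.default_rng(7).uniform(0, 20, 100))
        binned = binned_of({"a": t, "s": []}, duration=20.0)
        cm = correlation_matrix(binned)
        k = cm.electrode_ids.index("s")
        assert np.all(cm.matrix[k] == 0.0) and np.all(cm.matrix[:, k] == 0.0)
        assert cm.degenerate == {"s"}

    def test_matrix_ordered_by_compartment(self, layout):
        rng = np.random.default_rng(8)
        ids = ["64", "14", "34"]  # long, somatic, short
        binned = binned_of(
            {e: np.sort(rng.uniform(0, 10, 50)) for e in ids}, duration=10.0
        )
        cm = correlation_matrix(binned, layout=layout)
        assert cm.electrode_ids == ["14", "34", "64"]


class TestSurrogates:
    def test_exact_shifted_copy_minimal_p(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 20.0, 200))
        y = x + 0.010  # +2 bins at 5 ms
        test = significance_by_surrogates(x, y, duration=20.5, n_surrogates=199, seed=1)
        assert test.defined
        assert test.observed.lag_bins == 2
        assert test.p_cmax == pytest.approx(1.0 / 200.0)

    def test_sparse_train_undefined(self):
        test = significance_by_surrogates(
            np.array([]), np.array([1.0, 2.0]), duration=10.0, n_surrogates=100, seed=0
        )
        assert not test.defined and np.isnan(test.p_cmax)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            significance_by_surrogates(
                np.array([1.0, 2.0]), np.array([1.0, 2.0]), 10.0, n_surrogates=10
            )

    def test_independent_pair_not_significant_mostly(self):
        rng = np.random.default_rng(10)
        hits = 0
        for k in range(20):
            x = np.sort(rng.uniform(0, 20.0, 60))
            y = np.sort(rng.uniform(0, 20.0, 60))
            t = significance_by_surrogates(x, y, 20.0, n_surrogates=199, seed=k)
            hits += t.p_cmax < 0.01
        assert hits <= 1
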