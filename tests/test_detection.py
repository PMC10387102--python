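import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfnet.detection import (
    SpikeTrainSet,
    active_electrodes,
    detect_spikes,
    extract_cutouts,
    mad,
    mean_firing_rate,
)
from mfnet.geometry import build_default_layout
from mfnet.preprocess import preprocess
from mfnet.synthetic import SourceSpec, simulate_recording

from _reference import ref_detect, ref_mad
from conftest import as_filtered


class TestMad:
    def test_normal_consistency(self):
        x = np.random.default_rng(0).normal(scale=3.0, size=100_000)
        assert mad(x) == pytest.approx(3.0, rel=0.02)
        assert mad(x, statistic="mean") == pytest.approx(3.0, rel=0.02)

    def test_raw_scale_is_plain_median_deviation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert mad(x, scale="raw") == np.median(np.abs(x - np.median(x)))

    def test_matches_reference(self):
        x = np.random.default_rng(1).normal(size=500)
        for statistic in ("median", "mean"):
            for scale in ("normal", "raw"):
                assert mad(x, statistic, scale) == pytest.approx(
                    ref_mad(x, statistic, scale), rel=1e-12
                )


def _ramp_baseline(n):
    """Deterministic sub-threshold baseline: raw MAD ~= 1 uV, median ~= 0,
    and both statistics stay put when a few samples are overwritten."""
    return np.linspace(-2.0, 2.0, n)


class TestDetectSpikes:
    def test_dead_time_suppresses_second_deflection(self):
        x = _ramp_baseline(5000)
        fs = 10_000.0
        for i in (1000, 1010):  # two -15 uV deflections 1 ms apart
            x[i : i + 4] = -15.0
        rec = as_filtered(x, fs)
        trains = detect_spikes(rec, k_mad=5.0, dead_time_ms=3.0, settle_ms=0.0,
                               mad_scale="raw")
        t = trains.trains["ch0"]
        assert len(t) == 1
        assert t[0] == pytest.approx(0.1, abs=1e-4)
        assert trains.polarities["ch0"] == -1

    def test_deflections_beyond_dead_time_both_kept(self):
        x = _ramp_baseline(5000)
        for i in (1000, 1040):  # 4 ms apart > 3 ms dead time
            x[i : i + 4] = -15.0
        trains = detect_spikes(as_filtered(x), k_mad=5.0, dead_time_ms=3.0,
                               settle_ms=0.0, mad_scale="raw")
        assert len(trains.trains["ch0"]) == 2

    def test_positive_polarity_selected_from_first_crossing(self):
        x = _ramp_baseline(5000)
        x[500 : 504] = 15.0  # positive first
        x[1000 : 1004] = -15.0
        trains = detect_spikes(as_filtered(x), k_mad=5.0, settle_ms=0.0, mad_scale="raw")
        assert trains.polarities["ch0"] == 1
        assert len(trains.trains["ch0"]) == 1  # the negative event is ignored

    def test_zero_trace_flagged_degenerate(self):
        trains = detect_spikes(as_filtered(np.zeros(1000)), settle_ms=0.0)
        assert "ch0" in trains.degenerate
        assert len(trains.trains["ch0"]) == 0

    def test_subthreshold_noise_yields_empty_train(self):
        x = _ramp_baseline(5000)  # never beyond 5 uV at raw MAD ~1
        trains = detect_spikes(as_filtered(x), k_mad=5.0, settle_ms=0.0, mad_scale="raw")
        assert len(trains.trains["ch0"]) == 0

    def test_matches_exhaustive_reference_on_random_traces(self):
        rng = np.random.default_rng(7)
        fs = 10_000.0
        for _ in range(20):
            x = rng.normal(size=3000)
            for i in rng.integers(0, 2950, size=8):
                x[i : i + 4] += rng.choice([-1, 1]) * rng.uniform(5, 20)
            got = detect_spikes(as_filtered(x, fs), settle_ms=0.0)
            want_t, want_thr, want_pol = ref_detect(x, fs)
            np.testing.assert_allclose(got.trains["ch0"], want_t, atol=0)
            assert got.thresholds["ch0"] == pytest.approx(want_thr, rel=1e-12)
            assert got.polarities["ch0"] == want_pol

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_raising_threshold_never_adds_spikes(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=2000)
        x[rng.integers(100, 1900)] -= 15.0
        counts = [
            len(detect_spikes(as_filtered(x), k_mad=k, settle_ms=0.0).trains["ch0"])
            for k in (3.0, 4.0, 5.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_dead_time_invariant_holds_on_output(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20_000)
        trains = detect_spikes(as_filtered(x), k_mad=2.0, dead_time_ms=3.0, settle_ms=0.0)
        isis = np.diff(trains.trains["ch0"])
        assert len(isis) > 0 and isis.min() >= 0.003 * (1 - 1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(as_filtered(np.zeros(100)), k_mad=0.0)


class TestActiveElectrodes:
    def _trains(self, n_spikes, duration=50.0):
        t = np.arange(n_spikes) * 1.0
        return SpikeTrainSet(trains={"e": t}, duration=duration)

    def test_boundary_rate_is_active(self):
        assert active_electrodes(self._trains(5), 0.1) == {"e"}  # 0.1 Hz exactly

    def test_below_boundary_inactive(self):
        assert active_electrodes(self._trains(4), 0.1) == set()  # 0.08 Hz

    def test_empty_train_inactive(self):
        assert active_electrodes(self._trains(0), 0.1) == set()


class TestMeanFiringRate:
    def test_forced_arithmetic(self):
        trains = SpikeTrainSet(
            trains={"a": np.arange(125) * 0.4, "b": np.arange(50) * 1.0},
            duration=50.0,
        )
        rates, mean = mean_firing_rate(trains)
        assert rates["a"] == pytest.approx(2.5)
        assert rates["b"] == pytest.approx(1.0)
        assert mean == pytest.approx(1.75)

    def test_mean_of_two_electrodes(self):
        trains = SpikeTrainSet(
            trains={"a": np.arange(50) * 0.9, "b": np.arange(150) * 0.3},
            duration=50.0,
        )
        _, mean = mean_firing_rate(trains, {"a", "b"})
        assert mean == pytest.approx(2.0)

    def test_empty_subset_gives_none_not_zero(self):
        trains = SpikeTrainSet(trains={"a": np.array([1.0])}, duration=10.0)
        rates, mean = mean_firing_rate(trains, set())
        assert rates == {} and mean is None


@pytest.fixture(scope="module")
def compartment_recording():
    """One electrode with a constant template, one fed by three sources
    of distinct amplitudes (proximal-like variability)."""
    lay = build_default_layout(
        {
            "grid": {"rows": 2, "cols": 2, "pitch_um": 100.0, "excluded": []},
            "compartments": {"somatic_chamber_A": [1, 1], "long_microchannel": [2, 2]},
            "references": {"R1": [1, 2]},
        }
    )
    sources = [
        SourceSpec("axon", "21", baseline_rate=3.0, peak_uv=-100.0, amplitude_jitter=0.02),
        SourceSpec("p1", "11", baseline_rate=1.5, peak_uv=-30.0, amplitude_jitter=0.02),
        SourceSpec("p2", "11", baseline_rate=1.5, peak_uv=-60.0, amplitude_jitter=0.02),
        SourceSpec("p3", "11", baseline_rate=1.5, peak_uv=-100.0, amplitude_jitter=0.02),
    ]
    rec, _ = simulate_recording(lay, sources, [], noise_sd=1.0, duration=60.0, seed=21)
    filt = preprocess(rec, lay)
    trains = detect_spikes(filt)
    return filt, trains


class TestCutouts:

    def test_axonal_electrode_low_amplitude_cv(self, compartment_recording):
        filt, trains = compartment_recording
        cuts = extract_cutouts(filt, trains)
        assert cuts.amplitude_cv("21") < 0.05

    def test_proximal_electrode_high_amplitude_cv(self, compartment_recording):
        filt, trains = compartment_recording
        cuts = extract_cutouts(filt, trains)
        assert cuts.amplitude_cv("11") > 0.2

    def test_single_spike_cv_zero(self):
        x = _ramp_baseline(5000)
        x[2000 : 2004] = -15.0
        rec = as_filtered(x)
        trains = detect_spikes(rec, settle_ms=0.0, mad_scale="raw")
        cuts = extract_cutouts(rec, trains)
        assert len(cuts.cutouts["ch0"]) == 1
        assert cuts.amplitude_cv("ch0") == 0.0

    def test_boundary_window_flagged_and_excluded(self):
        x = _ramp_baseline(1000)
        x[2 : 6] = -15.0  # too close to the start for a 1 ms pre-window
        x[500 : 504] = -15.0
        rec = as_filtered(x)
        trains = detect_spikes(rec, settle_ms=0.0, mad_scale="raw")
        cuts = extract_cutouts(rec, trains, pre_ms=1.0, post_ms=2.0)
        assert cuts.clipped["ch0"] == 1
        assert len(cuts.cutouts["ch0"]) == 1
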