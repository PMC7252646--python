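"""Connectivity pipeline: filter, phase, speed, phasor distance, threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eigenlock as el
from eigenlock.connectivity import WindowSpec, edge_margin

FS = 1000.0


def tone(freq, n=6000, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return np.cos(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_in_band_tone_passes(self):
        x = tone(10.0)
        y = el.bandpass_filter(x, (8.0, 12.0), FS)[0]
        core = slice(1000, 5000)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_rejected(self):
        x = tone(30.0)
        y = el.bandpass_filter(x, (8.0, 12.0), FS)[0]
        assert np.abs(y[1000:5000]).max() < 0.01

    def test_dc_rejected(self):
        # Hamming stopband: DC leakage below ~-53 dB of the input level
        y = el.bandpass_filter(np.ones(6000), (8.0, 12.0), FS)[0]
        assert np.abs(y[1000:5000]).max() < 5e-3

    def test_band_edge_validation(self):
        with pytest.raises(ValueError):
            el.bandpass_filter(tone(10.0), (8.0, 600.0), FS)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="too short"):
            el.bandpass_filter(tone(10.0, n=100), (8.0, 12.0), FS)

    def test_edge_margin_covers_group_delay(self):
        m = edge_margin((8.0, 12.0), FS)
        assert m >= 825 // 2  # at least half the filter length


class TestPhaseAndSpeed:
    def test_pure_cosine_phase_slope(self):
        phase = el.instantaneous_phase(tone(10.0))[0]
        slope = np.diff(phase[1000:5000])
        assert np.allclose(slope, 2 * np.pi * 10.0 / FS, atol=1e-4)

    def test_quadrature_pair_offset(self):
        x = np.vstack([tone(10.0), tone(10.0, phase=-np.pi / 2)])  # cos, sin
        phases = el.instantaneous_phase(x)
        offset = phases[0, 1000:5000] - phases[1, 1000:5000]
        assert np.allclose(offset, np.pi / 2, atol=1e-3)

    def test_phase_monotone_for_positive_tone(self):
        phase = el.instantaneous_phase(tone(25.0))[0]
        assert np.all(np.diff(phase[1000:5000]) > 0)

    def test_constant_channel_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            el.instantaneous_phase(np.zeros(100))

    def test_angular_speed_hand_examples(self):
        assert np.allclose(el.angular_speed(np.array([0.0, 0.1, 0.3]))[0],
                           [0.1, 0.2])
        ramp = 0.05 * np.arange(50)
        assert np.allclose(el.angular_speed(ramp)[0], 0.05)

    def test_angular_speed_output_length(self):
        assert el.angular_speed(np.zeros((3, 17))).shape == (3, 16)
        with pytest.raises(ValueError):
            el.angular_speed(np.array([1.0]))

    def test_wrapped_phase_warns(self):
        wrapped = np.angle(np.exp(1j * 0.5 * np.arange(40)))  # not unwrapped
        with pytest.warns(RuntimeWarning, match="unwrapped"):
            el.angular_speed(wrapped)


class TestWindowedDistance:
    window = WindowSpec(width=40, step=5, fs=FS)

    def test_identical_rows_give_zero(self):
        speeds = np.tile(0.03 * np.ones(200), (3, 1))
        d = el.windowed_plv_distance(speeds, self.window)
        assert np.all(d.distances == 0.0)

    def test_constant_gap_closed_form(self):
        delta = 2 * np.pi * 2.0 / FS  # a 2 Hz speed gap at 1 kHz
        speeds = np.vstack([np.zeros(100), np.full(100, delta)])
        d = el.windowed_plv_distance(speeds, self.window)
        expected = 2 * np.sin(delta / 2) * np.sqrt(40)
        assert np.allclose(d.distances[:, 0, 1], expected, rtol=1e-12)
        assert expected == pytest.approx(0.0795, abs=2e-4)

    def test_speed_mode_matches_phasor_to_first_order(self):
        rng = np.random.default_rng(0)
        speeds = 0.02 * rng.standard_normal((4, 300))
        dp = el.windowed_plv_distance(speeds, self.window, mode="phasor")
        ds = el.windowed_plv_distance(speeds, self.window, mode="speed")
        # all |speed gaps| < 0.05: phasor linearization within 0.1%
        assert np.allclose(dp.distances, ds.distances, rtol=1e-3)

    def test_metric_properties(self, rng):
        speeds = rng.uniform(-0.2, 0.2, size=(5, 120))
        d = el.windowed_plv_distance(speeds, self.window).distances
        assert np.allclose(d, d.transpose(0, 2, 1))
        assert np.all(d >= 0)
        for k in range(d.shape[0]):  # triangle inequality
            for i in range(5):
                for j in range(5):
                    for m in range(5):
                        assert d[k, i, j] <= d[k, i, m] + d[k, m, j] + 1e-12

    def test_window_too_long_raises(self):
        with pytest.raises(ValueError, match="fits no window"):
            el.windowed_plv_distance(np.zeros((2, 30)), self.window)

    @given(length=st.integers(41, 400), width=st.integers(2, 40),
           step=st.integers(1, 40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_closed_form(self, length, width, step):
        step = min(step, width)
        w = WindowSpec(width=width, step=step, fs=FS)
        d = el.windowed_plv_distance(np.zeros((2, length)), w)
        assert d.n_windows == (length - width) // step + 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_straddle_split_is_pythagorean(self, seed):
        # d^2 over a window equals the sum of sub-window d^2 for any split
        rng = np.random.default_rng(seed)
        speeds = rng.uniform(-np.pi / 2, np.pi / 2, size=(2, 40))
        cut = int(rng.integers(1, 40))
        full = el.windowed_plv_distance(speeds, WindowSpec(40, 40, FS))
        a = el.windowed_plv_distance(speeds[:, :cut],
                                     WindowSpec(max(cut, 2), max(cut, 2), FS)) \
            if cut >= 2 else None
        d2 = full.distances[0, 0, 1] ** 2
        z = np.exp(1j * speeds)
        d2a = np.sum(np.abs(z[0, :cut] - z[1, :cut]) ** 2)
        d2b = np.sum(np.abs(z[0, cut:] - z[1, cut:]) ** 2)
        assert d2 == pytest.approx(d2a + d2b, rel=1e-12)
        if a is not None:
            assert a.distances[0, 0, 1] ** 2 == pytest.approx(d2a, rel=1e-12)


class TestPhaseCoherence:
    window = WindowSpec(width=40, step=5, fs=FS)

    def test_constant_phase_difference_gives_one(self):
        phases = np.vstack([0.01 * np.arange(100), 0.01 * np.arange(100) + 1.3])
        c = el.phase_coherence(phases, self.window)
        assert np.allclose(c[:, 0, 1], 1.0)

    def test_full_cycle_sweep_vanishes(self):
        # phase difference sweeps exactly one full cycle across the window
        diff = 2 * np.pi * np.arange(40) / 40
        phases = np.vstack([np.zeros(40), diff])
        c = el.phase_coherence(phases, WindowSpec(40, 40, FS))
        assert c[0, 0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        phases = rng.uniform(0, 20, size=(4, 200))
        c = el.phase_coherence(phases, self.window)
        assert np.all((c >= 0) & (c <= 1))


class TestBinarize:
    def test_zero_distances_give_complete_graph(self):
        speeds = np.zeros((4, 60))
        nets = el.binarize(el.windowed_plv_distance(speeds, WindowSpec(40, 5, FS)),
                           1e-6)
        expected = 1 - np.eye(4)
        assert np.all(nets.adjacency == expected.astype(bool))

    def test_threshold_is_strict(self):
        d = el.DistanceMatrixSeries(
            distances=np.array([[[0.0, 0.5], [0.5, 0.0]]]),
            window_starts=np.array([0]), window=WindowSpec(40, 5, FS),
            channel_names=["a", "b"])
        assert not el.binarize(d, 0.5).adjacency[0, 0, 1]  # tie -> non-edge
        assert el.binarize(d, np.nextafter(0.5, 1)).adjacency[0, 0, 1]

    def test_threshold_below_min_distance_gives_empty_graph(self):
        rng = np.random.default_rng(1)
        speeds = rng.uniform(0.1, 0.5, size=(3, 60))
        dm = el.windowed_plv_distance(speeds, WindowSpec(40, 5, FS))
        nets = el.binarize(dm, dm.distances[dm.distances > 0].min() / 2)
        assert not nets.adjacency.any()

    def test_nonpositive_threshold_rejected(self):
        speeds = np.zeros((2, 60))
        dm = el.windowed_plv_distance(speeds, WindowSpec(40, 5, FS))
        with pytest.raises(ValueError):
            el.binarize(dm, 0.0)

    def test_scenario1_zero_noise_recovers_two_cliques(self, scenario1_run):
        _, _, networks = scenario1_run
        # window 100 lies fully inside the initial two-cluster segment
        a = networks.adjacency[100].astype(int)
        block1, block2 = np.ix_(range(3), range(3)), np.ix_(range(3, 8), range(3, 8))
        assert np.array_equal(a[block1], np.ones((3, 3), int) - np.eye(3, dtype=int))
        assert np.array_equal(a[block2], np.ones((5, 5), int) - np.eye(5, dtype=int))
        assert a[np.ix_(range(3), range(3, 8))].sum() == 0
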