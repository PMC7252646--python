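"""Prime-eigenvector extraction and meta-stable-state dynamics."""

import itertools

import numpy as np
import pytest

import eigenlock as el
from eigenlock.connectivity import BinaryNetworkSeries, WindowSpec
from eigenlock.eigendynamics import (
    EigenvectorSeries,
    InnerProductSeries,
    prime_eigenvector,
)
from conftest import random_adjacency


def clique_adjacency(n, members):
    a = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(members, 2):
        a[i, j] = a[j, i] = 1
    return a


def series_from(matrices, starts=None):
    mats = np.array(matrices, dtype=bool)
    n_w = mats.shape[0]
    starts = np.arange(n_w) if starts is None else np.asarray(starts)
    nets = BinaryNetworkSeries(adjacency=mats, threshold=1.0,
                               window_starts=starts,
                               window=WindowSpec(40, 1, 1000.0),
                               channel_names=[f"c{i}" for i in range(mats.shape[1])])
    return el.prime_eigenvector_series(nets)


def ip_series(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(len(values), bool) if valid is None else np.asarray(valid)
    return InnerProductSeries(values=values, valid=valid,
                              window_starts=np.arange(1, len(values) + 1))


class TestPrimeEigenvector:
    def test_five_clique_analytic_perron_vector(self):
        a = clique_adjacency(8, range(3, 8))
        pe = prime_eigenvector(a)
        assert pe.valid
        assert pe.eigenvalue == pytest.approx(4.0)
        expected = np.zeros(8)
        expected[3:] = 1 / np.sqrt(5)
        assert np.allclose(pe.vector, expected)

    def test_edgeless_graph_is_invalid(self):
        pe = prime_eigenvector(np.zeros((6, 6), dtype=int))
        assert not pe.valid
        assert np.all(pe.vector == 0)

    def test_two_cliques_supported_on_larger(self):
        a = clique_adjacency(8, range(3)) + clique_adjacency(8, range(3, 8))
        pe = prime_eigenvector(a)
        assert set(np.flatnonzero(pe.vector)) == set(range(3, 8))

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            prime_eigenvector(a)

    def test_degenerate_tie_broken_by_previous(self):
        a = clique_adjacency(8, range(4)) + clique_adjacency(8, range(4, 8))
        prev = np.zeros(8)
        prev[4:] = 0.5
        pe = prime_eigenvector(a, previous=prev)
        assert set(np.flatnonzero(pe.vector)) == set(range(4, 8))
        # without a previous vector, the lowest-index component wins
        pe0 = prime_eigenvector(a)
        assert set(np.flatnonzero(pe0.vector)) == set(range(4))

    def test_identical_consecutive_windows_give_inner_product_one(self):
        a = clique_adjacency(8, range(4)) + clique_adjacency(8, range(4, 8))
        es = series_from([a, a, a])
        ip = el.successive_inner_products(es)
        assert np.all(ip.values == 1.0)

    def test_nonnegative_orientation_on_random_graphs(self, rng):
        for _ in range(50):
            a = random_adjacency(rng, int(rng.integers(2, 10)))
            pe = prime_eigenvector(a)
            if pe.valid:
                assert np.all(pe.vector >= 0)
                assert np.linalg.norm(pe.vector) == pytest.approx(1.0)

    def test_clique_union_overlap_formula_small_graphs(self):
        # uniform Perron vectors: overlap = |A&B| / sqrt(|A| |B|)
        n = 6
        for size_a, size_b in [(3, 3), (3, 4), (4, 4), (2, 5)]:
            for shift in range(n - size_b + 1):
                a_nodes = frozenset(range(size_a))
                b_nodes = frozenset(range(shift, shift + size_b))
                va = prime_eigenvector(clique_adjacency(n, a_nodes)).vector
                vb = prime_eigenvector(clique_adjacency(n, b_nodes)).vector
                expected = len(a_nodes & b_nodes) / np.sqrt(size_a * size_b)
                assert float(va @ vb) == pytest.approx(expected)


class TestInnerProducts:
    def test_orthogonal_supports_give_zero(self):
        a1 = clique_adjacency(8, range(3))
        a2 = clique_adjacency(8, range(3, 8))
        es = series_from([a1, a2])
        assert el.successive_inner_products(es).values[0] == 0.0

    def test_shrinking_cluster_overlap(self):
        # a 12-set shrinking to an interior 7-subset: sqrt(7/12)
        big = clique_adjacency(15, range(3, 15))
        small = clique_adjacency(15, range(8, 15))
        es = series_from([big, small])
        assert el.successive_inner_products(es).values[0] == pytest.approx(
            np.sqrt(7 / 12))

    def test_pairs_with_invalid_windows_flagged(self):
        a = clique_adjacency(4, range(3))
        es = series_from([a, np.zeros((4, 4), int), a])
        ip = el.successive_inner_products(es)
        assert not ip.valid[0] and not ip.valid[1]
        assert np.isnan(ip.values[0])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            el.successive_inner_products(series_from([clique_adjacency(4, range(3))]))


class TestEvents:
    def test_direct_count(self):
        summary = el.count_events(ip_series([1.0, 1.0, 1.0, 0.0]))
        assert summary.n_event1 == 3 and summary.n_event0 == 1
        assert summary.freq_event1 == 0.75 and summary.freq_event0 == 0.25

    def test_mid_band_counts_nothing(self):
        summary = el.count_events(ip_series([0.5, 0.5, 0.5]))
        assert summary.n_event0 == summary.n_event1 == 0

    def test_invalid_pairs_excluded_from_denominator(self):
        summary = el.count_events(ip_series([1.0, np.nan, 0.0],
                                            valid=[True, False, True]))
        assert summary.n_valid == 2
        assert summary.freq_event0 == 0.5

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            el.count_events(ip_series([1.0, 0.5]), lo=0.5, hi=0.5)

    def test_scenario1_plateaus_dominate(self, scenario1_run):
        _, _, networks = scenario1_run
        summary = el.LeadingEigenvectorDynamics().events(networks)
        assert summary.freq_event1 > 0.9 > 0.1 > summary.freq_event0


class TestSpikes:
    def test_flat_series_has_no_spikes(self):
        assert el.detect_spikes(ip_series(np.ones(50))) == []

    def test_single_dip_reported_at_minimum(self):
        vals = np.ones(20)
        vals[7:10] = [0.97, 0.4, 0.97]
        spikes = el.detect_spikes(ip_series(vals))
        assert len(spikes) == 1
        assert spikes[0].pair_index == 8
        assert spikes[0].minimum == pytest.approx(0.4)
        assert spikes[0].depth == pytest.approx(0.6)

    def test_shallow_excursions_ignored(self):
        vals = np.ones(20)
        vals[5] = 0.96  # below plateau but above the spike level
        assert el.detect_spikes(ip_series(vals)) == []

    def test_adjacent_dips_need_plateau_between(self):
        vals = np.ones(20)
        vals[5:8] = [0.2, 0.95, 0.3]  # one excursion, two local minima
        assert len(el.detect_spikes(ip_series(vals))) == 1
        vals[6] = 0.995  # back at plateau: now two spikes
        assert len(el.detect_spikes(ip_series(vals))) == 2

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            el.detect_spikes(ip_series([1.0]), plateau_level=0.5, spike_level=0.9)


class TestRecurrence:
    def test_diagonal_one_for_valid_windows(self):
        a = clique_adjacency(5, range(3))
        r = el.recurrence_matrix(series_from([a, a, a]))
        assert np.allclose(np.diag(r), 1.0)

    def test_alternating_orthogonal_vectors_checkerboard(self):
        a1, a2 = clique_adjacency(6, range(3)), clique_adjacency(6, range(3, 6))
        r = el.recurrence_matrix(series_from([a1, a2, a1, a2]))
        expected = np.array([[1, 0, 1, 0], [0, 1, 0, 1],
                             [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        assert np.allclose(r, expected)

    def test_scenario_block_structure(self, scenario1_run):
        _, _, networks = scenario1_run
        es = el.prime_eigenvector_series(networks)
        r = el.recurrence_matrix(es, (100, 900))
        # windows 0-300 (steps 100-400): pre-merge plateau; 500-: merged
        assert np.allclose(r[:300, :300], 1.0)
        assert np.allclose(r[500:, 500:], 1.0)
        assert np.allclose(r[:300, 500:], np.sqrt(5 / 8))

    def test_empty_range_rejected(self):
        a = clique_adjacency(4, range(3))
        with pytest.raises(ValueError):
            el.recurrence_matrix(series_from([a, a]), (2, 2))


class TestSegmentation:
    def test_constant_series_single_state(self):
        a = clique_adjacency(5, range(4))
        seg = el.segment_states(series_from([a] * 10))
        assert len(seg.segments) == 1
        assert seg.segments[0].n_windows == 10

    def test_durations_partition_valid_windows(self, scenario2_run):
        _, _, networks = scenario2_run
        es = el.prime_eigenvector_series(networks)
        seg = el.segment_states(es)
        assert seg.durations().sum() == int(es.valid.sum())

    def test_scenario1_three_states_at_transitions(self, scenario1_run):
        _, _, networks = scenario1_run
        es = el.prime_eigenvector_series(networks)
        seg = el.segment_states(es)
        assert len(seg.segments) == 3
        bounds = [s.start for s in seg.segments[1:]]
        starts = networks.window_starts
        assert abs(starts[bounds[0]] - 500) <= 40
        assert abs(starts[bounds[1]] - 1500) <= 40


class TestAccumulatedFrequency:
    def test_running_ratio(self):
        acc0, acc1 = el.accumulated_event_frequency(ip_series([1, 1, 0, 1]))
        assert np.allclose(acc1, [1, 1, 2 / 3, 3 / 4])
        assert np.allclose(acc0, [0, 0, 1 / 3, 1 / 4])

    def test_final_value_matches_event_summary(self, scenario1_run):
        _, _, networks = scenario1_run
        ip = el.LeadingEigenvectorDynamics().transform(networks)
        acc0, acc1 = el.accumulated_event_frequency(ip)
        summary = el.count_events(ip)
        assert acc0[-1] == pytest.approx(summary.freq_event0)
        assert acc1[-1] == pytest.approx(summary.freq_event1)

    def test_saturated_series_constant_one(self):
        _, acc1 = el.accumulated_event_frequency(ip_series(np.ones(9)))
        assert np.all(acc1 == 1.0)
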