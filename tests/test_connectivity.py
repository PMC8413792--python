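"""Epoching, Pearson matrices, and the three thresholding schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from fnirs_fc.connectivity import (
    ConnectionMatrix, binarize, correlation_p_value, extract_segments,
    pearson_matrix, threshold_absolute, threshold_cost, threshold_surrogate,
    COST_GRID,
)
from fnirs_fc.montage import EventSchedule, build_default_schedule

FS = 3.9


def random_cm(rng, n=10, n_samples=39):
    x = rng.standard_normal((n_samples, n))
    return pearson_matrix(x)


class TestExtractSegments:
    def test_seven_equal_segments_of_39_samples(self, schedule):
        segs = extract_segments(int(175 * FS), FS, schedule)
        assert len(segs) == 7
        assert all(s.n_samples == 39 for s in segs)  # floor(10 * 3.9)
        assert [s.label for s in segs] == [
            "Rest", "Stim1", "Stim2", "Stim3", "Stim4", "Stim5", "Stim6"]

    def test_rest_window_centred_at_30s(self, schedule):
        rest = extract_segments(int(175 * FS), FS, schedule)[0]
        mid_s = (rest.start + rest.n_samples / 2) / FS
        assert mid_s == pytest.approx(30.0, abs=1.0 / FS)

    def test_stimulus_segments_start_at_onsets(self, schedule):
        segs = extract_segments(int(175 * FS), FS, schedule)
        assert segs[1].start == int(np.floor(60 * FS))
        assert segs[2].start == int(np.floor(80 * FS))

    def test_missing_stimulus_rejected(self):
        partial = EventSchedule(tuple(
            e for e in build_default_schedule().entries if e[0] != "Stim6"))
        with pytest.raises(ValueError, match="Stim6"):
            extract_segments(int(175 * FS), FS, partial)

    def test_recording_too_short_rejected(self, schedule):
        with pytest.raises(ValueError, match="extends past"):
            extract_segments(400, FS, schedule)


class TestPearsonMatrix:
    def test_identical_channels_correlate_fully(self, rng):
        x = rng.standard_normal(39)
        cm = pearson_matrix(np.column_stack([x, x, rng.standard_normal(39)]))
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_negated_channel_anticorrelates(self, rng):
        x = rng.standard_normal(39)
        cm = pearson_matrix(np.column_stack([x, -x]))
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        block = rng.standard_normal((39, 5))
        cm = pearson_matrix(block)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert cm.r[i, j] == 0.0
                    continue
                xi = block[:, i] - block[:, i].mean()
                xj = block[:, j] - block[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cm.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_channel_zeroed_and_flagged(self, rng):
        block = rng.standard_normal((39, 4))
        block[:, 2] = 5.0
        cm = pearson_matrix(block)
        assert cm.zero_variance_channels == (2,)
        assert np.all(cm.r[2] == 0) and np.all(cm.r[:, 2] == 0)

    def test_too_short_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            pearson_matrix(rng.standard_normal((2, 4)))


class TestThresholdAbsolute:
    def test_low_cutoff_keeps_uniform_matrix(self):
        r = np.full((6, 6), 0.5); np.fill_diagonal(r, 0)
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_absolute(cm, 0.15).n_edges == 15

    def test_high_cutoff_empties_uniform_matrix(self):
        r = np.full((6, 6), 0.5); np.fill_diagonal(r, 0)
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_absolute(cm, 0.75).n_edges == 0

    def test_value_equal_to_cutoff_is_kept(self):
        # only coefficients strictly below the cutoff are discarded
        r = np.zeros((3, 3)); r[0, 1] = r[1, 0] = 0.40
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_absolute(cm, 0.40).weights[0, 1] == 0.40


class TestThresholdCost:
    def test_113_edges_at_ten_percent_of_48_nodes(self, rng):
        # round(0.10 * 1128) with all coefficients positive and distinct
        r = np.zeros((48, 48))
        iu = np.triu_indices(48, 1)
        vals = rng.permutation(np.linspace(0.01, 0.99, iu[0].size))
        r[iu] = vals; r = r + r.T
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_cost(cm, 0.10).n_edges == 113

    def test_full_cost_equals_negatives_zeroed(self, rng):
        cm = random_cm(rng)
        net = threshold_cost(cm, 1.0)
        expected = np.where(cm.r > 0, cm.r, 0.0)
        assert np.array_equal(net.weights, expected)

    def test_all_negative_matrix_gives_empty_network(self):
        r = -0.5 * np.ones((5, 5)); np.fill_diagonal(r, 0)
        cm = ConnectionMatrix(r=r, n_samples=39)
        for cost in (0.1, 0.5, 1.0):
            assert threshold_cost(cm, cost).n_edges == 0

    def test_edge_sets_nested_across_grid(self, rng):
        cm = random_cm(rng, n=12)
        prev = None
        for cost in COST_GRID:
            edges = set(zip(*np.nonzero(np.triu(
                threshold_cost(cm, cost).weights, 1))))
            if prev is not None:
                assert prev <= edges
            prev = edges


class TestThresholdSurrogate:
    def test_p_values_match_t_distribution_oracle(self):
        for r, n in ((0.5, 39), (0.2, 39), (0.7, 10)):
            t = r * np.sqrt((n - 2) / (1 - r**2))
            expected = 2 * sstats.t.sf(abs(t), n - 2)
            assert correlation_p_value(r, n) == pytest.approx(expected, rel=1e-12)

    def test_strong_positive_coefficient_retained(self):
        r = np.zeros((3, 3)); r[0, 1] = r[1, 0] = 0.5
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_surrogate(cm).weights[0, 1] == 0.5  # p ~ 0.0012

    def test_weak_coefficient_removed(self):
        r = np.zeros((3, 3)); r[0, 1] = r[1, 0] = 0.2
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_surrogate(cm).weights[0, 1] == 0.0  # p ~ 0.22

    def test_perfect_correlation_retained(self):
        r = np.zeros((3, 3)); r[0, 1] = r[1, 0] = 1.0
        cm = ConnectionMatrix(r=r, n_samples=39)
        assert threshold_surrogate(cm).weights[0, 1] == 1.0

    def test_null_retention_rate_near_alpha_over_two(self, rng):
        # positive-side-only retention halves the two-sided alpha
        kept = 0; total = 0
        for _ in range(60):
            cm = random_cm(rng, n=20, n_samples=39)
            net = threshold_surrogate(cm, 0.05)
            kept += net.n_edges
            total += 20 * 19 // 2
        assert kept / total == pytest.approx(0.025, abs=0.008)

    def test_retention_monotone_in_coefficient(self):
        rs = np.linspace(0.01, 0.99, 50)
        r = np.zeros((3, 3))
        kept = []
        for val in rs:
            r[0, 1] = r[1, 0] = val
            cm = ConnectionMatrix(r=r.copy(), n_samples=39)
            kept.append(threshold_surrogate(cm).weights[0, 1] > 0)
        # once retained, stays retained for larger coefficients
        first = kept.index(True)
        assert all(kept[first:])


class TestBinarize:
    def test_maps_positive_weights_to_one(self):
        w = np.array([[0, 0.3, 0.9], [0.3, 0, 0], [0.9, 0, 0]])
        from fnirs_fc.connectivity import ThresholdedNetwork
        net = ThresholdedNetwork(weights=w, scheme="absolute", parameter=0.15)
        b = binarize(net)
        assert set(np.unique(b.weights)) <= {0.0, 1.0}
        assert b.n_edges == net.n_edges

    def test_idempotent(self, rng):
        net = threshold_cost(random_cm(rng), 0.5)
        once = binarize(net)
        twice = binarize(once)
        assert np.array_equal(once.weights, twice.weights)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.sampled_from(["absolute", "cost", "surrogate"]))
def test_thresholding_contracts(seed, scheme):
    """No scheme increases entries, breaks symmetry, or keeps negatives."""
    rng = np.random.default_rng(seed)
    cm = random_cm(rng, n=8)
    if scheme == "absolute":
        net = threshold_absolute(cm, 0.3)
    elif scheme == "cost":
        net = threshold_cost(cm, 0.4)
    else:
        net = threshold_surrogate(cm, 0.05)
    assert np.all(net.weights >= 0)
    assert np.array_equal(net.weights, net.weights.T)
    assert np.all(net.weights <= np.maximum(cm.r, 0) + 1e-15)
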