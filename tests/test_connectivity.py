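"""Cross-correlogram construction, jitter surrogates, connection calls, and
connection-probability summaries."""

import numpy as np
import pandas as pd
import pytest

from acephys import connectivity as conn
from acephys.types import LAYERS, SpikeTrain


def _train(times, uid=0, **kw):
    return SpikeTrain(unit_id=uid, spike_times=np.asarray(times, float), **kw)


class TestComputeCcg:
    def test_pure_shift_concentrates_in_one_bin(self):
        origin = np.arange(1.0, 100.0, 0.5)
        target = origin + 0.002
        lags, counts = conn.compute_ccg(origin, target, bin_ms=1.0, max_lag_ms=10.0)
        assert counts[lags == 2.0][0] == origin.size
        assert counts.sum() == origin.size

    def test_independent_poisson_flat_at_product_level(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 600, 3000))
        b = np.sort(rng.uniform(0, 600, 3000))
        lags, counts = conn.compute_ccg(a, b, max_lag_ms=50.0)
        expected = 5.0 * 5.0 * 0.001 * 600.0       # rate*rate*bin*duration = 15
        assert counts.mean() == pytest.approx(expected, rel=0.1)
        assert counts.max() < expected + 6 * np.sqrt(expected)

    def test_mirror_symmetry_between_directions(self):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 60, 400))
        b = np.sort(rng.uniform(0, 60, 300))
        _, ab = conn.compute_ccg(a, b, max_lag_ms=20.0)
        _, ba = conn.compute_ccg(b, a, max_lag_ms=20.0)
        np.testing.assert_array_equal(ab, ba[::-1])

    def test_empty_train_errors(self):
        with pytest.raises(ValueError):
            conn.compute_ccg(np.array([]), np.array([1.0]))

    def test_bin_must_divide_max_lag(self):
        with pytest.raises(ValueError):
            conn.compute_ccg(np.array([1.0]), np.array([2.0]), bin_ms=3.0, max_lag_ms=10.0)


class TestJitter:
    def test_count_conserved_and_bounded(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 100, 2000))
        j = conn.jitter_spike_train(t, 3.0, rng=np.random.default_rng(3))
        assert j.size == t.size
        assert np.all(np.diff(j) >= 0)
        assert np.abs(np.sort(j) - np.sort(t)).max() <= 0.006 + 1e-9

    def test_mean_displacement_near_zero(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 1000, 20000))
        j = conn.jitter_spike_train(t, 3.0, rng=np.random.default_rng(5))
        # uniform(+/-3 ms): SE of the mean = 3e-3/sqrt(3 n)
        se = 3e-3 / np.sqrt(3 * t.size)
        assert abs((j.sum() - t.sum()) / t.size) < 4 * se

    def test_deterministic_under_seed(self):
        t = np.linspace(0, 10, 100)
        a = conn.jitter_spike_train(t, 3.0, seed=11)
        b = conn.jitter_spike_train(t, 3.0, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_half_width_rejected(self):
        with pytest.raises(ValueError):
            conn.jitter_spike_train(np.array([1.0]), 0.0)


class TestSurrogateBands:
    def test_same_seed_identical_bands(self, unconnected_pair):
        o, t = (tr.spike_times for tr in unconnected_pair)
        u1, l1 = conn.surrogate_bands(o, t, n_surrogates=100, seed=7, max_lag_ms=10)
        u2, l2 = conn.surrogate_bands(o, t, n_surrogates=100, seed=7, max_lag_ms=10)
        np.testing.assert_array_equal(u1, u2)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_surrogates_error(self):
        with pytest.raises(ValueError):
            conn.surrogate_bands(np.array([1.0]), np.array([2.0]), n_surrogates=50)

    def test_observed_mostly_inside_band_for_independent_trains(self, unconnected_pair):
        o, t = (tr.spike_times for tr in unconnected_pair)
        lags, counts = conn.compute_ccg(o, t, max_lag_ms=50)
        upper, lower = conn.surrogate_bands(o, t, n_surrogates=200, seed=9, max_lag_ms=50)
        inside = np.mean((counts <= upper) & (counts >= lower))
        assert inside >= 0.9
        assert np.all(lower <= upper) and np.all(lower >= 0)


class TestClassifyConnection:
    def test_planted_excitatory_called(self, excitatory_pair):
        r = conn.analyze_pair(*excitatory_pair, seed=1, max_lag_ms=10)
        assert r.call == "excitatory"
        assert 0.0 <= r.first_significant_lag_ms <= 3.0

    def test_planted_inhibitory_called(self, inhibitory_pair):
        r = conn.analyze_pair(*inhibitory_pair, seed=2, max_lag_ms=10)
        assert r.call == "inhibitory"

    def test_independent_pair_mostly_none(self, unconnected_pair):
        r = conn.analyze_pair(*unconnected_pair, seed=3, max_lag_ms=10)
        assert r.call == "none" and np.isnan(r.first_significant_lag_ms)

    def test_excitatory_precedence_on_dual_crossing(self):
        lags = np.arange(-5.0, 6.0)
        counts = np.full(lags.size, 10)
        counts[lags == 1.0] = 30      # above band
        counts[lags == 2.0] = 0       # below band
        r = conn.CCGResult(0, 1, lags, counts, np.full(lags.size, 20.0),
                           np.full(lags.size, 5.0))
        r = conn.classify_connection(r)
        assert r.call == "excitatory"
        assert r.first_significant_lag_ms == 1.0

    def test_negative_lag_crossing_reported_as_reverse(self):
        lags = np.arange(-5.0, 6.0)
        counts = np.full(lags.size, 10)
        counts[lags == -2.0] = 30
        r = conn.CCGResult(0, 1, lags, counts, np.full(lags.size, 20.0),
                           np.full(lags.size, 5.0))
        r = conn.classify_connection(r)
        assert r.call == "none"
        assert r.reverse_call == "excitatory"

    def test_grid_mismatch_errors(self):
        r = conn.CCGResult(0, 1, np.arange(3.0), np.zeros(3), np.zeros(2), np.zeros(3))
        with pytest.raises(ValueError):
            conn.classify_connection(r)


class TestProbabilities:
    def _calls(self):
        ids = [0, 1, 2, 3, 4]
        calls = pd.DataFrame("none", index=ids, columns=ids, dtype=object)
        np.fill_diagonal(calls.values, np.nan)
        calls.loc[0, 1] = "excitatory"
        calls.loc[0, 2] = "excitatory"
        calls.loc[3, 4] = "inhibitory"
        return calls

    def test_counting(self):
        calls = self._calls()
        assert conn.connection_probability(calls, 0, [1, 2, 3, 4]) == pytest.approx(0.5)
        assert conn.connection_probability(calls, 1, [0, 2, 3, 4]) == 0.0
        assert conn.connection_probability(calls, 3, [4], kind="inhibitory") == 1.0
        assert np.isnan(conn.connection_probability(calls, 0, [0]))

    def test_per_neuron_table_and_summary(self):
        calls = self._calls()
        meta = pd.DataFrame({
            "cell_type": ["BS"] * 5,
            "layer": ["L_d1", "L_d2", "L_d2", "L_sup", "L_in"],
        }, index=[0, 1, 2, 3, 4])
        table = conn.per_neuron_connection_table(calls, meta, kind="excitatory")
        table["group"] = "control"
        d1_to_d2 = table[(table["origin_layer"] == "L_d1") & (table["target_layer"] == "L_d2")]
        assert d1_to_d2[d1_to_d2["origin_id"] == 0]["probability"].iloc[0] == 1.0
        summary = conn.laminar_connectivity_summary(table)
        mat = summary[("BS", "BS")]["control"]
        assert mat.loc["L_d1", "L_d2"] == 1.0
        # cells with no contributing neurons stay missing, not zero
        assert np.isnan(mat.loc["L_d2", "L_sup"]) or mat.loc["L_d2", "L_sup"] == 0.0

    def test_uniform_probability_fills_cells(self):
        rows = []
        for ol in LAYERS:
            for tl in LAYERS:
                for k in range(3):
                    rows.append({"origin_id": k, "origin_type": "BS",
                                 "origin_layer": ol, "target_type": "BS",
                                 "target_layer": tl, "probability": 0.25,
                                 "group": "treated"})
        summary = conn.laminar_connectivity_summary(pd.DataFrame(rows))
        mat = summary[("BS", "BS")]["treated"]
        assert (mat.to_numpy() == 0.25).all()

    def test_matrix_requires_two_units(self):
        with pytest.raises(ValueError):
            conn.connectivity_matrix([_train([1.0])])
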