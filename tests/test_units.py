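"""Unit-level measures: classification, quality metrics, firing-rate and
latency estimators."""

import numpy as np
import pandas as pd
import pytest

from acephys import synth, units
from acephys.types import EvokedSpec, QualityMetrics, SpikeTrain, UnitSpec


def _train(times, uid=0, **kw):
    return SpikeTrain(unit_id=uid, spike_times=np.asarray(times, float), **kw)


class TestCellType:
    @pytest.mark.parametrize("ttp,expected", [(0.3, "NS"), (0.8, "BS"), (0.5, "BS")])
    def test_split_at_half_millisecond(self, ttp, expected):
        assert units.classify_cell_type(ttp) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            units.classify_cell_type(np.nan)

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        ttps = rng.uniform(0.1, 1.5, 200)
        labels = [units.classify_cell_type(t) for t in ttps]
        assert sum(l == "BS" for l in labels) + sum(l == "NS" for l in labels) == 200


class TestQualityFilters:
    def _unit(self, uid=0, **q):
        return _train([0.0, 1.0], uid=uid, quality=QualityMetrics(**q))

    def test_silicon_keep_and_drop(self):
        good = self._unit(0, isolation_distance=25, overall_rate_hz=1.0)
        bad = self._unit(1, isolation_distance=19.9, overall_rate_hz=1.0)
        kept, log = units.apply_quality_filters([good, bad], "silicon")
        assert [u.unit_id for u in kept] == [0]
        assert "isolation_distance" in log.iloc[0]["reason"]

    def test_neuropixels_contamination_rule(self):
        bad = self._unit(2, rp_contamination=0.12, noise_cutoff_sd=1.0,
                         low_bin_fraction=0.01, overall_rate_hz=1.0)
        kept, log = units.apply_quality_filters([bad], "neuropixels")
        assert not kept and "contamination" in log.iloc[0]["reason"]

    def test_missing_metric_excludes_with_reason(self):
        u = self._unit(3, isolation_distance=None, overall_rate_hz=1.0)
        kept, log = units.apply_quality_filters([u], "silicon")
        assert not kept and "missing metric" in log.iloc[0]["reason"]

    def test_filter_monotone_in_each_metric(self):
        base = dict(rp_contamination=0.05, noise_cutoff_sd=2.0,
                    low_bin_fraction=0.05, overall_rate_hz=1.0)
        kept, _ = units.apply_quality_filters([self._unit(0, **base)], "neuropixels")
        assert kept
        for key, better in [("rp_contamination", 0.01), ("noise_cutoff_sd", 0.5),
                            ("low_bin_fraction", 0.0), ("overall_rate_hz", 5.0)]:
            improved = dict(base, **{key: better})
            kept2, _ = units.apply_quality_filters([self._unit(0, **improved)], "neuropixels")
            assert kept2, f"improving {key} must never exclude"


class TestRpContamination:
    def test_refractory_train_is_clean(self):
        t = np.arange(0, 600, 0.05)   # all ISIs 50 ms
        assert units.rp_contamination(t) == 0.0

    def test_poisson_train_is_fully_contaminated(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 600, 6000))
        assert units.rp_contamination(t) >= 0.9

    def test_planted_five_percent_recovered(self):
        rng = np.random.default_rng(2)
        refractory = np.cumsum(rng.exponential(1 / 10.0, 24000) + 0.011)
        span = refractory[-1] - refractory[0]
        contaminant = refractory[0] + np.sort(rng.uniform(0, span, int(0.05 * 24000)))
        mixed = np.sort(np.concatenate([refractory, contaminant]))
        assert units.rp_contamination(mixed) == pytest.approx(0.05, abs=0.03)

    def test_identical_times_degenerate(self):
        assert units.rp_contamination(np.zeros(10)) == 1.0


class TestNoiseCutoff:
    def test_untruncated_distribution_passes(self):
        rng = np.random.default_rng(3)
        sd, frac = units.noise_cutoff(rng.normal(50, 10, 20000))
        assert sd < 5

    def test_truncated_distribution_fails(self):
        rng = np.random.default_rng(4)
        amps = rng.normal(50, 10, 40000)
        sd, frac = units.noise_cutoff(amps[amps > 50])
        assert sd >= 5 or frac >= 0.1

    def test_isolated_low_outlier_gives_small_fraction(self):
        # lowest histogram bin holds a single isolated low value, so the
        # low-bin fraction is 1 / (modal bin count), far below the 10% cutoff
        amps = np.concatenate([[0.0], np.random.default_rng(5).normal(55, 2, 2000)])
        sd, frac = units.noise_cutoff(amps)
        counts, _ = np.histogram(amps, bins=100)
        assert frac == pytest.approx(1 / counts.max())
        assert frac < 0.1

    def test_constant_amplitudes_error(self):
        with pytest.raises(ValueError):
            units.noise_cutoff(np.full(200, 3.3))


class TestRates:
    def test_count_over_window(self):
        t = np.linspace(0, 299, 300)
        assert units.spontaneous_rate(_train(t), (0.0, 300.0)) == pytest.approx(1.0)

    def test_empty_train_zero(self):
        assert units.spontaneous_rate(_train([]), (0.0, 10.0)) == 0.0

    def test_poisson_rate_within_standard_error(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 300, 1500))
        se = np.sqrt(1500) / 300
        assert units.spontaneous_rate(_train(t), (0.0, 300.0)) == pytest.approx(5.0, abs=3 * se)

    def test_window_outside_recording_errors(self):
        with pytest.raises(ValueError):
            units.spontaneous_rate(_train([1.0, 2.0]), (100.0, 200.0))

    def test_prestimulus_split_by_outcome(self):
        t = np.sort(np.concatenate([np.arange(0.5, 1.0, 0.05), []]))
        events = pd.DataFrame({"onset_s": [1.0, 10.0], "outcome": ["hit", "miss"]})
        rates = units.prestimulus_rates(_train(t), events)
        assert rates["hit"] == pytest.approx(20.0)
        assert rates["miss"] == 0.0


class TestPsth:
    def test_single_latency_spike_gives_single_bin(self):
        onsets = np.arange(1.0, 21.0, 1.0)
        t = np.sort(onsets + 0.0105)
        centers, rate = units.compute_psth(_train(t), onsets, bin_ms=1.0)
        peak = np.argmax(rate)
        assert rate[peak] == pytest.approx(1000.0)
        assert centers[peak] == pytest.approx(0.0105, abs=5e-4)
        assert np.count_nonzero(rate) == 1

    def test_flat_for_homogeneous_poisson(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 600, 6000))
        onsets = np.arange(5.0, 595.0, 1.0)
        _, rate = units.compute_psth(_train(t), onsets, bin_ms=1.0, kernel_sd_ms=5.0)
        assert rate.mean() == pytest.approx(10.0, rel=0.1)

    def test_smoothing_conserves_area(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 100, 500))
        onsets = np.arange(2.0, 98.0, 1.0)
        _, raw = units.compute_psth(_train(t), onsets, kernel_sd_ms=0.0)
        _, smooth = units.compute_psth(_train(t), onsets, kernel_sd_ms=3.0)
        # kernel truncated +/-4 SD and renormalized; interior mass conserved
        assert smooth.sum() == pytest.approx(raw.sum(), rel=0.02)

    def test_merged_trains_psth_is_sum(self):
        rng = np.random.default_rng(9)
        a = np.sort(rng.uniform(0, 100, 300))
        b = np.sort(rng.uniform(0, 100, 400))
        onsets = np.arange(2.0, 98.0, 1.0)
        _, ra = units.compute_psth(_train(a), onsets)
        _, rb = units.compute_psth(_train(b), onsets)
        _, rm = units.compute_psth(_train(np.sort(np.concatenate([a, b]))), onsets)
        np.testing.assert_allclose(rm, ra + rb, atol=1e-9)


class TestEvokedResponse:
    def test_background_invariance(self, passive_events):
        # doubling a constant-rate background leaves the estimate unchanged in expectation
        uspec = [UnitSpec(unit_id=0, baseline_rate_hz=5.0)]
        evoked = EvokedSpec(latency_ms=0.0, gain_hz_by_intensity={70.0: 40.0})
        lo = synth.gen_evoked_spikes(uspec, evoked, passive_events, seed=10)[0]
        uspec2 = [UnitSpec(unit_id=0, baseline_rate_hz=10.0)]
        hi = synth.gen_evoked_spikes(uspec2, evoked, passive_events, seed=10)[0]
        r_lo = units.evoked_response(lo, passive_events, "passive").by_intensity[70.0]
        r_hi = units.evoked_response(hi, passive_events, "passive").by_intensity[70.0]
        assert r_lo == pytest.approx(2.0, abs=0.5)
        assert r_hi == pytest.approx(2.0, abs=0.5)

    def test_task_mode_uses_long_baseline(self, passive_events):
        sparse = passive_events.iloc[::2].reset_index(drop=True)  # 1.2-s spacing
        uspec = [UnitSpec(unit_id=0, baseline_rate_hz=5.0)]
        evoked = EvokedSpec(latency_ms=0.0, gain_hz_by_intensity={70.0: 40.0})
        tr = synth.gen_evoked_spikes(uspec, evoked, sparse, seed=11)[0]
        r = units.evoked_response(tr, sparse, "task")
        assert r.baseline_window_s == 0.5
        assert r.by_intensity[70.0] == pytest.approx(2.0, abs=0.6)


class TestMuaLatency:
    def test_planted_step_detected_within_one_ms(self):
        events = np.arange(1.0, 101.0, 0.5)[:200]
        ev = pd.DataFrame({"onset_s": events, "intensity_db": 70.0})
        uspec = [UnitSpec(unit_id=0, baseline_rate_hz=20.0)]
        evoked = EvokedSpec(latency_ms=8.0, gain_hz_by_intensity={70.0: 400.0})
        tr = synth.gen_evoked_spikes(uspec, evoked, ev, seed=12)[0]
        lat = units.mua_latency([tr], events)
        assert lat[0] == pytest.approx(8.0, abs=1.0)

    def test_silent_channel_undefined(self):
        events = np.arange(1.0, 101.0, 0.5)[:200]
        lat = units.mua_latency([np.array([])], events)
        assert np.isnan(lat[0])

    def test_requires_twenty_trials(self):
        with pytest.raises(ValueError):
            units.mua_latency([np.arange(10.0)], np.arange(1.0, 10.0))
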