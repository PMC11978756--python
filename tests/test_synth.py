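"""Generator contracts: planted parameters are recoverable and outputs are
bitwise reproducible under a fixed seed."""

import numpy as np
import pandas as pd
import pytest

from acephys import behavior, laminar, spectral, synth
from acephys._seeding import substream
from acephys.types import (
    ConnectionSpec,
    EvokedSpec,
    LaminarLFPSpec,
    NetworkSpec,
    PsychometricSpec,
    UnitSpec,
)


class TestSeeding:
    def test_same_names_same_stream(self):
        a = substream(7, "x", 3).standard_normal(5)
        b = substream(7, "x", 3).standard_normal(5)
        np.testing.assert_array_equal(a, b)

    def test_different_names_differ(self):
        a = substream(7, "x").standard_normal(5)
        b = substream(7, "y").standard_normal(5)
        assert not np.array_equal(a, b)


class TestBehaviorSession:
    def test_hit_rate_at_midpoint_is_half(self):
        # binomial oracle: p = 0.5 at the midpoint, n = 10000
        spec = PsychometricSpec(midpoint_db=45, slope_per_db=1.0, lapse=0.0,
                                catch_fa=0.0, intensities_db=(45.0,))
        s = synth.gen_behavior_session(spec, 10000, 10, seed=11)
        _, res = behavior.score_trials(s)
        assert res.hit_rate_by_intensity[45.0] == pytest.approx(0.5, abs=0.01)

    def test_zero_catch_fa_gives_zero_catch_licks(self):
        spec = PsychometricSpec(catch_fa=0.0)
        s = synth.gen_behavior_session(spec, 5, 500, seed=3)
        catch = s.catch_trials()
        assert sum(len(l) for l in catch["lick_times"]) == 0

    def test_deterministic_under_fixed_seed(self, psych_spec):
        a = synth.gen_behavior_session(psych_spec, 20, 10, seed=5)
        b = synth.gen_behavior_session(psych_spec, 20, 10, seed=5)
        pd.testing.assert_frame_equal(
            a.trials.drop(columns="lick_times"), b.trials.drop(columns="lick_times")
        )
        for x, y in zip(a.trials["lick_times"], b.trials["lick_times"]):
            np.testing.assert_array_equal(x, y)

    def test_iti_bounds_and_lick_floor(self, behavior_session):
        onsets = behavior_session.trials["onset_s"].to_numpy()
        gaps = np.diff(onsets) - behavior_session.response_window_s
        assert gaps.min() >= 2.0 and gaps.max() <= 4.0
        for _, tr in behavior_session.trials.iterrows():
            for lick in tr["lick_times"]:
                assert lick - tr["onset_s"] >= 0.05 - 1e-12

    def test_rejects_nonfinite_spec(self):
        with pytest.raises(ValueError):
            PsychometricSpec(midpoint_db=np.nan)
        with pytest.raises(ValueError):
            PsychometricSpec(lapse=1.5)


class TestCoupledTrains:
    def test_poisson_counts_within_3sd(self):
        net = NetworkSpec(
            units=[UnitSpec(unit_id=i, baseline_rate_hz=5.0) for i in range(8)],
            duration_s=300.0,
        )
        trains = synth.gen_coupled_spike_trains(net, seed=21)
        for t in trains:
            assert abs(t.n_spikes - 1500) <= 3 * np.sqrt(1500)

    def test_zero_transmission_equals_unconnected(self):
        units = [UnitSpec(unit_id=0, baseline_rate_hz=5.0),
                 UnitSpec(unit_id=1, baseline_rate_hz=5.0)]
        plain = synth.gen_coupled_spike_trains(NetworkSpec(units=units, duration_s=300), seed=9)
        coupled = synth.gen_coupled_spike_trains(
            NetworkSpec(units=units, duration_s=300,
                        connections=[ConnectionSpec(0, 1, +1, 1.5, 0.0)]),
            seed=9,
        )
        for a, b in zip(plain, coupled):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_zero_rate_unit_is_empty(self):
        net = NetworkSpec(units=[UnitSpec(unit_id=0, baseline_rate_hz=0.0)], duration_s=100)
        assert synth.gen_coupled_spike_trains(net, seed=1)[0].n_spikes == 0

    def test_trains_sorted_nonnegative_within_duration(self, excitatory_pair):
        for t in excitatory_pair:
            assert np.all(np.diff(t.spike_times) >= 0)
            assert t.spike_times.min() >= 0
            assert t.spike_times.max() < 600.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(units=[UnitSpec(unit_id=0), UnitSpec(unit_id=0)])


class TestEvokedSpikes:
    def test_planted_gain_yields_two_extra_spikes_per_window(self, passive_events):
        # Poisson oracle: 40 Hz gain over 50 ms -> mean 2.0 extra spikes
        units = [UnitSpec(unit_id=0, baseline_rate_hz=5.0)]
        evoked = EvokedSpec(latency_ms=0.0, gain_hz_by_intensity={70.0: 40.0})
        trains = synth.gen_evoked_spikes(units, evoked, passive_events, seed=33)
        from acephys.units import evoked_response
        r = evoked_response(trains[0], passive_events, condition="passive")
        assert r.by_intensity[70.0] == pytest.approx(2.0, abs=0.35)
        assert r.by_intensity[30.0] == pytest.approx(0.0, abs=0.35)

    def test_zero_gain_has_no_evoked_response(self, passive_events):
        from acephys.units import evoked_response
        units = [UnitSpec(unit_id=0, baseline_rate_hz=10.0)]
        evoked = EvokedSpec(latency_ms=5.0, gain_hz_by_intensity={})
        trains = synth.gen_evoked_spikes(units, evoked, passive_events, seed=4)
        r = evoked_response(trains[0], passive_events, condition="passive")
        for v in r.by_intensity.values():
            assert abs(v) < 0.35


class TestLaminarLFP:
    def test_planted_sink_recovered_through_pipeline(self, laminar_events):
        spec = LaminarLFPSpec(sink_channel=8, sink_amplitude=50.0, noise_sd=0.0)
        lfp = synth.gen_laminar_lfp(spec, laminar_events, 60.0, seed=2)
        pre = spectral.preprocess_lfp(lfp, "csd", "silicon")
        t, erp = laminar.compute_erp(pre, laminar_events["onset_s"].to_numpy())
        csd = laminar.compute_csd(erp, pre.channel_spacing_mm)
        assert laminar.locate_sink(csd, t) == 8

    def test_white_noise_band_powers_match_bandwidths(self, laminar_events):
        spec = LaminarLFPSpec(sink_amplitude=0.0, noise_sd=1.0)
        lfp = synth.gen_laminar_lfp(spec, laminar_events.iloc[:0], 120.0, seed=6)
        rp = spectral.welch_relative_power(lfp.data[3], lfp.sampling_rate)
        for name, (lo, hi) in spectral.BANDS.items():
            assert rp[name] == pytest.approx((hi - lo) / 47.0, abs=0.05)

    def test_silent_zero_noise_block_is_all_zero(self):
        spec = LaminarLFPSpec(sink_amplitude=0.0, noise_sd=0.0)
        lfp = synth.gen_laminar_lfp(spec, pd.DataFrame({"onset_s": []}), 5.0, seed=1)
        assert not lfp.data.any()

    def test_edge_sink_rejected(self):
        with pytest.raises(ValueError):
            LaminarLFPSpec(sink_channel=0)

    def test_oscillation_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            LaminarLFPSpec(sampling_rate=100.0, oscillations=[(60.0, 1.0, (0, 3))])
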