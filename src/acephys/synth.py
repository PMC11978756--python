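"""Synthetic-data generators with known ground truth.

Each generator emulates one data stream of a head-fixed auditory detection /
passive-listening experiment: Bernoulli trial outcomes from a logistic
psychometric function, homogeneous Poisson spike trains with planted pairwise
couplings, intensity-dependent evoked responses at fixed latency, and
multichannel LFP with a localized evoked dipole plus band-limited oscillations.
All randomness derives from one integer seed through independent named
substreams (see :mod:`acephys._seeding`), so outputs are bitwise reproducible
and adding one generator never perturbs another's stream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._seeding import substream
from .types import (
    BehaviorSession,
    ConnectionSpec,
    EvokedSpec,
    LaminarLFPSpec,
    LFPBlock,
    NetworkSpec,
    PsychometricSpec,
    SpikeTrain,
    UnitSpec,
)

logger = logging.getLogger(__name__)

RT_FLOOR_S = 0.05            # no physical lick can occur 50 ms after onset
COUPLING_JITTER_S = 2e-4     # inserted spikes jittered within +/-0.2 ms
SINK_PROFILE_SD_CH = 1.5     # spatial SD (channels) of the evoked dipole

__all__ = [
    "gen_behavior_session",
    "gen_coupled_spike_trains",
    "gen_evoked_spikes",
    "gen_laminar_lfp",
]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def gen_behavior_session(
    spec: PsychometricSpec,
    n_trials_per_intensity: int,
    n_catch: int,
    seed: int,
    session_start_s: float = 5.0,
) -> BehaviorSession:
    """Simulate one detection-task session.

    Sound and catch trials are pseudo-randomly interleaved.  On a sound trial
    the hit indicator is Bernoulli with the lapse-adjusted logistic probability
    of ``spec``; a hit's lick time is onset + max(50 ms, N(rt_mean, rt_sd))
    truncated to the 1-s response window.  Catch-trial licks are Bernoulli with
    ``spec.catch_fa`` at a uniform time inside the window.  The intertrial
    interval is uniform 2-4 s.
    """
    if n_trials_per_intensity <= 0 or n_catch < 0:
        raise ValueError("trial counts must be positive")
    rng = substream(seed, "behavior")
    intensities = np.asarray(spec.intensities_db, dtype=float)

    labels = np.concatenate(
        [np.repeat(intensities, n_trials_per_intensity), np.full(n_catch, np.nan)]
    )
    rng.shuffle(labels)
    n = labels.size

    iti = rng.uniform(2.0, 4.0, size=n)
    window = 1.0
    onsets = session_start_s + np.concatenate(([0.0], np.cumsum(window + iti[:-1])))

    rows = []
    for onset, intensity in zip(onsets, labels):
        is_catch = not np.isfinite(intensity)
        licks: list[float] = []
        if is_catch:
            if rng.random() < spec.catch_fa:
                licks.append(onset + rng.uniform(RT_FLOOR_S, window))
        else:
            p_hit = float(spec.hit_probability(intensity))
            if rng.random() < p_hit:
                rt = max(RT_FLOOR_S, rng.normal(spec.rt_mean_s, spec.rt_sd_s))
                licks.append(onset + min(rt, window))
        rows.append(
            {
                "onset_s": onset,
                "intensity_db": intensity,
                "is_catch": is_catch,
                "lick_times": np.asarray(licks, dtype=float),
            }
        )
    return BehaviorSession(trials=pd.DataFrame(rows), response_window_s=window)


# ---------------------------------------------------------------------------
# coupled spike trains
# ---------------------------------------------------------------------------

def _poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _delete_in_windows(times: np.ndarray, starts: np.ndarray, width: float) -> np.ndarray:
    """Drop all entries of sorted ``times`` covered by [start, start+width)."""
    if starts.size == 0 or times.size == 0:
        return times
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + width, side="left")
    delta = np.zeros(times.size + 1, dtype=np.int64)
    np.add.at(delta, lo, 1)
    np.add.at(delta, hi, -1)
    covered = np.cumsum(delta[:-1]) > 0
    return times[~covered]


def gen_coupled_spike_trains(spec: NetworkSpec, seed: int) -> list[SpikeTrain]:
    """Simulate Poisson units with planted excitatory/inhibitory couplings.

    Every unit is a homogeneous Poisson process at its baseline rate.  Each
    excitatory connection inserts, per origin spike and with its transmission
    probability, one extra target spike at origin time + delay +/- 0.2 ms
    jitter.  Each inhibitory connection deletes, per origin spike and with
    that probability, all target spikes within [delay, delay + window] where
    the suppression window defaults to 2 ms.
    Couplings read the origin's baseline train, so chained connections do not
    compound.
    """
    base: dict[int, np.ndarray] = {}
    for u in spec.units:
        rng = substream(seed, "poisson", u.unit_id)
        base[u.unit_id] = _poisson_train(u.baseline_rate_hz, spec.duration_s, rng)

    out = {uid: t.copy() for uid, t in base.items()}
    for conn in spec.connections:
        rng = substream(seed, "coupling", conn.origin_id, conn.target_id)
        origin = base[conn.origin_id]
        gate = rng.random(origin.size) < conn.transmission_prob
        fired = origin[gate]
        delay = conn.delay_ms * 1e-3
        if conn.sign > 0:
            extra = fired + delay + rng.uniform(-COUPLING_JITTER_S, COUPLING_JITTER_S, fired.size)
            extra = extra[(extra >= 0.0) & (extra < spec.duration_s)]
            out[conn.target_id] = np.sort(np.concatenate([out[conn.target_id], extra]))
        else:
            out[conn.target_id] = _delete_in_windows(
                out[conn.target_id], fired + delay, conn.inhibition_window_ms * 1e-3
            )

    trains = []
    for u in spec.units:
        trains.append(
            SpikeTrain(
                unit_id=u.unit_id,
                spike_times=out[u.unit_id],
                trough_to_peak_ms=u.trough_to_peak_ms,
                depth_um=u.depth_um,
                cell_type=u.cell_type,
                layer=u.layer,
            )
        )
    return trains


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------

def gen_evoked_spikes(
    units: list[UnitSpec],
    evoked: EvokedSpec,
    events: pd.DataFrame,
    seed: int,
    duration_s: float | None = None,
) -> list[SpikeTrain]:
    """Baseline Poisson spiking plus intensity-dependent evoked spikes.

    ``events`` needs ``onset_s`` (sorted) and ``intensity_db`` columns.  Per
    event, extra spikes are Poisson with rate ``gain_hz_by_intensity[I]``
    inside [onset+latency, onset+latency+window].
    """
    onsets = events["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted by onset")
    if onsets.size > 1 and np.min(np.diff(onsets)) < evoked.window_ms * 1e-3:
        logger.warning("event spacing shorter than the evoked analysis window")
    if duration_s is None:
        duration_s = float(onsets[-1]) + 1.0 if onsets.size else 1.0

    window_s = evoked.window_ms * 1e-3
    lat_s = evoked.latency_ms * 1e-3
    intensities = events["intensity_db"].to_numpy(dtype=float)

    trains = []
    for u in units:
        rng = substream(seed, "evoked", u.unit_id)
        t = _poisson_train(u.baseline_rate_hz, duration_s, rng)
        extras = []
        for onset, inten in zip(onsets, intensities):
            gain = float(evoked.gain_hz_by_intensity.get(inten, 0.0))
            if gain <= 0:
                continue
            k = rng.poisson(gain * window_s)
            if k:
                extras.append(onset + lat_s + rng.uniform(0.0, window_s, size=k))
        if extras:
            t = np.sort(np.concatenate([t] + extras))
        t = t[(t >= 0.0) & (t < duration_s)]
        trains.append(
            SpikeTrain(
                unit_id=u.unit_id,
                spike_times=t,
                trough_to_peak_ms=u.trough_to_peak_ms,
                depth_um=u.depth_um,
                cell_type=u.cell_type,
                layer=u.layer,
            )
        )
    return trains


# ---------------------------------------------------------------------------
# laminar LFP
# ---------------------------------------------------------------------------

def gen_laminar_lfp(
    spec: LaminarLFPSpec,
    events: pd.DataFrame,
    duration_s: float,
    seed: int,
) -> LFPBlock:
    """Gaussian-noise LFP with a planted evoked dipole and oscillations.

    The per-event template is a temporal Gaussian (center ``sink_latency_ms``,
    SD ``sink_width_ms``) whose spatial profile is a three-point dipole scaled
    so the CSD second difference ((Va+Vb)-2Vo)/d^2 attains its most negative
    extremum exactly on ``sink_channel``.  Stationary sinusoids are added over
    the channel ranges of ``spec.oscillations``.
    """
    onsets = events["onset_s"].to_numpy(dtype=float) if len(events) else np.array([])
    if onsets.size and (onsets.min() < 0 or onsets.max() >= duration_s):
        raise ValueError("duration must cover all events")

    fs = spec.sampling_rate
    n_samples = int(round(duration_s * fs))
    rng = substream(seed, "lfp")
    data = (
        rng.standard_normal((spec.n_channels, n_samples)) * spec.noise_sd
        if spec.noise_sd > 0
        else np.zeros((spec.n_channels, n_samples))
    )

    # Temporal template of the evoked deflection.
    if spec.sink_amplitude != 0 and onsets.size:
        width_s = spec.sink_width_ms * 1e-3
        t_rel = np.arange(-4 * width_s, 4 * width_s + spec.sink_latency_ms * 1e-3, 1.0 / fs)
        shape = np.exp(-0.5 * ((t_rel - spec.sink_latency_ms * 1e-3) / width_s) ** 2)
        shape = shape[t_rel >= 0]
        t_rel = t_rel[t_rel >= 0]
        # Spatial profile: Ricker (Mexican-hat) centered on the sink channel —
        # a smooth dipole whose second spatial difference keeps its most
        # negative extremum on sink_channel even after the +/-1-channel
        # smoothing of the CSD preprocessing presets (a 3-point dipole sits at
        # the spatial Nyquist limit and flips its extremum under smoothing).
        # Sign matches the analysis convention: the CSD map is the raw second
        # difference and the sink is its most negative value.
        ch = np.arange(spec.n_channels, dtype=float)
        u2 = ((ch - spec.sink_channel) / SINK_PROFILE_SD_CH) ** 2
        spatial = spec.sink_amplitude * (1.0 - u2) * np.exp(-u2 / 2.0)
        for onset in onsets:
            i0 = int(round(onset * fs))
            idx = i0 + np.round(t_rel * fs).astype(int)
            ok = (idx >= 0) & (idx < n_samples)
            data[:, idx[ok]] += spatial[:, None] * shape[ok][None, :]

    tgrid = np.arange(n_samples) / fs
    for freq, amp, (ch_lo, ch_hi) in spec.oscillations:
        wave = amp * np.sin(2 * np.pi * freq * tgrid)
        data[ch_lo: ch_hi + 1, :] += wave[None, :]

    depths = -np.arange(spec.n_channels) * spec.channel_spacing_um
    return LFPBlock(
        data=data,
        sampling_rate=fs,
        channel_depths_um=depths,
        channel_spacing_mm=spec.channel_spacing_um / 1000.0,
        probe="silicon",
    )
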