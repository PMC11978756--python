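"""Shared domain containers for the pipeline.

Conventions used throughout the package:

* Times are seconds; depths are micrometres; channel spacing for CSD is
  millimetres (matching the units of the second-difference formula).
* Cortical depth is referenced to the top border of the input layer
  (the top CSD sink channel = 0 µm, positive above / superficial).
* Channel index 0 is the most superficial channel of a shank; index grows
  with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CELL_TYPES = ("BS", "NS")
LAYERS = ("L_sup", "L_in", "L_d1", "L_d2")
CATCH = "catch"


# ---------------------------------------------------------------------------
# electrophysiology containers
# ---------------------------------------------------------------------------

@dataclass
class QualityMetrics:
    """Cluster-quality numbers attached to a sorted unit.

    ``isolation_distance`` applies to silicon-probe sorts; ``rp_contamination``
    (refractory-period contamination fraction), ``noise_cutoff_sd`` and
    ``low_bin_fraction`` apply to Neuropixels sorts.  Any metric may be None
    when not computed for that probe.
    """

    isolation_distance: float | None = None
    overall_rate_hz: float | None = None
    rp_contamination: float | None = None
    noise_cutoff_sd: float | None = None
    low_bin_fraction: float | None = None


@dataclass
class SpikeTrain:
    """One unit's event times plus waveform/position/quality metadata."""

    unit_id: int
    spike_times: np.ndarray
    trough_to_peak_ms: float | None = None
    max_channel: int | None = None
    depth_um: float | None = None
    region: str = "AC"
    cell_type: str | None = None
    layer: str | None = None
    quality: QualityMetrics | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration_s: float) -> float:
        return self.n_spikes / duration_s


@dataclass
class LFPBlock:
    """Multichannel LFP: channels x samples with geometry.

    ``channel_spacing_mm`` is the inter-channel distance used by the CSD
    second difference.  ``shank_ids``/``row_ids`` are optional probe-layout
    metadata consulted by the preprocessing presets.
    """

    data: np.ndarray                       # (n_channels, n_samples)
    sampling_rate: float
    channel_depths_um: np.ndarray | None = None
    channel_spacing_mm: float = 0.05
    probe: str = "silicon"
    shank_ids: np.ndarray | None = None
    row_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("LFP data must be channels x samples")
        if self.channel_spacing_mm <= 0:
            raise ValueError("channel spacing must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# behavior containers
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSession:
    """Ordered detection-task trials.

    ``trials`` columns: ``onset_s`` (float, strictly increasing),
    ``intensity_db`` (float; NaN on catch trials), ``is_catch`` (bool),
    ``lick_times`` (object: 1-D float array of absolute lick times).
    """

    trials: pd.DataFrame
    response_window_s: float = 1.0

    def __post_init__(self) -> None:
        required = {"onset_s", "intensity_db", "is_catch", "lick_times"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials table missing columns: {sorted(missing)}")
        onsets = self.trials["onset_s"].to_numpy(dtype=float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def sound_trials(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_catch"]]

    def catch_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["is_catch"]]


# ---------------------------------------------------------------------------
# synthetic-data specifications (ground truth)
# ---------------------------------------------------------------------------

def _check_prob(p: float, name: str) -> None:
    if not np.isfinite(p) or not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass
class PsychometricSpec:
    """Planted logistic psychometric function for the detection task.

    p(hit | I) = (1 - lapse) / (1 + exp(-slope * (I - midpoint))), with an
    intensity-independent false-alarm probability on catch trials.
    """

    midpoint_db: float = 45.0
    slope_per_db: float = 1.0
    lapse: float = 0.0
    catch_fa: float = 0.1
    intensities_db: Sequence[float] = (30.0, 40.0, 50.0, 60.0, 70.0)
    rt_mean_s: float = 0.3
    rt_sd_s: float = 0.08

    def __post_init__(self) -> None:
        for v, name in [(self.midpoint_db, "midpoint_db"),
                        (self.slope_per_db, "slope_per_db"),
                        (self.rt_mean_s, "rt_mean_s"), (self.rt_sd_s, "rt_sd_s")]:
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        _check_prob(self.lapse, "lapse")
        _check_prob(self.catch_fa, "catch_fa")
        if self.slope_per_db <= 0:
            raise ValueError("slope must be positive")
        ints = np.asarray(self.intensities_db, dtype=float)
        if ints.size < 1 or np.any(np.diff(ints) <= 0):
            raise ValueError("intensities must be strictly increasing")

    def hit_probability(self, intensity_db: float) -> float:
        z = self.slope_per_db * (np.asarray(intensity_db, float) - self.midpoint_db)
        return (1.0 - self.lapse) / (1.0 + np.exp(-z))


@dataclass
class UnitSpec:
    """Ground-truth description of one simulated unit."""

    unit_id: int
    cell_type: str = "BS"
    layer: str = "L_in"
    depth_um: float = -75.0
    baseline_rate_hz: float = 5.0
    trough_to_peak_ms: float = 0.8

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline rate must be >= 0")


@dataclass
class ConnectionSpec:
    """Planted pairwise coupling: +1 inserts a delayed target spike per
    origin spike with the given probability, -1 deletes target spikes in a
    2-ms window after the delay."""

    origin_id: int
    target_id: int
    sign: int = +1
    delay_ms: float = 1.5
    transmission_prob: float = 0.2
    inhibition_window_ms: float = 2.0   # suppression duration after the delay (sign -1)

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if not (0.0 < self.delay_ms <= 5.0):
            raise ValueError("delay must be in (0, 5] ms")
        _check_prob(self.transmission_prob, "transmission_prob")
        if self.inhibition_window_ms <= 0:
            raise ValueError("inhibition window must be positive")
        if self.origin_id == self.target_id:
            raise ValueError("self-connections are not allowed")


@dataclass
class NetworkSpec:
    """A population of Poisson units with planted couplings."""

    units: Sequence[UnitSpec]
    connections: Sequence[ConnectionSpec] = field(default_factory=list)
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_ids must be unique")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for c in self.connections:
            if c.origin_id not in ids or c.target_id not in ids:
                raise ValueError(f"connection references unknown unit: {c}")


@dataclass
class EvokedSpec:
    """Planted evoked response: extra Poisson rate (per intensity) inside a
    fixed-latency window after each stimulus onset."""

    latency_ms: float = 10.0
    gain_hz_by_intensity: dict = field(default_factory=dict)   # dB -> Hz
    window_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.latency_ms < 0:
            raise ValueError("latency must be >= 0")
        if self.window_ms <= 0:
            raise ValueError("window must be positive")


@dataclass
class LaminarLFPSpec:
    """Planted laminar LFP: localized evoked dipole + oscillations + noise.

    The evoked template is a temporal Gaussian whose spatial profile is a
    discrete dipole (center channel one sign, flanking channels half the
    opposite sign) so the CSD second-difference extremum lands exactly on
    ``sink_channel``.
    """

    n_channels: int = 16
    channel_spacing_um: float = 50.0
    sampling_rate: float = 1000.0
    sink_channel: int = 8
    sink_amplitude: float = 100.0
    sink_latency_ms: float = 20.0
    sink_width_ms: float = 8.0
    oscillations: Sequence[tuple] = field(default_factory=list)  # (Hz, amp, (ch_lo, ch_hi))
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.sink_channel < self.n_channels):
            raise ValueError("sink_channel out of range")
        if self.sink_channel == 0 or self.sink_channel == self.n_channels - 1:
            raise ValueError("sink channel needs two neighbors (not at array edge)")
        for f, _amp, _rng in self.oscillations:
            if self.sampling_rate <= 2 * f:
                raise ValueError("sampling rate must exceed twice every oscillation frequency")


@dataclass
class GroundTruth:
    """Bundle of planted parameters a recovery test compares against."""

    psychometric: PsychometricSpec | None = None
    network: NetworkSpec | None = None
    evoked: EvokedSpec | None = None
    lfp: LaminarLFPSpec | None = None
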