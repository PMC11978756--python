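"""Laminar analysis: event-related potentials, current source density, sink
localization, depth-based layer assignment, and thalamic channel-span
refinement.

The CSD map is the discrete second spatial difference
CSD = ((Va + Vb) - 2*Vo) / d^2 with d the inter-channel distance in mm; the
current sink is its most negative evoked extremum, and the sink channel
defines depth 0 = top border of the input layer.  Layer borders (relative to
that reference) are: L_sup > 0 um, L_in (0, -150] um, L_d1 (-150, -400] um,
L_d2 <= -400 um.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import LFPBlock

logger = logging.getLogger(__name__)

__all__ = [
    "compute_erp",
    "compute_csd",
    "locate_sink",
    "assign_layer",
    "layer_fraction",
    "estimate_mgb_span",
    "MGBEstimate",
]


def compute_erp(
    lfp: LFPBlock,
    events: np.ndarray,
    t_pre_s: float = 0.05,
    t_post_s: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-aligned trial-averaged LFP, baseline-referenced per channel.

    Returns (time axis in s relative to onset, channels x time average).
    The pre-onset mean is subtracted per channel.
    """
    onsets = np.asarray(events, dtype=float)
    if onsets.size == 0:
        raise ValueError("no events")
    if onsets.size < 5:
        logger.warning("compute_erp: only %d events; ERP will be noisy", onsets.size)
    fs = lfp.sampling_rate
    n_pre = int(round(t_pre_s * fs))
    n_post = int(round(t_post_s * fs))
    idx0 = np.round(onsets * fs).astype(int)
    if idx0.min() - n_pre < 0 or idx0.max() + n_post > lfp.n_samples:
        raise ValueError("events (with ERP window) fall outside the recording")
    sweeps = np.stack([lfp.data[:, i - n_pre: i + n_post] for i in idx0])
    erp = sweeps.mean(axis=0)
    erp = erp - erp[:, :n_pre].mean(axis=1, keepdims=True)
    t = (np.arange(-n_pre, n_post)) / fs
    return t, erp


def compute_csd(erp: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Second spatial difference ((Va+Vb) - 2*Vo)/d^2 per interior channel.

    Edge channels (no two neighbors) are NaN.
    """
    if spacing_mm <= 0:
        raise ValueError("channel spacing must be positive")
    erp = np.asarray(erp, dtype=float)
    if erp.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    csd = np.full_like(erp, np.nan)
    csd[1:-1] = (erp[:-2] + erp[2:] - 2.0 * erp[1:-1]) / spacing_mm**2
    return csd


def locate_sink(
    csd: np.ndarray,
    time_axis_s: np.ndarray,
    window_s: tuple[float, float] = (0.0, 0.05),
    tie_tol: float = 1e-9,
) -> int | None:
    """Channel with the most negative CSD extremum in the post-onset window.

    Contiguous channels tying within ``tie_tol`` resolve to the shallowest
    (lowest index), which becomes depth 0.  Returns None (flagged) when the
    windowed CSD has no negative value.
    """
    time_axis_s = np.asarray(time_axis_s, dtype=float)
    sel = (time_axis_s >= window_s[0]) & (time_axis_s <= window_s[1])
    if not sel.any():
        raise ValueError("sink search window outside the ERP span")
    windowed = np.asarray(csd, dtype=float)[:, sel]
    per_channel_min = np.full(windowed.shape[0], np.inf)
    finite = np.isfinite(windowed).any(axis=1)
    per_channel_min[finite] = np.nanmin(windowed[finite], axis=1)
    best = float(np.min(per_channel_min))
    if not (best < 0):
        logger.warning("locate_sink: no negative CSD in the search window")
        return None
    candidates = np.flatnonzero(per_channel_min <= best + tie_tol)
    return int(candidates[0])


def assign_layer(depth_um: float) -> str:
    """Map a depth (um relative to the top sink channel) to a cortical layer."""
    if not np.isfinite(depth_um):
        raise ValueError("depth must be finite")
    if depth_um > 0:
        return "L_sup"
    if depth_um > -150:
        return "L_in"
    if depth_um > -400:
        return "L_d1"
    return "L_d2"


def layer_fraction(w_sup_um: float, w_total_um: float) -> float:
    """Superficial-layer width fraction W_L2-4 / W_L2-6."""
    if w_total_um <= 0:
        raise ValueError("total width must be positive")
    if not (0 < w_sup_um <= w_total_um):
        raise ValueError("need 0 < w_sup <= w_total")
    return float(w_sup_um / w_total_um)


def session_layer_fraction(ratios: np.ndarray) -> float:
    """Session value: mean of the (typically 3) adjacent-area width ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("no ratios")
    return float(ratios.mean())


@dataclass
class MGBEstimate:
    """Refined auditory-thalamus channel span."""

    channel_range: tuple[int, int]        # inclusive (first, last)
    latencies_ms: np.ndarray
    n_channels: int
    histology_only: bool = False          # True when the latency refinement failed


def estimate_mgb_span(
    track_length_um: float,
    electrode_spacing_um: float,
    latencies_ms: np.ndarray,
    short_latency_ms: float = 20.0,
    histology_first_channel: int = 0,
) -> MGBEstimate:
    """Two-step MGB border estimate.

    Step 1 fixes the channel count n = round(track_length / spacing) from the
    histological track length.  Step 2 slides an n-channel window across the
    thalamic channels and places it where the count of channels with a defined
    latency below ``short_latency_ms`` is maximal (ties -> deepest window,
    i.e. largest starting index).  When no channel shows a short latency the
    histology-only placement starting at ``histology_first_channel`` is
    returned with a flag.
    """
    lat = np.asarray(latencies_ms, dtype=float)
    n = int(round(track_length_um / electrode_spacing_um))
    if n <= 0:
        raise ValueError("track length implies zero channels")
    n = min(n, lat.size)
    short = np.isfinite(lat) & (lat < short_latency_ms)
    if not short.any():
        logger.warning("estimate_mgb_span: no short-latency channels; histology-only placement")
        first = min(histology_first_channel, lat.size - n)
        return MGBEstimate((first, first + n - 1), lat, n, histology_only=True)
    window_counts = np.convolve(short.astype(int), np.ones(n, dtype=int), mode="valid")
    start = int(np.flatnonzero(window_counts == window_counts.max())[-1])  # deepest tie
    return MGBEstimate((start, start + n - 1), lat, n, histology_only=False)
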