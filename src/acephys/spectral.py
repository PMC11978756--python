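"""Spectral analysis: LFP preprocessing presets, Welch relative band power,
z-scored MUA band power, and spike-field coherence.

Band definitions follow the silent-period analysis: delta 1-4, theta 4-8,
alpha 8-12, beta 15-30, low gamma 30-48 Hz, each expressed relative to the
total 1-48 Hz power.  Welch segments are 2-s Hann windows with 50% overlap;
spike-field coherence uses 3 DPSS tapers per 2-s window.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .types import LFPBlock, SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "TOTAL_BAND",
    "preprocess_lfp",
    "welch_relative_power",
    "mua_relative_power",
    "spike_field_coherence",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "low_gamma": (30.0, 48.0),
}
TOTAL_BAND = (1.0, 48.0)

WELCH_SEGMENT_S = 2.0
FILTER_ORDER = 4


def _lowpass(data: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    sos = signal.butter(FILTER_ORDER, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _downsample(data: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    if fs <= target_fs:
        return data, fs
    step = int(round(fs / target_fs))
    return data[..., ::step], fs / step


def _spatial_smooth(data: np.ndarray, half_width: int) -> np.ndarray:
    if half_width <= 0:
        return data
    return uniform_filter1d(data, size=2 * half_width + 1, axis=0, mode="nearest")


# preset -> (lowpass Hz, spatial half-width in channels)
_PRESETS = {
    ("csd", "silicon"): (800.0, 1),
    ("csd", "neuropixels"): (100.0, 5),
    ("power", "silicon"): (800.0, 0),
    ("power", "neuropixels"): (50.0, 2),
}


def preprocess_lfp(lfp: LFPBlock, purpose: str, probe: str | None = None) -> LFPBlock:
    """Apply the named preprocessing preset and return a new LFPBlock.

    Presets (lowpass cutoff, downsample to 1 kHz, spatial smoothing):

    * csd/silicon: 800 Hz, smooth across one top + one bottom neighbor.
    * csd/neuropixels: 100 Hz, smooth +/- 5 channels.
    * power/silicon: 800 Hz, middle shank only (when ``shank_ids`` present).
    * power/neuropixels: one channel row (when ``row_ids`` present), 50 Hz,
      smooth +/- 2 channels.
    """
    probe = probe or lfp.probe
    key = (purpose, probe)
    if key not in _PRESETS:
        raise ValueError(f"unknown preprocessing preset: {key}")
    cutoff, half_width = _PRESETS[key]

    data = lfp.data
    depths = lfp.channel_depths_um
    if key == ("power", "silicon") and lfp.shank_ids is not None:
        shanks = np.unique(lfp.shank_ids)
        middle = shanks[len(shanks) // 2]
        sel = lfp.shank_ids == middle
        data = data[sel]
        depths = depths[sel] if depths is not None else None
    if key == ("power", "neuropixels") and lfp.row_ids is not None:
        rows = np.unique(lfp.row_ids)
        sel = lfp.row_ids == rows[0]
        data = data[sel]
        depths = depths[sel] if depths is not None else None

    if lfp.sampling_rate <= 2 * cutoff:
        cutoff = 0.4 * lfp.sampling_rate
    data = _lowpass(data, lfp.sampling_rate, cutoff)
    data, fs = _downsample(data, lfp.sampling_rate, 1000.0)
    data = _spatial_smooth(data, half_width)
    return replace(lfp, data=data, sampling_rate=fs, channel_depths_um=depths,
                   shank_ids=None, row_ids=None)


def _band_integral(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    # lower edge inclusive, upper exclusive, to avoid double-counting shared edges
    sel = (freqs >= band[0]) & (freqs < band[1])
    if sel.sum() < 2:
        return float(psd[sel].sum())
    return float(np.trapezoid(psd[sel], freqs[sel]))


def welch_relative_power(
    x: np.ndarray,
    sampling_rate: float,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Per-band power from a Welch PSD, relative to the total 1-48 Hz power.

    2-s Hann segments with 50% overlap.  An all-zero signal returns NaN for
    every band (flagged via a log warning) rather than propagating 0/0.
    """
    bands = bands or BANDS
    x = np.asarray(x, dtype=float)
    nperseg = int(WELCH_SEGMENT_S * sampling_rate)
    if x.size < 2 * nperseg:
        raise ValueError("signal shorter than two Welch segments")
    if not np.any(x != 0):
        logger.warning("welch_relative_power: all-zero signal; band powers undefined")
        return {name: np.nan for name in bands}
    freqs, psd = signal.welch(x, fs=sampling_rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
    total = _band_integral(freqs, psd, TOTAL_BAND)
    if total <= 0:
        return {name: np.nan for name in bands}
    return {name: _band_integral(freqs, psd, band) / total for name, band in bands.items()}


def mua_relative_power(
    trains: list[SpikeTrain] | list[np.ndarray],
    window: tuple[float, float],
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Relative band power of aggregated, z-scored multi-unit activity.

    Spikes of all units are aggregated into 1-ms bins over ``window``,
    z-scored against the whole-segment mean/SD, smoothed with a 3-ms Gaussian
    kernel, lowpass filtered below 100 Hz, and passed to
    :func:`welch_relative_power` at 1 kHz.
    """
    start, end = window
    times = [t.spike_times if isinstance(t, SpikeTrain) else np.asarray(t, float)
             for t in trains]
    total_spikes = sum(t.size for t in times)
    if len(times) < 2 and total_spikes < 100:
        raise ValueError("need >= 2 units or >= 100 spikes for MUA analysis")
    fs = 1000.0
    edges = np.arange(start, end + 1e-9, 1.0 / fs)
    agg = np.zeros(edges.size - 1)
    for t in times:
        agg += np.histogram(t, bins=edges)[0]
    if not agg.any():
        raise ValueError("empty MUA aggregate")
    z = (agg - agg.mean()) / agg.std(ddof=0)
    z = gaussian_filter1d(z, 3.0, mode="nearest", truncate=4.0)  # 3-ms kernel at 1 kHz
    z = _lowpass(z, fs, 100.0)
    return welch_relative_power(z, fs, bands=bands)


def spike_field_coherence(
    spikes: SpikeTrain | np.ndarray,
    lfp: LFPBlock,
    window: tuple[float, float] | None = None,
    n_tapers: int = 3,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Multitaper spike-field coherence, averaged over channels then bands.

    The spike train is binned at the LFP sampling rate.  Cross- and
    auto-spectra are estimated in 2-s windows with 50% overlap using
    ``n_tapers`` DPSS tapers, averaged across windows and tapers per channel;
    coherence is then averaged across channels and finally within each band.
    """
    bands = bands or BANDS
    t = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    fs = lfp.sampling_rate
    if window is None:
        window = (0.0, lfp.duration_s)
    start, end = window
    if end - start < 60.0:
        raise ValueError("need at least 60 s of overlapping data")
    t = t[(t >= start) & (t < end)]
    if t.size < 100:
        raise ValueError("need at least 100 spikes")
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    field = lfp.data[:, i0:i1]
    if np.ptp(field) == 0:
        raise ValueError("constant LFP; coherence undefined")
    edges = np.arange(start, end + 0.5 / fs, 1.0 / fs)
    spike_sig = np.histogram(t, bins=edges)[0].astype(float)
    n = min(spike_sig.size, field.shape[1])
    spike_sig, field = spike_sig[:n], field[:, :n]

    seg = int(WELCH_SEGMENT_S * fs)
    hop = seg // 2
    starts = np.arange(0, n - seg + 1, hop)
    if starts.size < 2:
        raise ValueError("too few coherence windows")
    tapers = signal.windows.dpss(seg, NW=(n_tapers + 1) / 2, Kmax=n_tapers)

    n_ch = field.shape[0]
    nfft = seg
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sxx = np.zeros(freqs.size)
    syy = np.zeros((n_ch, freqs.size))
    sxy = np.zeros((n_ch, freqs.size), dtype=complex)
    for s0 in starts:
        xseg = spike_sig[s0: s0 + seg]
        xseg = xseg - xseg.mean()
        ysegs = field[:, s0: s0 + seg]
        ysegs = ysegs - ysegs.mean(axis=1, keepdims=True)
        for taper in tapers:
            fx = np.fft.rfft(xseg * taper, nfft)
            fy = np.fft.rfft(ysegs * taper[None, :], nfft)
            sxx += np.abs(fx) ** 2
            syy += np.abs(fy) ** 2
            sxy += fy * np.conj(fx)[None, :]
    coherence = np.abs(sxy) ** 2 / (syy * sxx[None, :])
    mean_coh = coherence.mean(axis=0)      # across channels

    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(mean_coh[sel].mean())
    return out
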