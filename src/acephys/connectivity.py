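"""Putative monosynaptic connectivity from jitter-null cross-correlograms.

For an ordered pair of simultaneously recorded units, the cross-correlogram
(CCG) histograms target-spike lags relative to origin spikes in 1-ms bins.
A null distribution is built from 1000 surrogate CCGs, each obtained by
jittering every target spike uniformly within +/- 3 ms — this destroys
millisecond-scale synaptic coupling while preserving spike counts and slow
co-modulation.  Per-bin 99th/1st surrogate percentiles form the confidence
band; an observed count crossing the band within the [-3, +3] ms window calls
the pair excitatory (above) or inhibitory (below), with excitatory taking
precedence on dual crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from ._seeding import substream
from .types import LAYERS, SpikeTrain

__all__ = [
    "compute_ccg",
    "jitter_spike_train",
    "surrogate_bands",
    "classify_connection",
    "analyze_pair",
    "connectivity_matrix",
    "connection_probability",
    "per_neuron_connection_table",
    "laminar_connectivity_summary",
    "CCGResult",
]

DEFAULT_BIN_MS = 1.0
DEFAULT_MAX_LAG_MS = 50.0
JITTER_HALF_WIDTH_MS = 3.0
TEST_WINDOW_MS = 3.0            # call window: bin centers in [-3, +3] ms
N_SURROGATES = 1000
ALPHA = 0.01


def _lag_grid(bin_ms: float, max_lag_ms: float) -> np.ndarray:
    n_side = int(round(max_lag_ms / bin_ms))
    if abs(n_side * bin_ms - max_lag_ms) > 1e-9:
        raise ValueError("bin width must divide the maximum lag")
    return np.arange(-n_side, n_side + 1) * bin_ms


def compute_ccg(
    origin: np.ndarray,
    target: np.ndarray,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram of target lags (t_target - t_origin).

    Returns (bin centers in ms, counts).  Bins are centered on integer
    multiples of ``bin_ms``; both trains must be sorted and non-empty.
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    if origin.size == 0 or target.size == 0:
        raise ValueError("both spike trains must be non-empty")
    centers = _lag_grid(bin_ms, max_lag_ms)
    bin_s = bin_ms * 1e-3
    half_span = (max_lag_ms + bin_ms / 2) * 1e-3

    lo = np.searchsorted(target, origin - half_span, side="left")
    hi = np.searchsorted(target, origin + half_span, side="left")
    m = hi - lo
    total = int(m.sum())
    if total == 0:
        return centers, np.zeros(centers.size, dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(m)[:-1]))
    idx = np.arange(total) - np.repeat(offsets, m) + np.repeat(lo, m)
    diffs = target[idx] - np.repeat(origin, m)
    bins = np.floor((diffs + half_span) / bin_s).astype(np.int64)
    bins = np.clip(bins, 0, centers.size - 1)
    counts = np.bincount(bins, minlength=centers.size)
    return centers, counts


def jitter_spike_train(
    spikes: np.ndarray,
    half_width_ms: float = JITTER_HALF_WIDTH_MS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Displace each spike by an independent uniform draw on +/- half_width."""
    if half_width_ms <= 0:
        raise ValueError("jitter half-width must be positive")
    if rng is None:
        rng = substream(0 if seed is None else seed, "jitter")
    spikes = np.asarray(spikes, dtype=float)
    hw = half_width_ms * 1e-3
    return np.sort(spikes + rng.uniform(-hw, hw, size=spikes.size))


def surrogate_bands(
    origin: np.ndarray,
    target: np.ndarray,
    n_surrogates: int = N_SURROGATES,
    alpha: float = ALPHA,
    seed: int = 0,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    jitter_ms: float = JITTER_HALF_WIDTH_MS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin upper/lower confidence bounds from jittered-target surrogates.

    Each surrogate jitters the target train by +/- ``jitter_ms`` and recomputes
    the CCG; the bounds are the per-bin 100*(1-alpha) and 100*alpha
    percentiles (99th/1st at the default alpha = 0.01).
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for the percentile bounds")
    if rng is None:
        rng = substream(seed, "surrogates")
    centers = _lag_grid(bin_ms, max_lag_ms)
    surr = np.empty((n_surrogates, centers.size), dtype=np.int64)
    for k in range(n_surrogates):
        jt = jitter_spike_train(target, jitter_ms, rng=rng)
        surr[k] = compute_ccg(origin, jt, bin_ms, max_lag_ms)[1]
    upper = np.percentile(surr, 100 * (1 - alpha), axis=0)
    lower = np.percentile(surr, 100 * alpha, axis=0)
    return upper, lower


@dataclass
class CCGResult:
    """CCG plus surrogate band and the resulting connection call."""

    origin_id: int
    target_id: int
    lags_ms: np.ndarray
    counts: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    call: str = "none"                      # origin -> target call
    reverse_call: str = "none"              # target -> origin call
    first_significant_lag_ms: float = np.nan
    diagnostics: dict = field(default_factory=dict)


def _directional_call(
    counts: np.ndarray, upper: np.ndarray, lower: np.ndarray,
    lags: np.ndarray, window: np.ndarray,
) -> tuple[str, float]:
    above = window & (counts > upper)
    below = window & (counts < lower)
    if above.any():
        call, crossing = "excitatory", above
    elif below.any():
        call, crossing = "inhibitory", below
    else:
        return "none", np.nan
    crossed = lags[crossing]
    return call, float(crossed[np.argmin(np.abs(crossed))])


def classify_connection(ccg: CCGResult, window_ms: float = TEST_WINDOW_MS) -> CCGResult:
    """Call the pair from band crossings in the short-latency lag windows.

    The significance span is split by direction: crossings at lags in
    [0, +3] ms support the origin -> target connection (``call``), crossings
    in [-3, 0] ms the reverse direction (``reverse_call``).  Within each
    window, excitatory (any bin above the upper bound) takes precedence over
    inhibitory (any bin below the lower bound); otherwise none.  The first
    significant lag is the forward crossing bin center closest to zero.
    """
    if ccg.lags_ms.shape != ccg.counts.shape or ccg.upper.shape != ccg.counts.shape:
        raise ValueError("lag grid mismatch between counts and bounds")
    eps = 1e-9
    fwd = (ccg.lags_ms >= -eps) & (ccg.lags_ms <= window_ms + eps)
    rev = (ccg.lags_ms >= -window_ms - eps) & (ccg.lags_ms <= eps)
    ccg.call, ccg.first_significant_lag_ms = _directional_call(
        ccg.counts, ccg.upper, ccg.lower, ccg.lags_ms, fwd
    )
    ccg.reverse_call, _ = _directional_call(
        ccg.counts, ccg.upper, ccg.lower, ccg.lags_ms, rev
    )
    return ccg


def analyze_pair(
    origin: SpikeTrain,
    target: SpikeTrain,
    seed: int = 0,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    n_surrogates: int = N_SURROGATES,
    alpha: float = ALPHA,
    jitter_ms: float = JITTER_HALF_WIDTH_MS,
    max_origin_spikes: int | None = None,
) -> CCGResult:
    """Full CCG + surrogate-band + classification for one ordered pair.

    Surrogate randomness derives from the master seed and the (origin, target)
    unit ids, so evaluation order cannot change results.  When
    ``max_origin_spikes`` is set, that many origin spikes are subsampled
    (deterministically from the same stream) before analysis.
    """
    o, t = origin.spike_times, target.spike_times
    rng = substream(seed, "ccg-pair", origin.unit_id, target.unit_id)
    if max_origin_spikes is not None and o.size > max_origin_spikes:
        o = np.sort(rng.choice(o, size=max_origin_spikes, replace=False))
    lags, counts = compute_ccg(o, t, bin_ms, max_lag_ms)
    upper, lower = surrogate_bands(
        o, t, n_surrogates=n_surrogates, alpha=alpha,
        bin_ms=bin_ms, max_lag_ms=max_lag_ms, jitter_ms=jitter_ms, rng=rng,
    )
    result = CCGResult(
        origin_id=origin.unit_id, target_id=target.unit_id,
        lags_ms=lags, counts=counts, upper=upper, lower=lower,
    )
    return classify_connection(result)


def connectivity_matrix(
    trains: list[SpikeTrain],
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Calls for every ordered pair of simultaneously recorded units.

    Returns a units x units DataFrame of {none, excitatory, inhibitory} with
    NaN on the diagonal.  Requires >= 2 units.
    """
    if len(trains) < 2:
        raise ValueError("need at least 2 simultaneously recorded units")
    ids = [tr.unit_id for tr in trains]
    by_id = {tr.unit_id: tr for tr in trains}
    calls = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=object)
    for oid, tid in permutations(ids, 2):
        res = analyze_pair(by_id[oid], by_id[tid], seed=seed, **kwargs)
        calls.loc[oid, tid] = res.call
    return calls


def connection_probability(
    calls: pd.DataFrame,
    origin_id: int,
    candidate_target_ids: list[int],
    kind: str = "excitatory",
) -> float:
    """Fraction of candidate partners with a significant ``kind`` call from
    ``origin_id`` (self excluded).  NaN when there are no candidates."""
    targets = [t for t in candidate_target_ids if t != origin_id]
    if not targets:
        return np.nan
    row = calls.loc[origin_id, targets]
    return float((row == kind).sum() / len(targets))


def per_neuron_connection_table(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    kind: str = "excitatory",
) -> pd.DataFrame:
    """Per-origin-neuron connection probabilities by target class.

    ``meta`` is indexed by unit_id with ``cell_type`` and ``layer`` columns.
    One row per (origin neuron, target cell_type, target layer) combination
    that has at least one candidate partner.
    """
    rows = []
    for oid in calls.index:
        for ttype in meta["cell_type"].unique():
            for tlayer in meta["layer"].unique():
                targets = meta.index[
                    (meta["cell_type"] == ttype) & (meta["layer"] == tlayer)
                ].tolist()
                p = connection_probability(calls, oid, targets, kind=kind)
                if np.isnan(p):
                    continue
                rows.append({
                    "origin_id": oid,
                    "origin_type": meta.loc[oid, "cell_type"],
                    "origin_layer": meta.loc[oid, "layer"],
                    "target_type": ttype,
                    "target_layer": tlayer,
                    "probability": p,
                })
    return pd.DataFrame(rows)


def laminar_connectivity_summary(
    per_neuron: pd.DataFrame,
    group_col: str = "group",
    control_label: str = "control",
    treated_label: str = "treated",
) -> dict:
    """Layer-resolved 4x4 median connection-probability matrices.

    For each (origin type, target type) combination and each group, the matrix
    cell (origin layer, target layer) holds the median across contributing
    neurons of their per-neuron probabilities; empty cells stay NaN (missing,
    never zero).  The difference map is control median - treated median.
    """
    out: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    type_pairs = per_neuron[["origin_type", "target_type"]].drop_duplicates()
    for _, tp in type_pairs.iterrows():
        otype, ttype = tp["origin_type"], tp["target_type"]
        sub = per_neuron[
            (per_neuron["origin_type"] == otype) & (per_neuron["target_type"] == ttype)
        ]
        mats: dict[str, pd.DataFrame] = {}
        for label in (control_label, treated_label):
            mat = pd.DataFrame(np.nan, index=list(LAYERS), columns=list(LAYERS))
            g = sub[sub[group_col] == label] if group_col in sub.columns else sub
            for (ol, tl), cell in g.groupby(["origin_layer", "target_layer"]):
                mat.loc[ol, tl] = float(cell["probability"].median())
            mats[label] = mat
        mats["difference"] = mats[control_label] - mats[treated_label]
        out[(otype, ttype)] = mats
    return out
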