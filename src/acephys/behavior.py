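"""Detection-task psychometrics: trial scoring, d', thresholds, reaction times.

The detectability index is d' = Z(hit rate) - Z(false-alarm rate), Z being the
inverse standard normal CDF; extreme rates are clipped to [1/(2n), 1 - 1/(2n)]
before the inverse transform.  The detection threshold is the intensity where a
cross-validated logistic binomial fit of hit probability vs intensity reaches
50%, averaged over the two random halves of the session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._seeding import substream
from .types import BehaviorSession

__all__ = [
    "score_trials",
    "compute_dprime",
    "estimate_threshold",
    "mean_reaction_time",
    "check_phase_criteria",
    "PsychometricResult",
]

HIT, MISS, FALSE_ALARM, CORRECT_REJECTION = "hit", "miss", "false_alarm", "correct_rejection"


@dataclass
class PsychometricResult:
    """Per-session psychometric summary."""

    hit_rate_by_intensity: dict[float, float]
    fa_rate: float                     # NaN when no catch trials (flagged)
    fa_rate_defined: bool
    dprime_by_intensity: dict[float, float] = field(default_factory=dict)
    rt_by_intensity: dict[float, float] = field(default_factory=dict)
    threshold_db: float = np.nan
    threshold_defined: bool = False
    diagnostics: dict = field(default_factory=dict)


def _licked_in_window(onset: float, licks: np.ndarray, window: float) -> bool:
    # response window (onset, onset + window], right edge closed
    licks = np.asarray(licks, dtype=float)
    return bool(np.any((licks > onset) & (licks <= onset + window)))


def score_trials(session: BehaviorSession) -> tuple[pd.DataFrame, PsychometricResult]:
    """Label every trial hit/miss/false_alarm/correct_rejection and compute rates.

    A sound trial with at least one lick inside (onset, onset+1 s] is a hit; a
    catch trial with a lick in the same window is a false alarm.  The
    false-alarm rate is flagged undefined (NaN) when the session has no catch
    trials, never silently zero.
    """
    if session.n_trials == 0:
        raise ValueError("session has no trials")
    w = session.response_window_s
    outcomes = []
    for _, tr in session.trials.iterrows():
        licked = _licked_in_window(tr["onset_s"], tr["lick_times"], w)
        if tr["is_catch"]:
            outcomes.append(FALSE_ALARM if licked else CORRECT_REJECTION)
        else:
            outcomes.append(HIT if licked else MISS)
    table = session.trials.copy()
    table["outcome"] = outcomes

    sound = table[~table["is_catch"]]
    hit_rates = {
        float(i): float((g["outcome"] == HIT).mean())
        for i, g in sound.groupby("intensity_db")
    }
    catch = table[table["is_catch"]]
    fa_defined = len(catch) > 0
    fa_rate = float((catch["outcome"] == FALSE_ALARM).mean()) if fa_defined else np.nan
    result = PsychometricResult(
        hit_rate_by_intensity=hit_rates, fa_rate=fa_rate, fa_rate_defined=fa_defined
    )
    return table, result


def compute_dprime(
    hit_rate: float, fa_rate: float, n_hit_trials: int, n_catch_trials: int
) -> float:
    """d' = Z(hit rate) - Z(false-alarm rate) with 1/(2n) extreme-rate clipping."""
    if n_hit_trials <= 0 or n_catch_trials <= 0:
        raise ValueError("trial counts must be positive")
    for r in (hit_rate, fa_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    h = np.clip(hit_rate, 1.0 / (2 * n_hit_trials), 1.0 - 1.0 / (2 * n_hit_trials))
    f = np.clip(fa_rate, 1.0 / (2 * n_catch_trials), 1.0 - 1.0 / (2 * n_catch_trials))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def _fit_threshold(intensity: np.ndarray, hit: np.ndarray) -> float:
    """Logistic binomial fit; returns the 50%-hit intensity or NaN if degenerate."""
    X = sm.add_constant(intensity)
    try:
        with warnings.catch_warnings():
            # steep psychometric functions routinely separate perfectly at
            # 10-dB steps; the 50% crossing of the IRLS limit is still usable
            warnings.simplefilter("ignore")
            fit = sm.GLM(hit, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception:
        return np.nan
    b0, b1 = fit.params
    if not np.isfinite(b0) or not np.isfinite(b1) or b1 <= 0:
        return np.nan
    # require an actual 50% crossing inside the sampled intensity range
    p_lo = 1.0 / (1.0 + np.exp(-(b0 + b1 * intensity.min())))
    p_hi = 1.0 / (1.0 + np.exp(-(b0 + b1 * intensity.max())))
    if not (p_lo < 0.5 < p_hi):
        return np.nan
    return float(-b0 / b1)


def estimate_threshold(session: BehaviorSession, seed: int) -> tuple[float, bool]:
    """Cross-validated detection threshold.

    Sound trials are split into a random half and the remainder (stratified by
    intensity); each half gets a logistic binomial fit of hit vs intensity, and
    the threshold is the mean of the two halves' 50%-hit intensities.  Returns
    (threshold_db, defined); undefined when either fit fails, has non-positive
    slope, or never crosses 50% within the sampled range.
    """
    table, _ = score_trials(session)
    sound = table[~table["is_catch"]]
    if sound["intensity_db"].nunique() < 2:
        raise ValueError("need at least 2 distinct intensities")
    rng = substream(seed, "threshold-split")

    in_first = np.zeros(len(sound), dtype=bool)
    pos = 0
    for _, g in sound.groupby("intensity_db"):
        k = len(g)
        pick = rng.permutation(k) < k // 2
        in_first[pos: pos + k] = pick
        pos += k

    intensity = sound["intensity_db"].to_numpy(dtype=float)
    hit = (sound["outcome"] == HIT).to_numpy(dtype=float)
    thresholds = []
    for mask in (in_first, ~in_first):
        thresholds.append(_fit_threshold(intensity[mask], hit[mask]))
    thresholds = np.asarray(thresholds)
    if np.any(~np.isfinite(thresholds)):
        return np.nan, False
    return float(np.mean(thresholds)), True


def mean_reaction_time(session: BehaviorSession) -> dict[float, float]:
    """Per-intensity mean of (first in-window lick - onset) over hit trials.

    Intensities with no hits map to NaN (flagged undefined).
    """
    table, _ = score_trials(session)
    sound = table[~table["is_catch"]]
    w = session.response_window_s
    out: dict[float, float] = {}
    for inten, g in sound.groupby("intensity_db"):
        rts = []
        for _, tr in g.iterrows():
            licks = np.asarray(tr["lick_times"], dtype=float)
            in_win = licks[(licks > tr["onset_s"]) & (licks <= tr["onset_s"] + w)]
            if in_win.size:
                rts.append(in_win.min() - tr["onset_s"])
        out[float(inten)] = float(np.mean(rts)) if rts else np.nan
    return out


def check_phase_criteria(phase: int, summaries: list[dict]) -> tuple[bool, str]:
    """Training-phase pass rules applied to an ordered session history.

    Phase 1 (basic lick training): last session has > 300 licks.
    Phase 2 (auditory conditioning): >= 150 licks with >= 60% success at 2-s
    sounds in 2 consecutive sessions.
    Phase 3 (auditory detection): (70-dB hit rate - catch false-alarm rate)
    > 0.40 in 2 consecutive sessions, after at least 10 sessions.

    ``summaries`` dicts carry whichever fields the phase needs: ``n_licks``,
    ``success_rate``, ``sound_duration_s`` (phase 2), ``hit_rate_70db``,
    ``fa_rate`` (phase 3).
    """
    if phase not in (1, 2, 3):
        raise ValueError("phase must be 1, 2 or 3")
    if not summaries:
        return False, "no session history"

    if phase == 1:
        licks = summaries[-1].get("n_licks")
        if licks is None:
            return False, "missing n_licks"
        return (licks > 300), f"last session licks = {licks} (need > 300)"

    def _consecutive(flags: list[bool]) -> bool:
        return any(a and b for a, b in zip(flags, flags[1:]))

    if phase == 2:
        flags = []
        for s in summaries:
            ok = (
                s.get("n_licks", 0) >= 150
                and s.get("success_rate", 0.0) >= 0.60
                and s.get("sound_duration_s", np.inf) <= 2.0
            )
            flags.append(ok)
        if len(flags) < 2:
            return False, "need at least 2 sessions for the consecutive rule"
        return _consecutive(flags), "2 consecutive qualifying 2-s-sound sessions required"

    # phase 3
    if len(summaries) < 10:
        return False, f"only {len(summaries)} sessions completed (need >= 10)"
    flags = []
    for s in summaries:
        hit70, fa = s.get("hit_rate_70db"), s.get("fa_rate")
        flags.append(hit70 is not None and fa is not None and (hit70 - fa) > 0.40)
    return _consecutive(flags), "hit70 - fa > 0.40 in 2 consecutive sessions required"
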