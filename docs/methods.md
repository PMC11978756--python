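# Methods

`acephys` reimplements, as a tested library, the analysis chain of a
head-fixed mouse auditory experiment: a sound-detection task scored by
signal-detection theory, laminar extracellular recordings analyzed by current
source density, spectral measures of spontaneous activity, and effective
monosynaptic connectivity inferred from jitter-null cross-correlograms.
Because real recordings are large and lab-specific, every stage is validated
against synthetic data with planted ground truth; this note documents the
models, the parameters that matter, and the numerical choices where the
procedure left them open.

## Behavioral model and psychometrics

A detection trial presents broadband noise at one of several intensities
(30–70 dB SPL in 10-dB steps by default) or nothing (catch trial); a lick
inside the 1-s response window after onset is a hit (sound) or false alarm
(catch). The window is treated as half-open on the left and closed on the
right: a lick at exactly onset + 1 s still counts.

Detection sensitivity is d' = Z(hit rate) − Z(false-alarm rate) with Z the
inverse standard normal CDF. Empirical rates of 0 or 1 make Z infinite, so
rates are clipped to [1/(2n), 1 − 1/(2n)] with n the relevant trial count —
the standard log-linear-style correction; the clipping rule is declared here
rather than inferred.

The detection threshold is estimated by a cross-validated logistic binomial
GLM of hit against intensity (sound trials only; catch trials carry no
intensity). Trials are split into a random half and its complement,
stratified by intensity so neither half loses a level; each half is fit
separately, the threshold is the intensity where the fitted probability
reaches 0.5, and the session threshold is the mean of the two. A fit is
flagged undefined when the slope is non-positive, the IRLS fit fails, or the
fitted curve never crosses 0.5 inside the sampled intensity range (e.g. an
all-hit session). Steep psychometric functions routinely separate perfectly
at 10-dB steps; the 50%-crossing of the IRLS limit remains usable and is
accepted, which in practice bounds recovery error at roughly the spacing of
the informative intensities (median error ≈ 1.8 dB at slope 1/dB, well inside
the ±2 dB validation bound).

The synthetic session generator plants p(hit | I) =
(1 − lapse) · 1/(1 + exp(−slope·(I − midpoint))), a flat catch false-alarm
probability, reaction times Normal(0.3 s, 0.08 s) floored at 50 ms (no
physical lick can be faster) and truncated to the window, and uniform 2–4-s
intertrial intervals.

## Cell types, quality control

Units are split at a 0.5-ms waveform trough-to-peak duration into
narrow-spiking (NS, putative fast-spiking; < 0.5 ms) and broad-spiking (BS,
putative excitatory; ≥ 0.5 ms); the boundary value itself maps to BS, a
declared tie rule.

Quality filters are probe-specific. Silicon-probe sorts keep units with
isolation (Mahalanobis) distance ≥ 20 and overall rate > 0.1 Hz. Neuropixels
sorts keep units with refractory-period contamination < 10%, an
amplitude-histogram noise cutoff < 5 SD with the lowest bin under 10% of the
modal bin, and rate > 0.1 Hz. A missing metric excludes the unit with an
explicit reason; the filter is monotone in every metric.

`rp_contamination` estimates the contaminant fraction without assuming a
refractory period: for each candidate period t_r on a 0.5–10-ms grid, the
observed number of spike pairs closer than t_r is compared with N·r·t_r, the
count expected from a homogeneous process at the unit's rate. Under a model
in which a fraction c of spikes is independent contamination the expected
ratio is 2c(1 − c) (contaminant–signal cross pairs dominate), so the estimate
inverts that relation (smaller root), returns 1 when the ratio admits no root
(no refractoriness detectable), and takes the minimum over the grid — the
most favorable candidate period. A fully Poisson train therefore estimates
≈ 1, a clean refractory train 0, and a planted 5% contamination ≈ 0.05.

`noise_cutoff` detects amplitude truncation at the spike-detection threshold:
the spike-amplitude histogram (100 bins) should have a tail-small lowest bin
if detection did not clip the distribution, so the metric is (lowest-bin
count − mean count of the highest-amplitude quartile of bins) / SD of those
counts, plus the lowest/modal bin-count ratio. The quartile choice and bin
count are configuration values.

## Evoked activity and latency

PSTHs are 1-ms binned, trial-averaged, optionally smoothed with a Gaussian
kernel truncated at ±4 SD and renormalized (area conserved). Evoked
responses are spike counts in the 50 ms from sound onset minus the baseline
expectation scaled to 50 ms; the baseline window is 50 ms pre-onset for
passive listening and 500 ms for task sessions (trials whose baseline would
overlap the previous stimulus are dropped and logged).

MUA response latency per channel: 1-ms binned trial-averaged activity,
5-ms Gaussian smoothing, normalization to (x − baseline mean)/(2.8 · baseline
SD), latency = first post-onset bin exceeding 1. Two numerical choices keep
the crossing calibrated, both documented in the function docstring:

* the kernel is causal (half-Gaussian over past bins). A zero-phase kernel
  leaks a strong response several ms before its true onset, biasing the
  threshold crossing early by up to 3 ms;
* the baseline SD of the smoothed trial-averaged trace is derived from the
  pooled per-trial baseline bin counts propagated through the kernel
  (SD·sqrt(Σk²/n_trials)), not from the ~100 heavily correlated smoothed
  baseline bins, whose sample SD has ~5 effective degrees of freedom and
  makes the 2.8-SD threshold itself unacceptably noisy (measured null
  false-crossing rate ~6% vs ~1.5% with the pooled estimator).

A zero baseline SD (silent channel) is floored at 1e−6 and flagged. The
thalamic channel span is refined in two steps: the histological track length
fixes the channel count n = round(length/spacing), then an n-channel window
is placed to maximize the number of channels with latency < 20 ms (ties to
the deepest window); with no short-latency channel the histology-only
placement is kept and flagged.

## Laminar analysis

LFP preprocessing presets (named dialects): CSD/silicon = 800-Hz lowpass,
downsample to 1 kHz, spatial smoothing across one neighbor each way;
CSD/Neuropixels = 100-Hz lowpass, 1 kHz, ±5 channels; power/silicon = 800-Hz
lowpass, 1 kHz, middle shank only; power/Neuropixels = one channel row,
50-Hz lowpass, ±2 channels. Butterworth order 4 applied forward-backward; the
order is a configuration value, not a claim about any particular rig.

The event-related potential is the stimulus-aligned trial average,
baseline-referenced to the pre-onset mean. The CSD map is the discrete
second spatial difference CSD = ((Va + Vb) − 2·Vo)/d² (d in mm); edge
channels are undefined. The sink is the most negative evoked extremum in the
0–50-ms window, ties resolving to the shallowest channel. Note the sign
convention: the physical CSD is −σ∇²V, so "most negative" here refers to the
second difference as computed; the synthetic generator plants its evoked
dipole with matching polarity so sink recovery is exact by construction.
The dipole's spatial profile is a Ricker (Mexican-hat) function with SD 1.5
channels rather than a 3-point stencil: a 3-point dipole sits at the spatial
Nyquist limit, and the preprocessing presets' channel smoothing flips its
second-difference extremum onto a neighboring channel.

The sink channel defines depth 0 = top border of the thalamorecipient input
layer. Layers by depth (positive above the sink): L_sup (putative L2/3)
> 0 µm; L_in (putative L4) 0 to −150 µm; L_d1 (putative L5) −150 to −400 µm;
L_d2 (putative L6) below −400 µm. Boundaries are half-open, closed above
(−150 µm → L_d1, −400 µm → L_d2); the mapping is total. Histological
superficial-layer fraction is W(L2–4)/W(L2–6), with the session value the
mean of three adjacent-area ratios.

## Spectral analysis

Band powers are computed from a Welch PSD (2-s Hann segments, 50% overlap)
by trapezoidal integration, each band relative to the total 1–48-Hz power:
delta 1–4, theta 4–8, alpha 8–12, beta 15–30, low gamma 30–48 Hz. Band edges
are lower-inclusive/upper-exclusive so the shared 4- and 8-Hz edges are not
double-counted; the five bands do not tile 12–15 Hz, so their sum can be
below 1. Relative power is scale-invariant; an all-zero signal is flagged
undefined rather than propagating NaNs.

MUA band power aggregates the units' spikes into 1-ms bins, z-scores against
the whole segment, smooths with a 3-ms Gaussian, lowpasses below 100 Hz, and
reuses the Welch pipeline at 1 kHz.

Spike–field coherence bins the spike train at the LFP rate and estimates
cross- and auto-spectra in 2-s windows with 50% overlap using 3 DPSS tapers
(NW = 2). Spectra are averaged over tapers and windows per channel, coherence
is formed per channel, averaged across channels, then averaged within each
band. The estimator family is a declared choice; its small-sample bias floor
is therefore measured empirically (an independent-spikes null) wherever a
coherence value is interpreted, rather than assumed.

## Connectivity inference

For an ordered unit pair, the cross-correlogram counts target-spike lags
relative to origin spikes in 1-ms bins (bin width is a declared default; the
test window below is what the procedure fixes). The null is built from 1000
surrogates, each jittering every target spike independently and uniformly
within ±3 ms — destroying millisecond-scale synaptic structure while
preserving counts and slow co-modulation — and taking per-bin 99th/1st
percentiles as the confidence band (one-sided 1% per direction).

Calls are directional: crossings at lags in [0, +3] ms support the
origin → target connection, crossings in [−3, 0] ms the reverse direction
(recorded separately); the zero-lag bin belongs to both windows. Within a
window, any bin above the upper bound calls the connection excitatory; else
any bin below the lower bound calls it inhibitory; excitatory takes
precedence on dual crossings (transmission peaks are narrower and more
reliable than troughs). The directional split matters for trough detection:
a deleted-spike trough depresses the jittered band in its ±3-ms
neighborhood, so intact opposite-side bins would otherwise cross the upper
bound and the precedence rule would mislabel strong inhibition as
excitation.

Surrogate randomness is keyed by a master seed plus the (origin, target)
unit ids, so evaluation order and parallelism cannot change results. An
optional origin-spike subsample (`max_origin_spikes`) is off by default.

Connection probability for a neuron is the number of significant connections
to a target class divided by the number of simultaneously recorded candidate
partners of that class (self excluded; undefined with no candidates, and
recordings need at least two units). Laminar summaries take, per (origin
layer → target layer) cell and per (origin type → target type) matrix, the
median across contributing neurons of their per-neuron probabilities; empty
cells stay missing, never zero, and difference maps are control − treated.

### Planted-coupling conditions

The generator plants excitatory couplings by inserting one delayed
(±0.2-ms-jittered) target spike per origin spike with the stated
transmission probability, and inhibitory couplings by deleting target spikes
in a suppression window after the origin spike. The validation conditions
are: excitatory — 5-Hz Poisson pairs, 600 s, delay 1.5 ms, transmission 0.2;
inhibitory — 10-Hz pairs, suppression window 4 ms starting 0.1 ms after the
origin spike, deletion probability 0.8. The inhibitory condition follows a
power analysis: detecting a trough at the 1% band needs enough baseline
coincidences per bin (~60 at 10 Hz/600 s), and the suppression must cover
the whole forward test window, because any intact bin inside it sits above a
band depressed by the smeared deficit. A 4-ms suppression is also the more
physiological scale for a fast IPSP; the generator's default window remains
2 ms.

Calibration on independent pairs: with four 1-ms bins tested per direction
at pointwise 1% two-sided, the expected per-pair false-call rate is below
1 − 0.98⁴ ≈ 8%; integer-count discreteness makes the strict-inequality
crossing conservative, and the measured rate is ~3–5%.

## Group statistics

Shapiro–Wilk at α = 0.05 on every group gates parametric vs nonparametric
testing; groups with n < 3 or constant values force nonparametric with a
flag. The rank-sum test is two-sided Wilcoxon–Mann–Whitney, exact for small
untied samples (identical to exhaustive permutation enumeration there), with
Bonferroni adjustment min(1, p·m). Two-way ANOVA is fixed-effects with
interaction and Type-II sums of squares (the SS type is a declared choice
for unbalanced designs). Hedge's g is the pooled-SD standardized mean
difference times the small-sample correction J = 1 − 3/(4(nA+nB) − 9); a
zero pooled SD is flagged undefined.

`resample_balance` addresses unequal group sizes: 1000 subsamples of the
larger (treated) pool at the smaller (control) size, drawn without
replacement (with-replacement behind a flag), each summarized by its median.
The overlap probability is the declared two-sided empirical formulation
2·min(P(median ≥ control median), P(median ≤ control median)), capped at 1.

## Randomness and reproducibility

All stochastic routines draw from `numpy` Generators keyed by one integer
master seed plus named substream tokens (CRC32 of the name). Fixed seed ⇒
bitwise-identical outputs, and adding a new generator never perturbs an
existing stream.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the analyses consume:
logistic trial outcomes, Poisson spike trains with short-latency couplings,
fixed-latency evoked rate steps, and a laminar LFP with a localized evoked
dipole plus stationary sinusoids on white noise. They do not emulate
bursting or non-Poisson interval statistics, rate nonstationarity, common
input, waveform shape, electrode drift, or 1/f LFP background. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own model assumptions — not robustness to every failure mode of real
recordings; in particular, the jitter-null calibration measured here (on
homogeneous Poisson pairs) is a lower bound on false calls under strong
common slow co-modulation.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 100 behavioral
sessions (100 trials/intensity, 50 catch); 50 + 50 planted CSD dipoles
(noise-free and amplitude/noise = 5); 200 null, 50 excitatory and 50
inhibitory 600-s pairs at 1000 surrogates each; 100 latency repeats of 200
trials; 120-s coherence segments; and a two-group cohort of 50 BS + 30 NS
units per group over 300 s with treated BS rates scaled by 0.6. These sizes
give Monte-Carlo error comfortably below each stated tolerance while the
whole suite completes in a few minutes on one core.
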