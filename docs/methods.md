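# Methods

This note records the models, parameter choices and numerical decisions
behind `rfneurostim`, and what the synthetic-data validation does and does
not establish about real recordings.

## Stimulation protocol

A session is a sequence of non-overlapping trials, each one RF-ON epoch
followed by one RF-OFF epoch; epochs are half-open `[start, end)` intervals
in seconds and trials may start anywhere (the convenience constructor packs
them back-to-back from t = 0). For amplitude-modulated RF the envelope is
`s(t) = (1 + cos(2π·f·t − π))/2` measured from each ON onset: the envelope
is zero at onset and phase 0 is defined as the envelope peak. This phase
convention is a package choice — any fixed convention works because the
Rayleigh statistic is rotation invariant.

## Spike analysis

**Epoching and blanking.** RF switching transients contaminate the first
milliseconds after both transitions, so spikes within `blank_ms`
(default 20 ms) after every ON onset *and* every ON offset are discarded and
the epoch exposures shortened by the same amount. Rates are always
counts/exposure, which keeps them unbiased under blanking (verified on
homogeneous Poisson input).

**Modulation index and per-unit test.** MI is computed from pooled
exposure-corrected rates, `(Σon/T_on − Σoff/T_off)/(sum)`; significance uses
the *paired* Wilcoxon signed-rank across per-trial (ON, OFF) rate pairs,
two-sided, with zero differences dropped (Wilcoxon convention; all-tied
units get p = 1). The paired test was chosen over the unpaired rank-sum
because ON and OFF epochs are paired within trials by design — the unpaired
variant is reserved for comparing independent populations (stimulation vs
sham). Per-unit α is 0.05 with no multiple-testing correction, replicating
the per-neuron screening convention this analysis emulates; a
Benjamini–Hochberg step can be applied to the returned p-value column by the
caller if desired.

**Rayleigh test.** Implemented in closed form with the standard finite-n
series correction on `Z = nR²`, vectorised so calibration experiments can
run thousands of simulations; it agrees with `pingouin.circ_rayleigh` to
~10⁻³ relative (different correction families) and its null p-values are
uniform by KS test at n = 500. Units with fewer than 10 ON spikes are
flagged underpowered rather than tested.

## Calcium-imaging analysis

**ΔF/F and detrending.** ΔF/F uses the session-wide median F_M per unit
(median of raw ΔF/F is exactly zero by construction). Slow trends are
removed by subtracting a running 20th-percentile baseline over a 30-s window
(evaluated on a quarter-window grid and linearly interpolated — O(n) and
adequate for photobleaching-scale trends). The window must be long relative
to a transient decay so events ride on top of the baseline.

**Deconvolution.** A self-contained nonnegative AR(1) deconvolution
(pool-adjacent-violators, the unpenalised OASIS recursion) inverts the
indicator-decay model `c_t = γ·c_{t−1} + s_t`, `s ≥ 0`. γ is estimated per
unit from the lag-2/lag-1 autocovariance ratio (white measurement noise only
inflates lag 0), clipped to [0.2, 0.999], or can be supplied. The residual
noise scale is 1.4826·MAD(y − c).

**Noise threshold.** The event floor is `k_mad` (default 3) times the noise
scale. Because an AR(1) model splits a finite-rise transient across 2–3
frames — each fragment possibly sub-threshold even when the event itself is
5 noise SDs — the default threshold *refits* the deconvolution with that
floor as a minimum event size (the hard-threshold OASIS variant, which
merges fragments into their parent event) and then zeroes any residue.
Plain zeroing is available via `refit=False`; at SNR 5 it loses roughly
60% of unitary event mass and halves detection power, which is why the
refit is the default.

**Trial-shuffle test.** For each unit the observed MI of a per-epoch metric
(summed event amplitude by default) is compared with a null built by
swapping each trial's ON/OFF labels independently with probability ½,
n_shuffles = 1000 times. Swapping within trials preserves per-trial totals,
so the null MI reduces to `Σ sᵢdᵢ / Σ totᵢ` and is exact under the
exchangeability that a sham session tests. The two-sided p-value measures
distance from the null mean with the +1 correction, guaranteeing
p ≥ 1/(n_shuffles+1); an exhaustive 2ⁿ enumeration oracle validates the
Monte-Carlo null for small trial counts. Units need ≥ 20 usable trials;
trials overlapping registered noisy periods are dropped per unit, and
all-zero units are excluded with a flag rather than assigned a p-value.
Measured calibration: type-I error 0.03–0.06 at α = 0.05 over 1000 null
units, p-values uniform by KS test.

**Population comparisons.** Stimulation vs sham MI distributions are
compared with the two-sided rank-sum (Mann–Whitney) test, as are
per-session percent-affected values when both conditions have ≥ 2 sessions.
Double sessions of the same neurons are pooled by concatenating per-trial
value lists through an injective unit map before re-testing.

**Background-artifact QC.** The per-frame mean over non-footprint pixels
(or a supplied background trace) is epoched like any metric;
`%change = 100·(mean_ON − mean_OFF)/mean_OFF` with trial-shuffle
significance. Sessions with |%change| ≥ 1% (configurable) are flagged as
artifact-contaminated — the signature of RF interference with the imaging
LED is a stimulus-locked 1–4% background dip.

## Thermal dosimetry

**Lumped bioheat model.** The spatial conduction term of the full bioheat
balance is replaced by single-compartment Newton cooling:
`T(t) = T0 + drift·t + u(t)`, `du/dt = SAR/C − u/τ` (RF-ON) or `−u/τ`
(RF-OFF). No spatial geometry is available at desk scale, and the
short-duration analysis below only uses the conduction-free limit anyway.
The generator integrates the piecewise-constant forcing exactly (per-segment
exponential updates), so noiseless traces match the closed forms
`ΔT = (SAR/C)·t` (τ = ∞) and `ΔT_∞ = τ·SAR/C` to machine precision. Note
the drift enters additively around the cooling equilibrium; writing the
cooling term as `−(T − T0 − drift·t)/τ` instead would cancel the drift
entirely at τ = ∞, which contradicts the intended SAR = 0 behaviour
`T = T0 + drift·t`.

**Trend-corrected heating rate.** Per trial, a line is fitted to the 50-s
pre-stimulus window and extrapolated under the 50-s ON window; ΔT is the
gap between the measured temperature and that baseline. The readout averages
the last 5 s of the ON window and divides by the elapsed time at the
averaging window's *centre*, which is unbiased under linear heating and
reduces single-sample noise by ~7× — with a 0.02 °C noise floor this is
what brings a 4-trace mean within 2% of truth. Every step is linear in the
temperature, so the estimate is invariant (to rounding) under adding any
linear function of time to the trace.

**Pre-stimulus linearity screen.** A trial is rejected when its
pre-stimulus segment is materially curved. The criterion is the ratio of
quadratic-fit to linear-fit residual sums of squares (accept when
≥ `r2_threshold`, default 0.95): a noiseless line scores 1, a noiseless
parabola 0, and a noisy flat or linearly drifting baseline ≈ 1 − 1/(n−2).
A raw r² criterion was rejected because it is not drift invariant — a flat
noisy baseline has r² ≈ 0 while the same baseline plus drift has r² ≈ 0.9,
so acceptance (and hence the estimate) would change under added drift,
violating the invariance above.

**Constants.** Default `TissueConstants` are calibrated by algebraic
inversion of the worked dosimetry triple this package reproduces
(ΔT/Δt = 7.91×10⁻³ °C/s ↔ SAR = 28.84 W/kg ↔ |E| = 231.77 V/m):
with standard brain density ρ = 1046 kg/m³,
C = 28.84/0.00791 ≈ 3646 J·kg⁻¹·°C⁻¹ and σ = 2ρ·SAR/|E|² ≈ 1.1232 S/m —
both plausible for grey matter near 1 GHz (σ ≈ 0.9–1.3 S/m in standard
dielectric tabulations). They are calibration constants, not literature
citations, and every analysis accepts overrides. Thermal conductivity k is
carried for completeness but unused by the lumped model.

**Bioheat fitting.** `fit_lumped_bioheat` fits the Newton solution over the
first ON window and its decay by Levenberg–Marquardt with data-derived
starting values; 95% CIs come from the Jacobian covariance. With
`assume_no_cooling` the conduction-free (linear) model is fitted instead —
on noiseless τ = ∞ traces its slope equals the trend-corrected estimator
exactly, tying the two estimators together.

## Synthetic-data generator: scope and limits

The generator emulates the study conditions end to end: 300 trials of
3 s ON / 3 s OFF at 37.5 W for 30-minute sessions (spikes and imaging);
AM envelopes at 5–20 Hz; 30 frames/s GCaMP6f-like transients
(rise 0.05 s, decay 0.5 s, difference of exponentials, peak-normalised);
mild photobleaching with a 5400-s time constant by default (~25% fade over
30 min — sessions in such experiments are capped at 30 min precisely to
limit bleaching), applied multiplicatively to baseline plus transients;
baseline offset 10× noise SD so ΔF/F is well defined; 50-s continuous-RF
heating bouts with 50-s pre-stimulus baselines for dosimetry; movies with
Gaussian-blob footprints on a uniform background and an optional ON-locked
background dip. All randomness flows from one integer seed per call
(per-unit streams spawned from it), and identical seeds give bit-identical
outputs.

What passing tests on this generator establishes: the statistics are
correctly calibrated under exchangeable nulls, the chain recovers known
effect sizes at realistic SNR, and the dosimetry algebra and estimators are
exact on their model class. What they do not establish: robustness to
motion, to correlated (non-white, non-Gaussian) imaging noise, to cell
segmentation errors or crosstalk between overlapping footprints, to
non-Poisson spiking (bursting changes indicator nonlinearity), or to
indicator saturation — none of which the generator emulates. Manual
curation steps of real pipelines are replaced by programmatic flags
(usable-trial minimums, exclusion periods, underpowered flags).

## Problem sizes and runtime choices

The default test and acceptance workloads use 300-trial sessions; the
population-calibration checks use 1000 simulated units at the counts level,
100 repeats of 1300-unit condition comparisons, and a 200-unit full imaging
chain (60 suppressed at multiplier 0.5, SNR 5); dosimetry recovery uses
4 noisy traces (0.02 °C noise at 10 Hz sampling) and 100-seed fit-recovery
medians. These sizes give comfortable statistical margins for every
assertion while keeping the whole suite around a minute of compute.

## Known limitations

* AR(1) deconvolution mis-models the finite rise of the indicator; the
  s_min refit recovers event mass but event *timing* can shift by a frame.
* The lumped bioheat model has no perfusion or spatial conduction; τ is an
  effective constant, not a tissue property, and SAR from Eq. `C·ΔT/Δt` is
  only valid while heating is approximately linear (t ≪ τ).
* The shuffle null assumes within-trial exchangeability of ON/OFF labels;
  slow drifts in event rate are absorbed by pairing but serial correlation
  at the trial scale is not modelled.
* No multiple-testing correction is applied per unit by default (by
  design, to mirror per-neuron screening at α = 0.05).
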