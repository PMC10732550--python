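"""Trial-based spike-train analysis for intermittent RF stimulation.

Epochs spikes into RF-ON / RF-OFF halves of each trial (with a configurable
artifact-blanking window after both RF transitions), computes exposure-
corrected firing rates, the ON/OFF modulation index, per-unit paired
nonparametric significance, phase entrainment under amplitude-modulated RF,
and dose-response summaries across radiated-power levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import StimulusProtocol, am_phase
from .synth import SpikeTrainSet

__all__ = [
    "EpochedCounts",
    "epoch_spikes",
    "psth",
    "modulation_index",
    "test_unit_response",
    "rayleigh_test",
    "rayleigh_p",
    "phase_entrainment",
    "dose_response",
    "waveform_stability",
]

DEFAULT_BLANK_MS = 20.0


@dataclass
class EpochedCounts:
    """Per-unit, per-trial ON/OFF spike counts and blanking-corrected exposures."""

    unit_ids: np.ndarray
    on_counts: np.ndarray  # (n_units, n_trials)
    off_counts: np.ndarray  # (n_units, n_trials)
    on_exposure_s: np.ndarray  # (n_trials,)
    off_exposure_s: np.ndarray  # (n_trials,)
    blank_ms: float

    @property
    def n_trials(self) -> int:
        return self.on_counts.shape[1]

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Exposure-corrected per-trial ON and OFF rates, Hz."""
        return (self.on_counts / self.on_exposure_s,
                self.off_counts / self.off_exposure_s)


def epoch_spikes(spikes: SpikeTrainSet, protocol: StimulusProtocol,
                 blank_ms: float = DEFAULT_BLANK_MS,
                 recording_span_s: float | None = None) -> EpochedCounts:
    """Assign spikes to ON/OFF epochs, blanking after each RF transition.

    Spikes within ``blank_ms`` after every ON onset (start of the ON epoch)
    and after every ON offset (start of the OFF epoch) are discarded and the
    corresponding epoch exposures are shortened accordingly, so rates computed
    from counts/exposure stay unbiased.
    """
    blank = blank_ms / 1000.0
    if blank < 0 or blank >= min(protocol.on_duration, protocol.off_duration):
        raise ValueError("blank_ms must be >= 0 and shorter than both epochs")
    if recording_span_s is not None and protocol.session_length > recording_span_s + 1e-9:
        raise ValueError("protocol extends beyond the recording span")
    starts = protocol.trial_start_times
    n_trials = protocol.n_trials
    on_counts = np.zeros((spikes.n_units, n_trials), dtype=np.int64)
    off_counts = np.zeros_like(on_counts)
    on_end = starts + protocol.on_duration
    off_end = on_end + protocol.off_duration
    for u, st in enumerate(spikes.spike_times):
        st = np.sort(st)
        on_counts[u] = (np.searchsorted(st, on_end, side="left")
                        - np.searchsorted(st, starts + blank, side="left"))
        off_counts[u] = (np.searchsorted(st, off_end, side="left")
                         - np.searchsorted(st, on_end + blank, side="left"))
    on_exp = np.full(n_trials, protocol.on_duration - blank)
    off_exp = np.full(n_trials, protocol.off_duration - blank)
    return EpochedCounts(unit_ids=spikes.unit_ids.copy(),
                         on_counts=on_counts, off_counts=off_counts,
                         on_exposure_s=on_exp, off_exposure_s=off_exp,
                         blank_ms=blank_ms)


def psth(spikes: SpikeTrainSet, protocol: StimulusProtocol,
         bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing-rate histogram aligned to trial onset.

    Returns ``(bin_edges_s, rates_hz)`` where ``rates_hz`` has shape
    (n_units, n_bins) and each bin's rate is count / (n_trials * bin_s).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    bin_s = bin_ms / 1000.0
    period = protocol.on_duration + protocol.off_duration
    n_bins = int(round(period / bin_s))
    if abs(n_bins * bin_s - period) > 1e-9:
        raise ValueError("bin width must divide the trial period")
    edges = np.arange(n_bins + 1) * bin_s
    rates = np.zeros((spikes.n_units, n_bins))
    for u, st in enumerate(spikes.spike_times):
        for t0 in protocol.trial_start_times:
            rel = st[(st >= t0) & (st < t0 + period)] - t0
            rates[u] += np.histogram(rel, bins=edges)[0]
    rates /= protocol.n_trials * bin_s
    return edges, rates


def modulation_index(on_value, off_value):
    """Modulation index MI = (ON - OFF) / (ON + OFF), bounded in [-1, 1].

    Accepts scalars or arrays of nonnegative activity measures. Where both
    values are zero the index is undefined and NaN is returned.
    """
    on_value = np.asarray(on_value, dtype=float)
    off_value = np.asarray(off_value, dtype=float)
    if np.any(on_value < 0) or np.any(off_value < 0):
        raise ValueError("modulation index requires nonnegative inputs")
    total = on_value + off_value
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(total > 0, (on_value - off_value) / total, np.nan)
    return mi if mi.ndim else float(mi)


def _signed_rank_p(on_rates: np.ndarray, off_rates: np.ndarray) -> float:
    diffs = on_rates - off_rates
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(on_rates, off_rates, zero_method="wilcox",
                         alternative="two-sided")
    return float(res.pvalue)


def test_unit_response(epoched: EpochedCounts, alpha: float = 0.05) -> pd.DataFrame:
    """Per-unit paired ON-vs-OFF test (Wilcoxon signed-rank across trials).

    The modulation index is computed from pooled exposure-corrected rates,
    MI = (sum ON counts / total ON exposure - sum OFF counts / total OFF
    exposure) / (sum). Classification: ``unaffected`` if p >= alpha, else
    ``suppressed``/``excited`` by the sign of MI.
    """
    if epoched.n_trials < 2:
        raise ValueError("need at least 2 trials for the paired test")
    on_rates, off_rates = epoched.rates()
    pooled_on = epoched.on_counts.sum(axis=1) / epoched.on_exposure_s.sum()
    pooled_off = epoched.off_counts.sum(axis=1) / epoched.off_exposure_s.sum()
    mi = np.atleast_1d(modulation_index(pooled_on, pooled_off))
    rows = []
    for u, uid in enumerate(epoched.unit_ids):
        p = _signed_rank_p(on_rates[u], off_rates[u])
        if p >= alpha or not np.isfinite(mi[u]) or mi[u] == 0:
            cls = "unaffected"
        elif mi[u] < 0:
            cls = "suppressed"
        else:
            cls = "excited"
        rows.append((uid, mi[u], p, cls, "wilcoxon_signed_rank",
                     epoched.n_trials))
    return pd.DataFrame(rows, columns=["unit_id", "mi", "p_value",
                                       "response_class", "statistic_name",
                                       "n_trials"])


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------


def rayleigh_p(R, n):
    """Rayleigh-test p-value for resultant length ``R`` of ``n`` phases.

    Uses the standard finite-sample correction
    ``p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``
    with ``Z = n R^2``, clipped into (0, 1]. Vectorised over inputs.
    """
    R = np.asarray(R, dtype=float)
    n = np.asarray(n, dtype=float)
    Z = n * R ** 2
    with np.errstate(over="ignore", under="ignore"):
        p = np.exp(-Z) * (1.0 + (2.0 * Z - Z ** 2) / (4.0 * n)
                          - (24.0 * Z - 132.0 * Z ** 2 + 76.0 * Z ** 3
                             - 9.0 * Z ** 4) / (288.0 * n ** 2))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p if p.ndim else float(p)


def rayleigh_test(phases: np.ndarray) -> tuple[float, float, float, int]:
    """Rayleigh test of circular uniformity.

    Returns ``(resultant_length_R, p, mean_phase, n)``.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("no phases supplied")
    C = np.cos(phases).mean()
    S = np.sin(phases).mean()
    R = math.hypot(C, S)
    return R, rayleigh_p(R, n), math.atan2(S, C) % (2 * math.pi), n


def phase_entrainment(spikes: SpikeTrainSet, protocol: StimulusProtocol,
                      blank_ms: float = DEFAULT_BLANK_MS,
                      min_spikes: int = 10) -> pd.DataFrame:
    """Rayleigh phase-locking analysis of ON-epoch spikes to the AM envelope.

    Each ON-epoch spike (after onset blanking) is mapped to the envelope
    phase (0 = envelope peak). Units with fewer than ``min_spikes`` ON spikes
    are flagged ``underpowered`` and their p-value is NaN.
    """
    if protocol.am_frequency is None:
        raise ValueError("protocol has no AM frequency")
    blank = blank_ms / 1000.0
    rows = []
    for uid, st in zip(spikes.unit_ids, spikes.spike_times):
        phases = []
        for t0 in protocol.trial_start_times:
            sel = st[(st >= t0 + blank) & (st < t0 + protocol.on_duration)]
            if sel.size:
                phases.append(am_phase(sel - t0, protocol.am_frequency))
        phases = np.concatenate(phases) if phases else np.empty(0)
        n = phases.size
        if n < min_spikes:
            rows.append((uid, np.nan, np.nan, np.nan, n, True))
            continue
        R, p, mean_phase, _ = rayleigh_test(phases)
        rows.append((uid, mean_phase, R, p, n, False))
    return pd.DataFrame(rows, columns=["unit_id", "mean_phase",
                                       "resultant_length_R", "rayleigh_p",
                                       "n_spikes", "underpowered"])


# ---------------------------------------------------------------------------
# dose-response and waveform QC
# ---------------------------------------------------------------------------


def dose_response(sessions: list[tuple[EpochedCounts, float]],
                  alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-power response tables plus a per-unit |MI|-vs-power trend summary.

    ``sessions`` pairs epoched counts with the radiated power (W) of that
    session; all sessions must contain the same unit ids. Returns
    ``(per_power_table, per_unit_trend)`` where the trend table carries the
    Spearman correlation of |MI| with power (NaN when fewer than 3 powers).
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    ref_ids = sessions[0][0].unit_ids
    for ep, pw in sessions[1:]:
        if not np.array_equal(np.sort(ep.unit_ids), np.sort(ref_ids)):
            missing = sorted(set(ref_ids.tolist()) ^ set(ep.unit_ids.tolist()))
            raise ValueError(f"unit sets differ across sessions; mismatched ids: {missing}")
    tables = []
    for ep, pw in sessions:
        tab = test_unit_response(ep, alpha=alpha)
        tab.insert(0, "power_w", pw)
        tables.append(tab)
    per_power = pd.concat(tables, ignore_index=True)
    trend_rows = []
    powers = np.array([pw for _, pw in sessions], dtype=float)
    for uid in ref_ids:
        mis = per_power.loc[per_power.unit_id == uid].sort_values("power_w")
        abs_mi = mis["mi"].abs().to_numpy()
        pw_sorted = np.sort(powers)
        if len(powers) >= 3 and np.isfinite(abs_mi).all():
            rho = stats.spearmanr(pw_sorted, abs_mi).statistic
        else:
            rho = np.nan
        trend_rows.append((uid, rho))
    trend = pd.DataFrame(trend_rows, columns=["unit_id", "spearman_abs_mi_vs_power"])
    return per_power, trend


def waveform_stability(waveforms_on: np.ndarray, waveforms_off: np.ndarray,
                       threshold: float = 1.0) -> dict:
    """Compare mean spike waveforms between ON and OFF epochs.

    Returns the per-sample-point mean difference, the pooled SD, the maximum
    of |delta mean| / pooled SD, and a flag raised when that maximum exceeds
    ``threshold`` (waveform altered by RF, or unstable unit isolation).
    """
    w_on = np.atleast_2d(np.asarray(waveforms_on, dtype=float))
    w_off = np.atleast_2d(np.asarray(waveforms_off, dtype=float))
    if w_on.shape[0] < 2 or w_off.shape[0] < 2:
        raise ValueError("need >= 2 waveforms per condition to estimate SD")
    if w_on.shape[1] != w_off.shape[1]:
        raise ValueError("waveform lengths differ between conditions")
    delta = w_on.mean(axis=0) - w_off.mean(axis=0)
    pooled_sd = np.sqrt(0.5 * (w_on.var(axis=0, ddof=1) + w_off.var(axis=0, ddof=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.abs(delta) / pooled_sd
    max_ratio = float(np.nanmax(ratio))
    return {
        "delta_mean": delta,
        "pooled_sd": pooled_sd,
        "max_abs_delta_over_sd": max_ratio,
        "flag": bool(max_ratio > threshold),
    }
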