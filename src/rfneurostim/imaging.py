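"""Calcium-trace analysis: dF/F, detrending, AR(1) deconvolution and
trial-shuffle response statistics.

The per-neuron significance machinery is a label-permutation ("shuffle")
test: the modulation index of a per-epoch activity metric (area under the
dF/F curve, summed deconvolved-event amplitude, or event count) is compared
with its null distribution obtained by randomly swapping the ON/OFF labels
within each trial. Two-sidedness follows the distance-from-null-mean rule,
with the +1 correction so p >= 1/(n_shuffles + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ephys import modulation_index
from .protocol import StimulusProtocol
from .synth import MovieStack

__all__ = [
    "DffTrace",
    "DeconvolvedActivity",
    "EpochValues",
    "ShuffleTestResult",
    "compute_dff",
    "detrend",
    "deconvolve",
    "oasis_ar1",
    "threshold_events",
    "exclude_periods",
    "epoch_metric",
    "shuffle_test",
    "shuffle_test_set",
    "exhaustive_shuffle_null",
    "compare_conditions",
    "combine_sessions",
    "background_artifact_qc",
]

METRICS = ("auc", "spike_amp_sum", "spike_count")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DffTrace:
    """Median-normalised fluorescence per unit with exclusion annotations."""

    dff: np.ndarray  # (n_units, n_frames)
    timestamps: np.ndarray
    unit_ids: np.ndarray
    excluded_periods: list[list[tuple[float, float]]] = field(default=None)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.excluded_periods is None:
            self.excluded_periods = [[] for _ in range(self.dff.shape[0])]

    @property
    def n_units(self) -> int:
        return self.dff.shape[0]

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


@dataclass
class DeconvolvedActivity:
    """Nonnegative event series inferred from dF/F by AR(1) inversion."""

    events: np.ndarray  # (n_units, n_frames), amplitudes >= 0
    gamma: np.ndarray  # per-unit AR(1) coefficient
    noise_scale: np.ndarray  # per-unit scaled-MAD of the fit residual
    timestamps: np.ndarray
    unit_ids: np.ndarray
    threshold_k: float = 0.0
    excluded_periods: list[list[tuple[float, float]]] = field(default=None)
    trace: np.ndarray | None = None  # dF/F the events were fitted to

    def __post_init__(self) -> None:
        if self.excluded_periods is None:
            self.excluded_periods = [[] for _ in range(self.events.shape[0])]

    @property
    def n_units(self) -> int:
        return self.events.shape[0]


@dataclass
class EpochValues:
    """Per-trial ON and OFF values of an epoch metric, with usability mask."""

    metric_name: str
    unit_ids: np.ndarray
    on_values: np.ndarray  # (n_units, n_trials)
    off_values: np.ndarray
    usable: np.ndarray  # (n_units, n_trials) bool


@dataclass
class ShuffleTestResult:
    unit_id: int
    metric_name: str
    observed_mi: float
    null_mis: np.ndarray
    p_value: float
    affected: bool
    excluded: bool = False


# ---------------------------------------------------------------------------
# trace processing
# ---------------------------------------------------------------------------


def compute_dff(F: np.ndarray, timestamps: np.ndarray,
                unit_ids: np.ndarray | None = None) -> DffTrace:
    """dF/F = (F - F_M) / F_M with F_M the session-wide median per unit.

    The raw dF/F has median exactly zero by construction. Raises if any
    unit's median fluorescence is non-positive (degenerate baseline).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] < 2:
        raise ValueError("trace must have at least 2 frames")
    fm = np.median(F, axis=1, keepdims=True)
    if np.any(fm <= 0):
        bad = np.nonzero(fm.ravel() <= 0)[0].tolist()
        raise ValueError(f"non-positive median fluorescence for units {bad}")
    if unit_ids is None:
        unit_ids = np.arange(F.shape[0])
    return DffTrace(dff=(F - fm) / fm, timestamps=np.asarray(timestamps, float),
                    unit_ids=np.asarray(unit_ids))


def _running_percentile_baseline(x: np.ndarray, win: int, q: float) -> np.ndarray:
    """Windowed percentile baseline, evaluated on a coarse grid and linearly
    interpolated back to every frame (O(n), adequate for slow bleaching)."""
    n = x.size
    step = max(1, win // 4)
    centers, vals = [], []
    for start in range(0, n, step):
        lo = max(0, start - win // 2)
        hi = min(n, start + win // 2 + 1)
        centers.append(start)
        vals.append(np.percentile(x[lo:hi], q))
    centers = np.asarray(centers, dtype=float)
    vals = np.asarray(vals)
    return np.interp(np.arange(n, dtype=float), centers, vals)


def detrend(trace: DffTrace, window_s: float = 30.0,
            percentile: float = 20.0) -> DffTrace:
    """Remove slow trends (photobleaching) from dF/F traces.

    Subtracts a running ``percentile``-th percentile baseline computed over a
    ``window_s`` window. The window should be much longer than a transient
    decay so events ride on top of, rather than being absorbed into, the
    baseline.
    """
    dt = trace.frame_interval
    win = int(round(window_s / dt))
    if win < 2:
        raise ValueError("detrend window must span at least 2 frames")
    out = np.empty_like(trace.dff)
    for u in range(trace.n_units):
        out[u] = trace.dff[u] - _running_percentile_baseline(
            trace.dff[u], win, percentile)
    return replace(trace, dff=out,
                   excluded_periods=[list(p) for p in trace.excluded_periods])


def oasis_ar1(y: np.ndarray, gamma: float,
              s_min: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Online nonnegative AR(1) deconvolution (pool-adjacent-violators).

    Finds the calcium reconstruction ``c`` minimising ||y - c||^2 subject to
    ``s_t = c_t - gamma * c_{t-1} >= 0``. With ``s_min > 0`` the greedy
    hard-threshold variant is used: adjacent pools are merged while the jump
    between them is below ``s_min``, so every surviving event is at least
    ``s_min`` (this re-aggregates event mass that an AR(1) model splits
    across the rise of a transient, instead of discarding it). Returns
    ``(c, s)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    # pools: value (sum gamma^d y), weight (sum gamma^2d), start, length
    pv, pw, pt, pl = [], [], [], []
    for t in range(n):
        pv.append(y[t]); pw.append(1.0); pt.append(t); pl.append(1)
        while len(pv) > 1:
            g_l = gamma ** pl[-2]
            if pv[-1] / pw[-1] - g_l * pv[-2] / pw[-2] >= s_min:
                break
            pv[-2] += g_l * pv[-1]
            pw[-2] += g_l * g_l * pw[-1]
            pl[-2] += pl[-1]
            pv.pop(); pw.pop(); pt.pop(); pl.pop()
    c = np.empty(n)
    for v, w, t, ln in zip(pv, pw, pt, pl):
        h = max(v / w, 0.0)
        c[t:t + ln] = h * gamma ** np.arange(ln)
    s = np.empty(n)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return c, np.maximum(s, 0.0)


def _estimate_gamma(y: np.ndarray, dt: float) -> float:
    """AR(1) coefficient from the lag-2 / lag-1 autocovariance ratio
    (robust to white measurement noise, which only inflates lag 0)."""
    x = y - y.mean()
    r1 = float(x[:-1] @ x[1:])
    r2 = float(x[:-2] @ x[2:])
    if r1 <= 0 or r2 <= 0:
        return math.exp(-dt / 0.5)  # fall back to a GCaMP6f-like decay
    return float(np.clip(r2 / r1, 0.2, 0.999))


def deconvolve(trace: DffTrace, ar_order: int = 1,
               gamma: float | np.ndarray | None = None,
               uniformity_tol: float = 1e-6) -> DeconvolvedActivity:
    """Invert the AR(1) indicator model per unit, returning event amplitudes.

    ``gamma`` may be given explicitly (scalar or per unit); otherwise it is
    estimated from the trace autocovariance. Frames must be uniformly
    sampled. The residual noise scale is 1.4826 * MAD(y - c).
    """
    if ar_order != 1:
        raise ValueError("only AR(1) deconvolution is implemented")
    dts = np.diff(trace.timestamps)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > uniformity_tol * max(1.0, dt)):
        raise ValueError("timestamps are not uniformly sampled")
    n_units = trace.n_units
    if gamma is None:
        gammas = np.array([_estimate_gamma(trace.dff[u], dt) for u in range(n_units)])
    else:
        gammas = np.broadcast_to(np.asarray(gamma, dtype=float), (n_units,)).copy()
    events = np.empty_like(trace.dff)
    noise = np.empty(n_units)
    for u in range(n_units):
        c, s = oasis_ar1(trace.dff[u], gammas[u])
        resid = trace.dff[u] - c
        events[u] = s
        noise[u] = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    # events inside excluded periods are zeroed (they are unusable anyway)
    for u, periods in enumerate(trace.excluded_periods):
        for a, b in periods:
            events[u, (trace.timestamps >= a) & (trace.timestamps < b)] = 0.0
    return DeconvolvedActivity(events=events, gamma=gammas, noise_scale=noise,
                               timestamps=trace.timestamps.copy(),
                               unit_ids=trace.unit_ids.copy(),
                               excluded_periods=[list(p) for p in trace.excluded_periods],
                               trace=trace.dff.copy())


def threshold_events(dec: DeconvolvedActivity, k_mad: float = 3.0,
                     refit: bool = True) -> DeconvolvedActivity:
    """Apply a noise floor to deconvolved events.

    The threshold is ``k_mad`` times the per-unit residual noise scale. By
    default (``refit=True``) the deconvolution is re-run with that value as a
    minimum event size (hard-threshold OASIS), which merges sub-threshold
    rising-edge fragments into their parent event rather than deleting their
    mass; any residue still below threshold is then zeroed. With
    ``refit=False`` sub-threshold events are simply zeroed. ``k_mad = 0`` is
    the identity.
    """
    if k_mad < 0:
        raise ValueError("k_mad must be >= 0")
    if k_mad == 0:
        return replace(dec, events=dec.events.copy(), threshold_k=0.0,
                       excluded_periods=[list(p) for p in dec.excluded_periods])
    if refit and dec.trace is not None and math.isfinite(k_mad):
        events = np.empty_like(dec.events)
        for u in range(dec.n_units):
            s_min = k_mad * dec.noise_scale[u]
            _, s = oasis_ar1(dec.trace[u], dec.gamma[u], s_min=s_min)
            events[u] = np.where(s >= s_min, s, 0.0)
    else:
        thr = k_mad * dec.noise_scale[:, None]
        events = np.where(dec.events >= thr, dec.events, 0.0)
    for u, periods in enumerate(dec.excluded_periods):
        for a, b in periods:
            events[u, (dec.timestamps >= a) & (dec.timestamps < b)] = 0.0
    return replace(dec, events=events, threshold_k=k_mad,
                   excluded_periods=[list(p) for p in dec.excluded_periods])


def exclude_periods(trace: DffTrace,
                    periods: list[tuple[float, float]],
                    unit_ids=None) -> DffTrace:
    """Register noisy periods; downstream per-trial metrics skip any trial
    overlapping a registered period for that unit.

    ``periods`` is a list of half-open ``[start, end)`` intervals in seconds;
    applied to all units unless ``unit_ids`` narrows the set.
    """
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    for a, b in periods:
        if b <= a:
            raise ValueError(f"inverted interval [{a}, {b})")
        if b < t0 or a > t1:
            raise ValueError(f"interval [{a}, {b}) lies outside the session")
    new = [list(p) for p in trace.excluded_periods]
    targets = (range(trace.n_units) if unit_ids is None
               else [int(np.flatnonzero(trace.unit_ids == uid)[0]) for uid in unit_ids])
    for u in targets:
        new[u].extend((float(a), float(b)) for a, b in periods)
    return replace(trace, dff=trace.dff.copy(), excluded_periods=new)


# ---------------------------------------------------------------------------
# epoch metrics and shuffle testing
# ---------------------------------------------------------------------------


def _overlaps(periods, a, b) -> bool:
    return any(pa < b and pb > a for pa, pb in periods)


def epoch_metric(activity, protocol: StimulusProtocol,
                 metric: str) -> EpochValues:
    """Per-trial ON and OFF values of an activity metric per unit.

    ``auc`` integrates dF/F over the epoch (sum * frame interval) and needs a
    :class:`DffTrace`; ``spike_amp_sum`` and ``spike_count`` need a
    :class:`DeconvolvedActivity`. Trials overlapping a unit's excluded
    periods are marked unusable.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "auc":
        if not isinstance(activity, DffTrace):
            raise TypeError("auc metric needs a DffTrace")
        values = activity.dff
        dt = activity.frame_interval
    else:
        if not isinstance(activity, DeconvolvedActivity):
            raise TypeError(f"{metric} metric needs a DeconvolvedActivity")
        values = activity.events
        dt = float(np.median(np.diff(activity.timestamps)))
    ts = activity.timestamps
    n_units = values.shape[0]
    n_trials = protocol.n_trials
    on = np.zeros((n_units, n_trials))
    off = np.zeros((n_units, n_trials))
    usable = np.ones((n_units, n_trials), dtype=bool)
    on_win = protocol.on_windows()
    off_win = protocol.off_windows()
    on_idx = [np.searchsorted(ts, w) for w in on_win]
    off_idx = [np.searchsorted(ts, w) for w in off_win]
    for k in range(n_trials):
        i0, i1 = on_idx[k]
        j0, j1 = off_idx[k]
        seg_on = values[:, i0:i1]
        seg_off = values[:, j0:j1]
        if metric == "auc":
            on[:, k] = seg_on.sum(axis=1) * dt
            off[:, k] = seg_off.sum(axis=1) * dt
        elif metric == "spike_amp_sum":
            on[:, k] = seg_on.sum(axis=1)
            off[:, k] = seg_off.sum(axis=1)
        else:  # spike_count
            on[:, k] = (seg_on > 0).sum(axis=1)
            off[:, k] = (seg_off > 0).sum(axis=1)
    for u in range(n_units):
        periods = activity.excluded_periods[u]
        if not periods:
            continue
        for k in range(n_trials):
            if _overlaps(periods, on_win[k, 0], off_win[k, 1]):
                usable[u, k] = False
    return EpochValues(metric_name=metric, unit_ids=activity.unit_ids.copy(),
                       on_values=on, off_values=off, usable=usable)


def shuffle_test(on_values: np.ndarray, off_values: np.ndarray,
                 n_shuffles: int = 1000, seed: int = 0,
                 alpha: float = 0.05, unit_id: int = 0,
                 metric_name: str = "metric",
                 min_trials: int = 20) -> ShuffleTestResult:
    """Trial-shuffle permutation test of the ON/OFF modulation index.

    The observed MI uses summed ON vs summed OFF values. The null swaps each
    trial's ON/OFF labels independently with probability 1/2, ``n_shuffles``
    times; since per-trial totals are preserved, the null MI is
    ``sum(sign_i * d_i) / sum(total_i)`` with ``d_i = on_i - off_i``. The
    two-sided empirical p-value measures distance from the null mean:
    ``p = (1 + #{|MI0 - mean(MI0)| >= |MI_obs - mean(MI0)|}) / (n_shuffles + 1)``.
    """
    on_values = np.asarray(on_values, dtype=float)
    off_values = np.asarray(off_values, dtype=float)
    n_trials = on_values.size
    if n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} usable trials, got {n_trials}")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    total = float(on_values.sum() + off_values.sum())
    if total == 0:
        return ShuffleTestResult(unit_id=unit_id, metric_name=metric_name,
                                 observed_mi=np.nan, null_mis=np.empty(0),
                                 p_value=np.nan, affected=False, excluded=True)
    d = on_values - off_values
    obs = float(d.sum() / total)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_shuffles, n_trials)) * 2 - 1
    null = (signs @ d) / total
    center = null.mean()
    p = (1.0 + np.count_nonzero(np.abs(null - center) >= abs(obs - center))) \
        / (n_shuffles + 1.0)
    return ShuffleTestResult(unit_id=unit_id, metric_name=metric_name,
                             observed_mi=obs, null_mis=null, p_value=p,
                             affected=bool(p < alpha))


def exhaustive_shuffle_null(on_values: np.ndarray,
                            off_values: np.ndarray) -> np.ndarray:
    """Exact shuffle null by enumerating all 2^n per-trial label flips.

    Oracle for small trial counts (n <= ~16); matches what the Monte-Carlo
    null in :func:`shuffle_test` samples from.
    """
    d = np.asarray(on_values, dtype=float) - np.asarray(off_values, dtype=float)
    total = float(np.sum(on_values) + np.sum(off_values))
    n = d.size
    if n > 20:
        raise ValueError("exhaustive enumeration limited to n <= 20 trials")
    if total == 0:
        raise ValueError("all values zero: MI undefined")
    codes = np.arange(2 ** n, dtype=np.int64)
    signs = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1
    return (signs @ d) / total


def shuffle_test_set(values: EpochValues, n_shuffles: int = 1000,
                     seed: int = 0, alpha: float = 0.05,
                     min_trials: int = 20,
                     keep_null: bool = False) -> tuple[pd.DataFrame, list[ShuffleTestResult]]:
    """Run :func:`shuffle_test` for every unit of an :class:`EpochValues`.

    Trials flagged unusable for a unit are dropped before testing; units with
    fewer than ``min_trials`` usable trials, or with all-zero values, are
    excluded (NaN p). Per-unit RNG streams are spawned from ``seed``.
    """
    children = np.random.SeedSequence(seed).spawn(len(values.unit_ids))
    results = []
    rows = []
    for u, uid in enumerate(values.unit_ids):
        mask = values.usable[u]
        on = values.on_values[u, mask]
        off = values.off_values[u, mask]
        rng_seed = children[u]
        if on.size < min_trials:
            res = ShuffleTestResult(unit_id=int(uid), metric_name=values.metric_name,
                                    observed_mi=np.nan, null_mis=np.empty(0),
                                    p_value=np.nan, affected=False, excluded=True)
        else:
            res = _shuffle_test_seeded(on, off, n_shuffles, rng_seed, alpha,
                                       int(uid), values.metric_name, min_trials)
        if not keep_null:
            res.null_mis = np.empty(0)
        results.append(res)
        rows.append((res.unit_id, res.metric_name, res.observed_mi,
                     res.p_value, res.affected, res.excluded, int(on.size)))
    table = pd.DataFrame(rows, columns=["unit_id", "metric", "mi", "p_value",
                                        "affected", "excluded", "n_trials"])
    return table, results


def _shuffle_test_seeded(on, off, n_shuffles, seed_seq, alpha, unit_id,
                         metric_name, min_trials):
    # same as shuffle_test but accepting a SeedSequence for spawned streams
    total = float(on.sum() + off.sum())
    if total == 0:
        return ShuffleTestResult(unit_id=unit_id, metric_name=metric_name,
                                 observed_mi=np.nan, null_mis=np.empty(0),
                                 p_value=np.nan, affected=False, excluded=True)
    d = on - off
    obs = float(d.sum() / total)
    rng = np.random.default_rng(seed_seq)
    signs = rng.integers(0, 2, size=(n_shuffles, d.size)) * 2 - 1
    null = (signs @ d) / total
    center = null.mean()
    p = (1.0 + np.count_nonzero(np.abs(null - center) >= abs(obs - center))) \
        / (n_shuffles + 1.0)
    return ShuffleTestResult(unit_id=unit_id, metric_name=metric_name,
                             observed_mi=obs, null_mis=null, p_value=p,
                             affected=bool(p < alpha))


# ---------------------------------------------------------------------------
# population comparisons
# ---------------------------------------------------------------------------


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # fully tied: no evidence of a difference
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_conditions(stim: pd.DataFrame, sham: pd.DataFrame,
                       alpha: float = 0.05) -> dict:
    """Compare stimulation vs sham shuffle-test populations.

    Inputs are per-unit tables from :func:`shuffle_test_set` (columns ``mi``,
    ``affected``, optionally ``session``). Returns the two-sided rank-sum
    p-value on the pooled MI distributions, percent-affected per condition,
    and (when both conditions have >= 2 sessions) a rank-sum comparison of
    per-session percent-affected values.
    """
    if len(stim) == 0 or len(sham) == 0:
        raise ValueError("both condition tables must be non-empty")
    stim_mi = stim["mi"].to_numpy(float)
    sham_mi = sham["mi"].to_numpy(float)
    stim_mi = stim_mi[np.isfinite(stim_mi)]
    sham_mi = sham_mi[np.isfinite(sham_mi)]
    out = {
        "rank_sum_p_mi": _ranksum_p(stim_mi, sham_mi),
        "percent_affected_stim": 100.0 * stim["affected"].mean(),
        "percent_affected_sham": 100.0 * sham["affected"].mean(),
        "n_stim": int(len(stim)),
        "n_sham": int(len(sham)),
        "rank_sum_p_percent_affected": np.nan,
    }
    if "session" in stim.columns and "session" in sham.columns:
        ps = stim.groupby("session")["affected"].mean().to_numpy() * 100
        qs = sham.groupby("session")["affected"].mean().to_numpy() * 100
        if len(ps) >= 2 and len(qs) >= 2:
            out["rank_sum_p_percent_affected"] = _ranksum_p(ps, qs)
        else:
            warnings.warn("fewer than 2 sessions per condition: per-session "
                          "comparison skipped", stacklevel=2)
    return out


def combine_sessions(session_a: dict, session_b: dict, unit_map: dict,
                     n_shuffles: int = 1000, seed: int = 0,
                     alpha: float = 0.05, metric_name: str = "combined",
                     min_trials: int = 20) -> tuple[pd.DataFrame, list]:
    """Pool per-trial epoch values of the same neurons across two sessions.

    ``session_a``/``session_b`` map unit id -> ``(on_values, off_values)``
    per-trial arrays; ``unit_map`` maps session-a ids to session-b ids and
    must be injective. Mapped units get their trial lists concatenated before
    a fresh shuffle test; unmapped units are dropped and reported.
    """
    targets = list(unit_map.values())
    if len(set(targets)) != len(targets):
        raise ValueError("unit_map must be injective (duplicate targets)")
    dropped = [uid for uid in session_a if uid not in unit_map]
    dropped += [uid for uid in session_b if uid not in set(targets)]
    rows = []
    children = np.random.SeedSequence(seed).spawn(max(1, len(unit_map)))
    for i, (ua, ub) in enumerate(sorted(unit_map.items())):
        if ua not in session_a or ub not in session_b:
            dropped.append(ua)
            continue
        on = np.concatenate([session_a[ua][0], session_b[ub][0]])
        off = np.concatenate([session_a[ua][1], session_b[ub][1]])
        res = _shuffle_test_seeded(on, off, n_shuffles, children[i], alpha,
                                   int(ua), metric_name, min_trials)
        rows.append((res.unit_id, res.observed_mi, res.p_value, res.affected,
                     res.excluded, int(on.size)))
    table = pd.DataFrame(rows, columns=["unit_id", "mi", "p_value", "affected",
                                        "excluded", "n_trials"])
    return table, sorted(set(dropped))


# ---------------------------------------------------------------------------
# background-artifact QC
# ---------------------------------------------------------------------------


def background_artifact_qc(background, protocol: StimulusProtocol,
                           timestamps: np.ndarray | None = None,
                           n_shuffles: int = 1000, seed: int = 0,
                           alpha: float = 0.05,
                           tolerance_pct: float = 1.0) -> dict:
    """Detect stimulus-locked background-fluorescence changes.

    ``background`` is either a :class:`MovieStack` (background = per-frame
    mean of non-footprint pixels) or a 1-D per-frame background trace with
    ``timestamps``. Reports the ON-vs-OFF percent change
    ``100 * (mean_ON - mean_OFF) / mean_OFF``, a trial-shuffle p-value on the
    per-trial mean difference, and flags the session as artifact-contaminated
    when ``|%change| >= tolerance_pct``.
    """
    if isinstance(background, MovieStack):
        trace = background.background_trace()
        if timestamps is None:
            dt = protocol.session_length / trace.size
            timestamps = np.arange(trace.size) * dt
    else:
        trace = np.asarray(background, dtype=float)
        if timestamps is None:
            raise ValueError("timestamps required for a bare background trace")
    timestamps = np.asarray(timestamps, dtype=float)
    on_means, off_means = [], []
    for (s0, s1), (f0, f1) in zip(protocol.on_windows(), protocol.off_windows()):
        on_sel = (timestamps >= s0) & (timestamps < s1)
        off_sel = (timestamps >= f0) & (timestamps < f1)
        if on_sel.any() and off_sel.any():
            on_means.append(trace[on_sel].mean())
            off_means.append(trace[off_sel].mean())
    on_means = np.asarray(on_means)
    off_means = np.asarray(off_means)
    if on_means.size == 0:
        raise ValueError("no trials covered by the background trace")
    mean_on = on_means.mean()
    mean_off = off_means.mean()
    pct = 100.0 * (mean_on - mean_off) / mean_off
    # shuffle significance on the per-trial mean difference
    d = on_means - off_means
    obs = d.mean()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB6)))
    signs = rng.integers(0, 2, size=(n_shuffles, d.size)) * 2 - 1
    null = (signs @ d) / d.size
    center = null.mean()
    p = (1.0 + np.count_nonzero(np.abs(null - center) >= abs(obs - center))) \
        / (n_shuffles + 1.0)
    return {
        "percent_change": float(pct),
        "p_value": float(p),
        "significant": bool(p < alpha),
        "flagged": bool(abs(pct) >= tolerance_pct),
        "n_trials": int(d.size),
    }
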