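"""Synthetic recordings with known ground truth.

Emulates the three data streams of an intermittent-RF stimulation study:

* per-unit spike trains (inhomogeneous Poisson, optional ON-epoch rate change
  and von-Mises phase locking to an AM envelope),
* GCaMP6f-like fluorescence traces at 30 frames/s (double-exponential kernel,
  photobleaching, Gaussian noise) and small movies with an optional
  stimulus-locked background dip (1-4% of background, the signature of an
  LED-interference artifact),
* lumped-bioheat brain-temperature traces under pulsed or continuous RF.

Every generator takes one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .protocol import StimulusProtocol, am_phase, make_protocol

__all__ = [
    "PopulationSpec",
    "CalciumKernelSpec",
    "BioheatParams",
    "SpikeTrainSet",
    "FluorescenceSet",
    "MovieStack",
    "TemperatureTrace",
    "make_protocol",
    "generate_spike_trains",
    "generate_calcium",
    "generate_movie",
    "generate_temperature",
]

EFFECT_CLASSES = ("suppressed", "excited", "unaffected")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Ground-truth description of a simulated neuronal population.

    ``effect_multiplier`` is the ON/OFF firing-rate ratio per unit: exactly 1
    for unaffected units, < 1 for suppressed, > 1 for excited.
    ``phase_locking_kappa`` is the von-Mises concentration of ON-epoch spikes
    around the AM envelope peak (0 = no locking).
    """

    n_units: int
    baseline_rates: np.ndarray
    effect_class: np.ndarray
    effect_multiplier: np.ndarray
    phase_locking_kappa: np.ndarray
    cell_type_label: np.ndarray
    seed: int
    preferred_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_rates", "effect_multiplier", "phase_locking_kappa"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.n_units,)).copy())
        self.effect_class = np.broadcast_to(
            np.asarray(self.effect_class, dtype=object), (self.n_units,)).copy()
        self.cell_type_label = np.broadcast_to(
            np.asarray(self.cell_type_label, dtype=object), (self.n_units,)).copy()
        if self.preferred_phase is None:
            self.preferred_phase = np.zeros(self.n_units)
        if np.any(self.baseline_rates <= 0):
            raise ValueError("baseline_rates must be positive")
        if np.any(self.phase_locking_kappa < 0):
            raise ValueError("kappa must be >= 0")
        for cls, mult in zip(self.effect_class, self.effect_multiplier):
            if cls not in EFFECT_CLASSES:
                raise ValueError(f"unknown effect class {cls!r}")
            if cls == "unaffected" and mult != 1.0:
                raise ValueError("unaffected units must have multiplier 1")
            if cls == "suppressed" and mult >= 1.0:
                raise ValueError("suppressed units must have multiplier < 1")
            if cls == "excited" and mult <= 1.0:
                raise ValueError("excited units must have multiplier > 1")

    @classmethod
    def uniform(cls, n_units: int, rate_hz: float, multiplier: float,
                seed: int, kappa: float = 0.0,
                cell_type: str = "pyramidal") -> "PopulationSpec":
        """Population in which every unit shares the same parameters."""
        if multiplier == 1.0:
            label = "unaffected"
        elif multiplier < 1.0:
            label = "suppressed"
        else:
            label = "excited"
        return cls(
            n_units=n_units,
            baseline_rates=np.full(n_units, rate_hz),
            effect_class=np.full(n_units, label, dtype=object),
            effect_multiplier=np.full(n_units, multiplier),
            phase_locking_kappa=np.full(n_units, kappa),
            cell_type_label=np.full(n_units, cell_type, dtype=object),
            seed=seed,
        )


@dataclass
class CalciumKernelSpec:
    """Shape and noise of the simulated indicator response.

    Defaults are GCaMP6f-like: 50 ms rise, 500 ms decay, 30 frames/s. The
    baseline offset keeps raw fluorescence strictly positive so the
    median-normalised dF/F is well defined; it defaults to 10x ``noise_sd``.
    """

    rise_time: float = 0.05
    decay_time: float = 0.5
    unit_amplitude: float = 1.0
    noise_sd: float = 0.1
    bleach_time_constant: float = 5400.0
    frame_rate: float = 30.0
    background_artifact_fraction: float = 0.0
    baseline_offset: float | None = None

    def __post_init__(self) -> None:
        if not (self.decay_time > self.rise_time > 0):
            raise ValueError("need decay_time > rise_time > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.background_artifact_fraction <= 0.04):
            raise ValueError("background_artifact_fraction must lie in [0, 0.04]")
        if self.baseline_offset is None:
            self.baseline_offset = 10.0 * self.noise_sd

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Difference-of-exponentials kernel, peak-normalised to 1."""
        t = np.asarray(t, dtype=float)
        tr, td = self.rise_time, self.decay_time
        t_peak = math.log(td / tr) * tr * td / (td - tr)
        peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
        out = np.where(t >= 0, np.exp(-t / td) - np.exp(-t / tr), 0.0)
        return out / peak

    @property
    def kernel_peak_time(self) -> float:
        tr, td = self.rise_time, self.decay_time
        return math.log(td / tr) * tr * td / (td - tr)


@dataclass
class BioheatParams:
    """Single-compartment bioheat parameters.

    ``sar`` drives heating at rate SAR/C (degC/s) while RF is ON;
    ``cooling_tau`` is the Newton-cooling time constant toward the baseline
    T0 + drift_slope * t (``inf`` disables cooling, the conduction-free
    short-heating regime).
    """

    sar: float
    heat_capacity_C: float = 3646.0
    cooling_tau: float = math.inf
    baseline_temp_T0: float = 37.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.heat_capacity_C <= 0:
            raise ValueError("heat_capacity_C must be positive")
        if self.cooling_tau <= 0:
            raise ValueError("cooling_tau must be positive (or inf)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrainSet:
    """Spike times per unit with ground-truth generation labels."""

    spike_times: list[np.ndarray]
    unit_ids: np.ndarray
    ground_truth: pd.DataFrame  # baseline_rate, effect_class, multiplier, kappa, cell_type

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def to_csv(self, path: str | Path) -> None:
        frames = [
            pd.DataFrame({"unit_id": uid, "spike_time_s": st})
            for uid, st in zip(self.unit_ids, self.spike_times)
        ]
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["unit_id", "spike_time_s"])
        out.to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_csv(cls, path: str | Path,
                 ground_truth: pd.DataFrame | None = None) -> "SpikeTrainSet":
        df = pd.read_csv(path)
        for col in ("unit_id", "spike_time_s"):
            if col not in df.columns:
                raise ValueError(f"spike table {path}: missing column {col!r}")
        unit_ids = np.unique(df["unit_id"].to_numpy())
        spikes = [np.sort(df.loc[df["unit_id"] == uid, "spike_time_s"].to_numpy(float))
                  for uid in unit_ids]
        if ground_truth is None:
            ground_truth = pd.DataFrame(index=pd.Index(unit_ids, name="unit_id"))
        return cls(spike_times=spikes, unit_ids=unit_ids, ground_truth=ground_truth)


@dataclass
class FluorescenceSet:
    """Raw fluorescence matrix with frame timestamps and ground truth."""

    F: np.ndarray  # (n_units, n_frames)
    timestamps: np.ndarray  # (n_frames,)
    unit_ids: np.ndarray
    ground_truth_spikes: list[np.ndarray] | None = None
    background_trace: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.F.shape[0]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("F", data=self.F)
            f.create_dataset("timestamps_s", data=self.timestamps)
            f.create_dataset("unit_ids", data=np.asarray(self.unit_ids, dtype=np.int64))
            if self.ground_truth_spikes is not None:
                g = f.create_group("ground_truth")
                for uid, st in zip(self.unit_ids, self.ground_truth_spikes):
                    g.create_dataset(str(uid), data=st)
            if self.background_trace is not None:
                f.create_dataset("background_trace", data=self.background_trace)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FluorescenceSet":
        with h5py.File(path, "r") as f:
            F = f["F"][()]
            ts = f["timestamps_s"][()]
            uids = f["unit_ids"][()]
            gts = None
            if "ground_truth" in f:
                gts = [f["ground_truth"][str(uid)][()] for uid in uids]
            bg = f["background_trace"][()] if "background_trace" in f else None
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"{path}: timestamps_s must be strictly increasing")
        return cls(F=F, timestamps=ts, unit_ids=uids,
                   ground_truth_spikes=gts, background_trace=bg)


@dataclass
class MovieStack:
    """Small synthetic 1-photon movie with known footprints and background."""

    frames: np.ndarray  # (n_frames, H, W) uint16
    footprints: np.ndarray  # (n_units, H, W) float, unit peak 1
    on_frame_mask: np.ndarray  # (n_frames,) bool
    background_level: float
    artifact_fraction: float

    def footprint_mask(self, threshold: float = 0.05) -> np.ndarray:
        """Boolean (H, W) mask of pixels belonging to any cell footprint."""
        return (self.footprints > threshold).any(axis=0)

    def background_trace(self, threshold: float = 0.05) -> np.ndarray:
        """Per-frame mean over non-footprint pixels."""
        mask = ~self.footprint_mask(threshold)
        if not mask.any():
            raise ValueError("no background pixels outside footprints")
        return self.frames[:, mask].mean(axis=1)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames, photometric="minisblack")


@dataclass
class TemperatureTrace:
    """Brain temperature time series with RF-ON annotation."""

    time_s: np.ndarray
    temp_C: np.ndarray
    rf_on: np.ndarray  # bool per sample

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "time_s": self.time_s,
            "temp_C": self.temp_C,
            "rf_on": self.rf_on.astype(int),
        }).to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemperatureTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "temp_C", "rf_on"):
            if col not in df.columns:
                raise ValueError(f"temperature table {path}: missing column {col!r}")
        t = df["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: time_s must be strictly increasing")
        return cls(time_s=t, temp_C=df["temp_C"].to_numpy(float),
                   rf_on=df["rf_on"].to_numpy().astype(bool))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _homogeneous_poisson(rng: np.random.Generator, rate: float,
                         t0: float, t1: float) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(t0 + rng.random(n) * (t1 - t0))


def generate_spike_trains(protocol: StimulusProtocol,
                          spec: PopulationSpec) -> SpikeTrainSet:
    """Draw per-unit spike trains from an inhomogeneous Poisson process.

    Rate is ``baseline`` outside ON epochs and ``baseline * multiplier``
    inside. If the protocol carries an AM frequency and a unit has kappa > 0,
    the ON-epoch intensity is further modulated proportionally to
    ``exp(kappa * cos(phase - preferred))``, normalised by the Bessel factor
    I0(kappa) so the mean ON rate is preserved. Spikes are generated by
    thinning. Reproducible for a fixed ``spec.seed``.
    """
    if protocol.am_frequency is None and np.any(spec.phase_locking_kappa > 0):
        warnings.warn("protocol has no AM envelope: phase_locking_kappa ignored",
                      stacklevel=2)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_units)
    on_win = protocol.on_windows()
    session = protocol.session_length
    spikes: list[np.ndarray] = []
    for u in range(spec.n_units):
        rng = np.random.default_rng(children[u])
        base = spec.baseline_rates[u]
        mult = spec.effect_multiplier[u]
        kappa = spec.phase_locking_kappa[u] if protocol.am_frequency is not None else 0.0
        mu = spec.preferred_phase[u]
        parts = [_homogeneous_poisson(rng, base, 0.0, session)]
        # Carve ON epochs out of the baseline train and redraw them at the
        # modulated rate.
        bg = parts[0]
        in_on = np.zeros(bg.size, dtype=bool)
        for s, e in on_win:
            in_on |= (bg >= s) & (bg < e)
        parts[0] = bg[~in_on]
        on_rate = base * mult
        if on_rate > 0:
            for s, e in on_win:
                if kappa > 0:
                    lam_max = on_rate * math.exp(kappa) / np.i0(kappa)
                    cand = _homogeneous_poisson(rng, lam_max, s, e)
                    if cand.size:
                        phi = am_phase(cand - s, protocol.am_frequency)
                        accept = rng.random(cand.size) < (
                            on_rate * np.exp(kappa * np.cos(phi - mu)) / np.i0(kappa)
                        ) / lam_max
                        parts.append(cand[accept])
                else:
                    parts.append(_homogeneous_poisson(rng, on_rate, s, e))
        spikes.append(np.sort(np.concatenate(parts)))
    gt = pd.DataFrame({
        "baseline_rate": spec.baseline_rates,
        "effect_class": spec.effect_class,
        "effect_multiplier": spec.effect_multiplier,
        "phase_locking_kappa": spec.phase_locking_kappa,
        "cell_type": spec.cell_type_label,
    }, index=pd.Index(np.arange(spec.n_units), name="unit_id"))
    return SpikeTrainSet(spike_times=spikes,
                         unit_ids=np.arange(spec.n_units),
                         ground_truth=gt)


def generate_calcium(spikes: SpikeTrainSet, kernel: CalciumKernelSpec,
                     session_length: float, seed: int = 0) -> FluorescenceSet:
    """Render spike trains into noisy fluorescence traces.

    Each spike adds a peak-normalised double-exponential transient of
    amplitude ``unit_amplitude``; the signal (baseline offset included, since
    photobleaching attenuates the whole image) is multiplied by
    ``exp(-t / bleach_time_constant)`` and iid Gaussian noise is added.
    """
    dt = 1.0 / kernel.frame_rate
    if kernel.rise_time < dt:
        warnings.warn("frame interval exceeds rise_time: transient onset "
                      "undersampled", stacklevel=2)
    t = np.arange(0.0, session_length, dt)
    n_frames = t.size
    # kernel support: rise + 8 decay constants
    support = kernel.kernel_peak_time + 8.0 * kernel.decay_time
    n_support = int(math.ceil(support / dt)) + 1
    k_lut = kernel.kernel(np.arange(n_support + 1) * dt)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA1C)))
    F = np.empty((spikes.n_units, n_frames))
    for u, st in enumerate(spikes.spike_times):
        clean = np.zeros(n_frames)
        for ts_ in st:
            i0 = int(math.ceil(ts_ / dt))
            if i0 >= n_frames:
                continue
            i1 = min(i0 + n_support, n_frames)
            seg = t[i0:i1] - ts_
            clean[i0:i1] += kernel.unit_amplitude * kernel.kernel(seg)
        signal = clean + kernel.baseline_offset
        if math.isfinite(kernel.bleach_time_constant):
            signal = signal * np.exp(-t / kernel.bleach_time_constant)
        F[u] = signal + rng.normal(0.0, kernel.noise_sd, n_frames)
    return FluorescenceSet(F=F, timestamps=t, unit_ids=spikes.unit_ids.copy(),
                           ground_truth_spikes=[s.copy() for s in spikes.spike_times])


def generate_movie(fluor: FluorescenceSet, artifact_fraction: float,
                   protocol: StimulusProtocol, shape: tuple[int, int] = (48, 48),
                   background_level: float = 400.0, seed: int = 0,
                   footprint_sigma_px: float = 2.0) -> MovieStack:
    """Render traces into a small 16-bit movie with Gaussian-blob footprints.

    During ON epochs the uniform background is multiplied by
    ``1 - artifact_fraction``, emulating the stimulus-locked background dip
    produced by RF interference with the imaging LED.
    """
    if not (0.0 <= artifact_fraction <= 0.1):
        raise ValueError("artifact_fraction must lie in [0, 0.1]")
    h, w = shape
    n_units, n_frames = fluor.F.shape
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x30F1E)))
    yy, xx = np.mgrid[0:h, 0:w]
    margin = int(3 * footprint_sigma_px) + 1
    centers = np.column_stack([
        rng.uniform(margin, h - margin, n_units),
        rng.uniform(margin, w - margin, n_units),
    ])
    # warn on heavily overlapping footprints
    if n_units > 1:
        from scipy.spatial.distance import pdist
        if np.any(pdist(centers) < 2 * footprint_sigma_px):
            warnings.warn("cell footprints overlap substantially", stacklevel=2)
    fps = np.empty((n_units, h, w))
    for u in range(n_units):
        cy, cx = centers[u]
        fps[u] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * footprint_sigma_px ** 2))
    on_mask = np.zeros(n_frames, dtype=bool)
    for s, e in protocol.on_windows():
        on_mask |= (fluor.timestamps >= s) & (fluor.timestamps < e)
    bg = np.where(on_mask, background_level * (1.0 - artifact_fraction),
                  background_level)
    # fluorescence scaled so unit dF maps to ~20% of background
    gain = 0.2 * background_level
    frames = bg[:, None, None] + gain * np.tensordot(
        np.clip(fluor.F, 0.0, None).T, fps, axes=(1, 0))
    frames = np.clip(frames, 0, 65535).astype(np.uint16)
    return MovieStack(frames=frames, footprints=fps, on_frame_mask=on_mask,
                      background_level=background_level,
                      artifact_fraction=artifact_fraction)


def _rf_on_windows(protocol: StimulusProtocol, rf_pattern: str) -> np.ndarray:
    if rf_pattern == "intermittent":
        return protocol.on_windows()
    if rf_pattern == "continuous_50s":
        s = protocol.trial_start_times
        return np.column_stack([s, s + 50.0])
    if rf_pattern == "pulse":
        s = protocol.trial_start_times[:1]
        return np.column_stack([s, s + protocol.on_duration])
    raise ValueError(f"unknown rf_pattern {rf_pattern!r}")


def generate_temperature(protocol: StimulusProtocol, params: BioheatParams,
                         rf_pattern: str = "intermittent",
                         seed: int = 0) -> TemperatureTrace:
    """Integrate the lumped bioheat model over a session.

    Model: ``T(t) = T0 + drift_slope * t + u(t)`` with
    ``du/dt = SAR/C - u / tau`` while RF is ON and ``du/dt = -u / tau``
    otherwise. The piecewise-constant forcing is integrated exactly (matrix
    exponential of a scalar), so noiseless traces match the closed forms to
    machine precision. Gaussian measurement noise is added per sample.
    """
    dt = 1.0 / params.sample_rate
    if rf_pattern == "intermittent" and dt > protocol.on_duration:
        raise ValueError("sample interval exceeds the ON epoch duration")
    t = np.arange(0.0, protocol.session_length + 0.5 * dt, dt)
    windows = _rf_on_windows(protocol, rf_pattern)
    rf_on = np.zeros(t.size, dtype=bool)
    for s, e in windows:
        rf_on |= (t >= s) & (t < e)
    # exact piecewise integration of u between consecutive samples, splitting
    # steps at ON/OFF boundaries
    edges = np.sort(windows.ravel())
    heat_rate = params.sar / params.heat_capacity_C
    tau = params.cooling_tau

    def is_on(time: float) -> bool:
        idx = np.searchsorted(edges, time, side="right")
        return idx % 2 == 1  # inside a [start, end) window

    def advance(u: float, t0: float, t1: float) -> float:
        # split at boundaries inside (t0, t1)
        inner = edges[(edges > t0 + 1e-15) & (edges < t1 - 1e-15)]
        pts = np.concatenate([[t0], inner, [t1]])
        for a, b in zip(pts[:-1], pts[1:]):
            drive = heat_rate if is_on(0.5 * (a + b)) else 0.0
            h = b - a
            if math.isinf(tau):
                u = u + drive * h
            else:
                decay = math.exp(-h / tau)
                u = u * decay + drive * tau * (1.0 - decay)
        return u

    u = 0.0
    uu = np.empty(t.size)
    uu[0] = 0.0
    for i in range(1, t.size):
        u = advance(u, t[i - 1], t[i])
        uu[i] = u
    temp = params.baseline_temp_T0 + params.drift_slope * t + uu
    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7E39)))
        temp = temp + rng.normal(0.0, params.noise_sd, t.size)
    return TemperatureTrace(time_s=t, temp_C=temp, rf_on=rf_on)
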