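"""Session configuration, validated input loading, and pipeline reports.

A session is described by a YAML config (paths + stage parameters + seed +
condition label). ``run_pipeline`` executes whichever stages have inputs and
writes a report whose tables are byte-reproducible from (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import tifffile
import yaml

from . import __version__ as _pkg_version
from .protocol import StimulusProtocol
from .synth import SpikeTrainSet, FluorescenceSet, TemperatureTrace
from . import ephys, imaging, dosimetry

__all__ = ["SessionConfig", "SessionReport", "read_inputs", "run_pipeline",
           "run_study"]

log = logging.getLogger("rfneurostim")

_FLOAT_FMT = "%.12g"


@dataclass
class SessionConfig:
    """Paths, stage parameters and seed for one analysis session."""

    protocol_path: str | None = None
    dosimetry_protocol_path: str | None = None
    spikes_path: str | None = None
    traces_path: str | None = None
    movie_path: str | None = None
    temperature_path: str | None = None
    condition_label: str = "stimulation"
    seed: int = 0
    blank_ms: float = 20.0
    alpha: float = 0.05
    n_shuffles: int = 1000
    k_mad: float = 3.0
    metric: str = "spike_amp_sum"
    detrend_window_s: float = 30.0
    min_trials: int = 20
    r2_threshold: float = 0.95
    prestim_window_s: float = 50.0
    on_window_s: float = 50.0
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition_label not in ("stimulation", "sham"):
            raise ValueError("condition_label must be 'stimulation' or 'sham'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100")
        if self.blank_ms < 0 or self.k_mad < 0:
            raise ValueError("blank_ms and k_mad must be >= 0")
        if self.metric not in imaging.METRICS:
            raise ValueError(f"metric must be one of {imaging.METRICS}")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionReport:
    tables: dict  # name -> DataFrame
    summary: dict
    provenance: dict
    failures: list

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        payload = {"summary": self.summary, "provenance": self.provenance,
                   "failures": self.failures}
        (out / "report.json").write_text(json.dumps(payload, indent=1,
                                                    sort_keys=True, default=str))


def _require(path: str | None, kind: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{kind} file not found: {p}")
    return p


def read_inputs(config: SessionConfig) -> dict:
    """Load and schema-validate every dataset referenced by the config."""
    data: dict = {}
    if config.protocol_path:
        data["protocol"] = StimulusProtocol.from_json(
            _require(config.protocol_path, "protocol"))
    if config.spikes_path:
        data["spikes"] = SpikeTrainSet.from_csv(
            _require(config.spikes_path, "spike table"))
    if config.traces_path:
        data["fluor"] = FluorescenceSet.from_hdf5(
            _require(config.traces_path, "trace file"))
    if config.movie_path:
        frames = tifffile.imread(_require(config.movie_path, "movie"))
        if "fluor" in data and frames.shape[0] != data["fluor"].F.shape[1]:
            raise ValueError(
                f"movie {config.movie_path}: frame count {frames.shape[0]} "
                f"!= trace length {data['fluor'].F.shape[1]}")
        data["movie_frames"] = frames
    if config.dosimetry_protocol_path:
        data["dosimetry_protocol"] = StimulusProtocol.from_json(
            _require(config.dosimetry_protocol_path, "dosimetry protocol"))
    if config.temperature_path:
        data["temperature"] = TemperatureTrace.from_csv(
            _require(config.temperature_path, "temperature table"))
    return data


def run_pipeline(config: SessionConfig) -> SessionReport:
    """Run every stage for which the config provides inputs.

    Stage failures are recorded in ``failures`` and do not abort the
    remaining stages; the report tables are deterministic functions of
    (inputs, config, seed).
    """
    data = read_inputs(config)
    tables: dict = {}
    summary: dict = {"condition": config.condition_label}
    failures: list = []
    protocol = data.get("protocol")

    if "spikes" in data and protocol is not None:
        try:
            epoched = ephys.epoch_spikes(data["spikes"], protocol,
                                         blank_ms=config.blank_ms)
            tab = ephys.test_unit_response(epoched, alpha=config.alpha)
            tables["ephys_units"] = tab
            summary["ephys_n_units"] = int(len(tab))
            summary["ephys_n_affected"] = int(
                (tab.response_class != "unaffected").sum())
            if protocol.am_frequency is not None:
                tables["phase_entrainment"] = ephys.phase_entrainment(
                    data["spikes"], protocol, blank_ms=config.blank_ms)
        except Exception as err:  # noqa: BLE001 - partial report contract
            failures.append({"stage": "ephys", "error": str(err)})
            log.exception("ephys stage failed")

    if "fluor" in data and protocol is not None:
        try:
            fluor = data["fluor"]
            dff = imaging.compute_dff(fluor.F, fluor.timestamps, fluor.unit_ids)
            dff = imaging.detrend(dff, window_s=config.detrend_window_s)
            if config.metric == "auc":
                activity = dff
            else:
                dec = imaging.deconvolve(dff)
                activity = imaging.threshold_events(dec, k_mad=config.k_mad)
            values = imaging.epoch_metric(activity, protocol, config.metric)
            tab, _ = imaging.shuffle_test_set(values,
                                              n_shuffles=config.n_shuffles,
                                              seed=config.seed,
                                              alpha=config.alpha,
                                              min_trials=config.min_trials)
            tables["imaging_units"] = tab
            usable = tab[~tab.excluded]
            summary["imaging_n_units"] = int(len(tab))
            summary["imaging_n_excluded"] = int(tab.excluded.sum())
            summary["imaging_n_affected"] = int(usable.affected.sum())
            summary["imaging_percent_affected"] = (
                100.0 * float(usable.affected.mean()) if len(usable) else float("nan"))
            bg = fluor.background_trace
            if bg is not None:
                qc = imaging.background_artifact_qc(
                    bg, protocol, timestamps=fluor.timestamps,
                    n_shuffles=config.n_shuffles, seed=config.seed,
                    alpha=config.alpha)
                tables["background_qc"] = pd.DataFrame([qc])
                summary["background_flagged"] = qc["flagged"]
        except Exception as err:  # noqa: BLE001
            failures.append({"stage": "imaging", "error": str(err)})
            log.exception("imaging stage failed")

    if "temperature" in data and protocol is not None:
        try:
            constants = dosimetry.TissueConstants(**config.constants) \
                if config.constants else dosimetry.DEFAULT_CONSTANTS
            dosim_protocol = data.get("dosimetry_protocol", protocol)
            heating = dosimetry.estimate_heating(
                data["temperature"], dosim_protocol,
                prestim_window_s=config.prestim_window_s,
                on_window_s=config.on_window_s,
                r2_threshold=config.r2_threshold)
            result = dosimetry.dosimetry_from_rate(
                heating.rate_dT_dt, power_w=dosim_protocol.radiated_power,
                constants=constants)
            tables["dosimetry_trials"] = heating.per_trial
            summary["dosimetry"] = result.to_dict()
            summary["dosimetry"]["n_accepted_trials"] = heating.n_accepted
        except Exception as err:  # noqa: BLE001
            failures.append({"stage": "dosimetry", "error": str(err)})
            log.exception("dosimetry stage failed")

    provenance = {"package_version": _pkg_version, "seed": config.seed,
                  "config_hash": config.hash()}
    return SessionReport(tables=tables, summary=summary,
                         provenance=provenance, failures=failures)


def run_study(stim_config: SessionConfig,
              sham_config: SessionConfig | None = None) -> dict:
    """Run a stimulation session (and optionally its sham control) and
    compare the imaging modulation-index populations between conditions.

    Returns ``{"stimulation": SessionReport, "sham": SessionReport | None,
    "comparison": dict | None}``; the comparison stage is skipped with a
    notice when no sham config is given or either imaging table is missing.
    """
    stim_report = run_pipeline(stim_config)
    out = {"stimulation": stim_report, "sham": None, "comparison": None}
    if sham_config is None:
        log.info("no sham session configured: condition comparison skipped")
        return out
    sham_report = run_pipeline(sham_config)
    out["sham"] = sham_report
    stim_tab = stim_report.tables.get("imaging_units")
    sham_tab = sham_report.tables.get("imaging_units")
    if stim_tab is None or sham_tab is None:
        log.info("imaging table missing in a condition: comparison skipped")
        return out
    out["comparison"] = imaging.compare_conditions(
        stim_tab[~stim_tab.excluded], sham_tab[~sham_tab.excluded],
        alpha=stim_config.alpha)
    return out
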