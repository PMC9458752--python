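"""Readers/writers for the fixture formats, run configuration and the
seeded end-to-end pipeline.

Formats are deliberately plain: trial tables are CSV, ground truth is
JSON, and trace bundles are a directory with ``meta.json`` plus either
``samples.bin`` (little-endian float32, sweep-major) or a ``samples.csv``
fallback (sweep, time_s, value).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .intracellular import TraceSweep

TRIAL_COLUMNS = ["mouse_id", "unit_id", "eye", "orientation_deg", "repeat",
                 "spike_count", "stim_s", "trial_s"]
VALID_EYES = {"contra", "ipsi", "blank"}


class SchemaError(ValueError):
    """Input file does not match the declared schema."""


class CorruptionError(ValueError):
    """Header and payload of a trace bundle disagree."""


# ---------------------------------------------------------------------------
# trial tables

def write_trial_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a per-trial spike-count table."""
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    bad = set(table["eye"].unique()) - VALID_EYES
    if bad:
        raise SchemaError(f"unknown eye labels: {sorted(bad)}")
    table["mouse_id"] = table["mouse_id"].astype(str)
    table["unit_id"] = table["unit_id"].astype(str)
    return table


# ---------------------------------------------------------------------------
# trace bundles

def write_trace_bundle(path, sweeps: list, extra_meta: dict | None = None,
                       fmt: str = "bin") -> None:
    """Write sweeps to a bundle directory (binary or CSV payload)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rates = {s.sampling_rate_hz for s in sweeps}
    units = {s.units for s in sweeps}
    if len(rates) != 1 or len(units) != 1:
        raise ValueError("sweeps must share sampling rate and units")
    meta = {
        "sampling_rate_hz": rates.pop(),
        "units": units.pop(),
        "sweep_lengths": [int(s.samples.size) for s in sweeps],
        "annotations": [_jsonable(s.annotations) for s in sweeps],
        "format": fmt,
    }
    if extra_meta:
        meta["protocol"] = _jsonable(extra_meta)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if fmt == "bin":
        data = np.concatenate([s.samples for s in sweeps]).astype("<f4")
        (path / "samples.bin").write_bytes(data.tobytes())
    elif fmt == "csv":
        frames = []
        for i, s in enumerate(sweeps):
            frames.append(pd.DataFrame({
                "sweep": i, "time_s": s.time_s,
                "value": s.samples.astype(np.float32)}))
        pd.concat(frames).to_csv(path / "samples.csv", index=False)
    else:
        raise ValueError(f"unknown bundle format {fmt!r}")


def read_trace_bundle(path) -> list:
    """Read a trace bundle back into a list of ``TraceSweep``."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    lengths = meta["sweep_lengths"]
    total = sum(lengths)
    if (path / "samples.bin").exists():
        raw = np.frombuffer((path / "samples.bin").read_bytes(), dtype="<f4")
        if raw.size != total:
            raise CorruptionError(
                f"samples.bin has {raw.size} samples, header says {total}")
        flat = raw.astype(float)
    elif (path / "samples.csv").exists():
        df = pd.read_csv(path / "samples.csv")
        if len(df) != total:
            raise CorruptionError(
                f"samples.csv has {len(df)} rows, header says {total}")
        flat = df["value"].to_numpy(dtype=float)
    else:
        raise FileNotFoundError(f"no samples payload in {path}")
    sweeps, k = [], 0
    anns = meta.get("annotations", [{}] * len(lengths))
    for n, ann in zip(lengths, anns):
        sweeps.append(TraceSweep(flat[k:k + n], meta["sampling_rate_hz"],
                                 units=meta["units"], annotations=dict(ann)))
        k += n
    return sweeps


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_truth_json(obj, path) -> None:
    d = obj.to_dict() if hasattr(obj, "to_dict") else _jsonable(obj)
    Path(path).write_text(json.dumps(d, indent=1))


def read_truth_json(path, cls=None):
    d = json.loads(Path(path).read_text())
    return cls.from_dict(d) if cls is not None else d


# ---------------------------------------------------------------------------
# run configuration and pipeline

_CONFIG_KEYS = None  # populated below


@dataclass
class RunConfig:
    """Declarative configuration for a simulate-and-analyse run.

    Every analysis default is overridable here and the file round-trips
    losslessly; unknown keys are rejected so silent typos cannot change an
    analysis.
    """

    seed: int = 0
    n_mice: int = 7
    n_units: int = 30
    md_shift: float = 0.5
    contra_drive_hz: float = 8.0
    ipsi_drive_hz: float = 4.0
    baseline_hz: float = 2.0
    tuning_kappa: float = 1.5
    drive_sigma: float = 0.6
    response_mode: str = "global_pref"
    inclusion_factor: float = 1.5
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunReport:
    config: dict
    outputs: dict
    warnings: list = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return {"config": self.config, "outputs": self.outputs,
                "warnings": self.warnings, "version": self.version}

    def digest(self) -> str:
        """Deterministic hash of everything the run produced."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Simulate an ND and an MD cohort and run the full OD analysis chain.

    Deterministic for a fixed config; writes per-unit/per-mouse CSVs and a
    group JSON when ``out_dir`` is set.
    """
    from . import od, synth

    protocol = synth.StimProtocol()
    base = dict(contra_drive_hz=config.contra_drive_hz,
                ipsi_drive_hz=config.ipsi_drive_hz,
                baseline_hz=config.baseline_hz,
                tuning_kappa=config.tuning_kappa,
                drive_sigma=config.drive_sigma)
    nd_pop = synth.ODPopulation(md_shift=0.0, **base)
    md_pop = synth.ODPopulation(md_shift=config.md_shift, **base)
    nd_tab, _ = synth.gen_od_dataset(protocol, nd_pop, config.n_units,
                                     config.n_mice, seed=config.seed,
                                     mouse_prefix="nd")
    md_tab, _ = synth.gen_od_dataset(protocol, md_pop, config.n_units,
                                     config.n_mice, seed=config.seed + 1,
                                     mouse_prefix="md")
    od_cfg = od.ODConfig(response_mode=config.response_mode,
                         inclusion_factor=config.inclusion_factor)
    nd_mice = [g for _, g in nd_tab.groupby("mouse_id", sort=True)]
    md_mice = [g for _, g in md_tab.groupby("mouse_id", sort=True)]
    res = od.od_group_analysis(nd_mice, md_mice, protocol, od_cfg)

    outputs = {
        "nd_mean_cbi": float(res.nd_cbi.mean()),
        "md_mean_cbi": float(res.md_cbi.mean()),
        "nd_cbi": res.nd_cbi.tolist(),
        "md_cbi": res.md_cbi.tolist(),
        "ks_D": res.ks.statistic, "ks_p": res.ks.p,
        "cbi_t": res.cbi_t.statistic, "cbi_df": res.cbi_t.df,
        "cbi_p": res.cbi_t.p,
        "nd_category_counts": res.nd_counts.tolist(),
        "md_category_counts": res.md_counts.tolist(),
    }
    warnings = [f"mouse {m} ({c}) dropped: no included units"
                for c, m in res.dropped_mice]
    report = RunReport(config=asdict(config), outputs=outputs,
                       warnings=warnings)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trial_table(nd_tab, out / "nd_trials.csv")
        write_trial_table(md_tab, out / "md_trials.csv")
        (out / "group_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))
    return report
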