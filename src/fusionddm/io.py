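"""Plain-text exchange formats: trial tables (TSV), run-configs (YAML) and
evidence traces (two-column delimited text)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stage_one import StageOneParams
from .stage_two import StageTwoParams
from .stimuli import StimulusSchedule, make_fusion_schedule

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_run_config",
    "write_run_config",
    "schedule_to_config",
    "schedule_from_config",
    "stage_one_from_config",
    "stage_one_to_config",
    "stage_two_from_config",
    "stage_two_to_config",
    "write_evidence_trace",
]

TRIAL_COLUMNS = ["observer_id", "condition_label", "choice", "rt_ms"]


def write_trial_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in TRIAL_COLUMNS
    ]
    table[cols].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"condition_label", "choice", "rt_ms"} - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    return table


def write_run_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_run_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def schedule_to_config(d_a: float, d_b: float, isi: float = 0.0, condition_label=None) -> dict:
    cfg = {"d_a_ms": d_a, "isi_ms": isi, "d_b_ms": d_b}
    if condition_label is not None:
        cfg["condition_label"] = condition_label
    return cfg


def schedule_from_config(cfg: dict) -> StimulusSchedule:
    return make_fusion_schedule(
        float(cfg["d_a_ms"]),
        float(cfg["d_b_ms"]),
        float(cfg.get("isi_ms", 0.0)),
        cfg.get("condition_label"),
    )


def stage_one_to_config(p: StageOneParams) -> dict:
    return {"tau_ms": p.tau, "k": p.k, "delta_ms": p.delta, "T2_ms": p.T2}


def stage_one_from_config(cfg: dict) -> StageOneParams:
    return StageOneParams(
        tau=float(cfg["tau_ms"]),
        k=float(cfg["k"]),
        delta=float(cfg.get("delta_ms", 0.0)),
        T2=float(cfg.get("T2_ms", 100.0)),
    )


def stage_two_to_config(p: StageTwoParams) -> dict:
    return asdict(p)


def stage_two_from_config(cfg: dict) -> StageTwoParams:
    return StageTwoParams(**{k: float(v) for k, v in cfg.items()})


def write_evidence_trace(times: np.ndarray, values: np.ndarray, path) -> None:
    pd.DataFrame({"time_ms": times, "E": values}).to_csv(path, sep="\t", index=False)
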