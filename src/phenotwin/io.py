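"""Screen dataset container, file formats and run configuration.

A screen is a table of motion-index traces (one row per well) plus well
metadata (plate, row, column, treatment, role, replicate).  Two on-disk
dialects are supported:

* ``csv`` — a single CSV with metadata columns followed by one column per
  frame (``f0 … fN-1``); practical for small fixtures.
* ``npy`` — a directory holding ``wells.csv`` (metadata), ``traces.npy``
  (wells × frames float array) and ``meta.json`` (provenance + stimulus
  schedule); practical at the canonical 101,250-frame scale.

Well coordinates are 0-based row/column internally; "B03"-style names are
accepted on input and normalized.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenDataset",
    "RunConfig",
    "ROLE_DRUG",
    "ROLE_VEHICLE",
    "ROLE_LETHAL",
    "parse_well_name",
    "format_well_name",
    "read_screen",
    "write_screen",
    "load_config",
    "save_config",
    "config_hash",
]

ROLE_DRUG = "drug"
ROLE_VEHICLE = "vehicle"
ROLE_LETHAL = "lethal"

WELL_METADATA_COLUMNS = ["well_id", "plate_id", "row", "col",
                         "treatment_id", "role", "replicate_index"]

_WELL_NAME_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


def parse_well_name(name: str) -> tuple[int, int]:
    """'B03' -> (1, 2): 0-based (row, col)."""
    m = _WELL_NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unrecognized well name {name!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if not (0 <= col < 12):
        raise ValueError(f"well column out of range in {name!r}")
    return row, col


def format_well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


@dataclass
class ScreenDataset:
    """Trace table + well metadata for one screen.

    ``traces`` is a (n_wells, n_frames) float array; ``wells`` a DataFrame
    with :data:`WELL_METADATA_COLUMNS`, row-aligned with ``traces``.
    """

    traces: np.ndarray
    wells: pd.DataFrame
    schedule: object | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D wells x frames array")
        if len(self.wells) != self.traces.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.wells)}) != trace rows ({self.traces.shape[0]})")
        if self.wells["well_id"].duplicated().any():
            dup = self.wells.loc[self.wells["well_id"].duplicated(), "well_id"].iloc[0]
            raise ValueError(f"duplicate well id {dup!r}")
        coords = self.wells[["plate_id", "row", "col"]]
        if coords.duplicated().any():
            bad = coords[coords.duplicated()].iloc[0]
            raise ValueError(f"duplicate well position plate={bad.plate_id} "
                             f"row={bad.row} col={bad.col}")

    @property
    def n_wells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def indices_for_role(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.wells["role"] == role).to_numpy())

    def indices_for_treatment(self, treatment_id: str) -> np.ndarray:
        return np.flatnonzero((self.wells["treatment_id"] == treatment_id).to_numpy())

    def drug_ids(self) -> list[str]:
        mask = self.wells["role"] == ROLE_DRUG
        return sorted(self.wells.loc[mask, "treatment_id"].unique())

    def copy(self) -> "ScreenDataset":
        return ScreenDataset(traces=self.traces.copy(), wells=self.wells.copy(),
                             schedule=self.schedule, provenance=dict(self.provenance))


def _normalize_wells(df: pd.DataFrame) -> pd.DataFrame:
    """Accept 'well' name columns or 1-based coordinates; emit 0-based rows."""
    df = df.copy()
    if "row" not in df.columns and "well" in df.columns:
        rows, cols = zip(*(parse_well_name(w) for w in df["well"]))
        df["row"], df["col"] = rows, cols
    if df.get("coordinate_base", pd.Series(dtype=int)).eq(1).any():
        df["row"] -= 1
        df["col"] -= 1
        df = df.drop(columns=["coordinate_base"])
    missing = [c for c in WELL_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well metadata missing columns {missing}")
    return df[WELL_METADATA_COLUMNS].reset_index(drop=True)


def _schedule_to_dict(schedule) -> dict | None:
    if schedule is None:
        return None
    if hasattr(schedule, "to_dict"):
        return schedule.to_dict()
    return dict(schedule)


def write_screen(dataset: ScreenDataset, path: str | Path, dialect: str = "npy") -> Path:
    """Write a screen; returns the path written (a directory for ``npy``)."""
    path = Path(path)
    meta = {"provenance": dataset.provenance,
            "schedule": _schedule_to_dict(dataset.schedule)}
    if dialect == "npy":
        path.mkdir(parents=True, exist_ok=True)
        dataset.wells.to_csv(path / "wells.csv", index=False)
        np.save(path / "traces.npy", dataset.traces)
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        return path
    if dialect == "csv":
        frames = pd.DataFrame(dataset.traces,
                              columns=[f"f{i}" for i in range(dataset.n_frames)])
        out = pd.concat([dataset.wells.reset_index(drop=True), frames], axis=1)
        out.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
        return path
    raise ValueError(f"unknown screen dialect {dialect!r}")


def read_screen(path: str | Path, dialect: str | None = None) -> ScreenDataset:
    path = Path(path)
    if dialect is None:
        dialect = "npy" if path.is_dir() else "csv"
    if dialect == "npy":
        wells = _normalize_wells(pd.read_csv(path / "wells.csv"))
        traces = np.load(path / "traces.npy")
        meta_path = path / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    elif dialect == "csv":
        raw = pd.read_csv(path)
        frame_cols = [c for c in raw.columns if re.fullmatch(r"f\d+", c)]
        frame_cols.sort(key=lambda c: int(c[1:]))
        traces = raw[frame_cols].to_numpy(dtype=float)
        wells = _normalize_wells(raw.drop(columns=frame_cols))
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    else:
        raise ValueError(f"unknown screen dialect {dialect!r}")
    schedule = None
    if meta.get("schedule"):
        from .synthetic_data import StimulusSchedule
        schedule = StimulusSchedule.from_dict(meta["schedule"])
    return ScreenDataset(traces=traces, wells=wells, schedule=schedule,
                         provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# Run configuration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "phenotwin-out",
    "sim": {},                      # SimConfig field overrides
    "filter": {"mode": "ternary", "n_trees": 500, "split_fraction": 0.8},
    "pairs": {"fraction": 0.8, "quota_pos_ctrl": 0.25, "quota_neg_ctrl": 0.25},
    "model": {"architecture": "twin_nn"},  # TwinModelConfig overrides
    "eval": {"knn_k": 15, "top_n": 50, "umap_neighbors": 10, "umap_min_dist": 0.1},
    "stress": {"window": 11, "cutoffs": [2.0, 5.2]},
    "phenosearch": {"top_k": 500,
                    "thresholds": {"target_sim": 0.2, "struct_dist": 0.5,
                                   "pheno_dist": 0.3}},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Nested configuration for the whole pipeline; unspecified keys default."""

    values: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    def section(self, name: str) -> dict:
        return self.values.get(name, {})

    @property
    def seed(self) -> int:
        return int(self.values.get("seed", 0))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    values = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        values = _deep_update(values, loaded)
    if overrides:
        values = _deep_update(values, overrides)
    return RunConfig(values=values)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.values, sort_keys=True))
    return path


def config_hash(config: RunConfig | dict) -> str:
    values = config.values if isinstance(config, RunConfig) else config
    blob = json.dumps(values, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
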