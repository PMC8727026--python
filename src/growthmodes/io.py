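"""CSV and config I/O.

Two tabular schemas are supported:

* per-cycle table — columns ``generation, Lb_um, Ld_um, Td_min, rate,
  Ti_min, Tn_min, n_origins`` (empty fields for absent values);
* trajectory table (long format) — ``generation, t_min, L_um, extended``.

Real mother-machine exports with other column names can be read through
a remapping table (``colmap={"their_name": "canonical_name"}``).
Configs are flat key/value files (YAML subset) whose keys mirror the
parameter dataclass fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .params import ConstrictionParams, ModelParams, ReplicationParams
from .records import (
    CYCLE_COLUMNS,
    TRAJECTORY_COLUMNS,
    CellCycleRecord,
    Trajectory,
    frame_to_records,
    records_to_frame,
    trajectories_to_frame,
)

__all__ = [
    "write_cycles_csv",
    "read_cycles_csv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "load_config",
    "params_from_config",
]

_LENGTH_FMT = "%.6g"


def write_cycles_csv(records: Sequence[CellCycleRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format=_LENGTH_FMT)


def read_cycles_csv(
    path: str | Path, colmap: Optional[Mapping[str, str]] = None
) -> list[CellCycleRecord]:
    """Read a per-cycle table; ``colmap`` remaps foreign column names."""
    df = pd.read_csv(path)
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = {"generation", "Lb_um", "Ld_um", "Td_min", "rate"} - set(df.columns)
    if missing:
        raise ValueError(f"per-cycle table missing columns: {sorted(missing)}")
    for col in CYCLE_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    return frame_to_records(df[CYCLE_COLUMNS])


def write_trajectories_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False, float_format=_LENGTH_FMT)


def read_trajectories_csv(
    path: str | Path,
    cycles: Optional[Sequence[CellCycleRecord]] = None,
    colmap: Optional[Mapping[str, str]] = None,
) -> list[Trajectory]:
    """Read a long-format trajectory table back into Trajectory objects.

    ``Td`` per trajectory is taken from the matching cycle record when
    ``cycles`` is given, otherwise from the last non-extended sample
    time (exact for simulated grids, a lower bound for real data).
    """
    df = pd.read_csv(path)
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = set(TRAJECTORY_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    if "extended" not in df.columns:
        df["extended"] = 0
    td_by_gen = {c.generation: c.Td for c in cycles} if cycles else {}
    out: list[Trajectory] = []
    for gen, grp in df.groupby("generation", sort=True):
        grp = grp.sort_values("t_min")
        in_cycle = grp.loc[grp["extended"] == 0, "t_min"]
        td = td_by_gen.get(gen, float(in_cycle.max()) if len(in_cycle) else float("nan"))
        extended = bool((grp["extended"] == 1).any())
        window = float(grp["t_min"].max()) - td if extended else 0.0
        out.append(
            Trajectory(
                cycle_ref=int(gen),
                times=grp["t_min"].to_numpy(dtype=float),
                lengths=grp["L_um"].to_numpy(dtype=float),
                Td=td,
                post_division_window=max(window, 0.0),
                is_extended=extended,
            )
        )
    return out


def load_config(path: str | Path) -> dict:
    """Load a flat key/value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping of key: value pairs")
    return cfg


def params_from_config(
    cfg: Mapping,
) -> tuple[ModelParams, Optional[ReplicationParams], Optional[ConstrictionParams]]:
    """Build parameter objects from a flat config mapping.

    Keys mirroring :class:`ModelParams` fields go to the model;
    replication keys (``delta_ii_*``, ``cd_*``, ``dt``) and constriction
    keys (``delta_bn_*``, ``delta_nd_*``) build the optional parameter
    sets when any of them is present.
    """
    model = ModelParams.from_dict(cfg)
    rep_keys = {"delta_ii_mean", "delta_ii_cv", "cd_mean", "cd_cv", "dt"}
    con_keys = {"delta_bn_mean", "delta_bn_cv", "delta_nd_mean", "delta_nd_cv"}
    rep = None
    if rep_keys & set(cfg):
        rep = ReplicationParams(**{k: cfg[k] for k in rep_keys & set(cfg)})
    con = None
    if con_keys & set(cfg):
        con = ConstrictionParams(**{k: cfg[k] for k in con_keys & set(cfg)})
    return model, rep, con
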