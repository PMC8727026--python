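"""Per-cycle records, sampled trajectories, and their tabular views."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

#: canonical per-cycle CSV column order
CYCLE_COLUMNS = [
    "generation",
    "Lb_um",
    "Ld_um",
    "Td_min",
    "rate",
    "Ti_min",
    "Tn_min",
    "n_origins",
]

#: canonical long-format trajectory CSV column order
TRAJECTORY_COLUMNS = ["generation", "t_min", "L_um", "extended"]


@dataclass
class CellCycleRecord:
    """One generation: birth/division lengths (um), timing (min), rate.

    ``rate`` is the per-cycle exponential growth rate (1/min) or the
    absolute elongation speed (um/min) in linear mode; for the
    super-exponential model it is the initial rate lambda_0.  ``Ti`` and
    ``Tn`` are replication-initiation and constriction times measured
    from birth, when the model provides them.
    """

    generation: int
    Lb: float
    Ld: float
    Td: float
    rate: float
    Ti: Optional[float] = None
    Tn: Optional[float] = None
    n_origins: Optional[int] = None


class Lineage(List[CellCycleRecord]):
    """A sequence of cell-cycle records with simulation bookkeeping.

    Behaves as a plain list of :class:`CellCycleRecord`; ``n_rejected``
    counts the reject-and-resample events of the run that produced it.
    """

    def __init__(self, records: Iterable[CellCycleRecord] = (), n_rejected: int = 0):
        super().__init__(records)
        self.n_rejected = n_rejected


@dataclass
class Trajectory:
    """Length-vs-time samples for one cycle on a fixed time grid.

    ``times`` start at 0 (birth) and advance in steps of the sampling
    interval; in-cycle samples satisfy ``t <= Td``.  When
    ``is_extended``, samples past ``Td`` hold the summed length of the
    two daughters.
    """

    cycle_ref: int
    times: np.ndarray
    lengths: np.ndarray
    Td: float
    post_division_window: float = 0.0
    is_extended: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must have equal length")

    @property
    def ages(self) -> np.ndarray:
        return self.times / self.Td


def records_to_frame(records: Sequence[CellCycleRecord]) -> pd.DataFrame:
    """Tabulate cycle records with the canonical column layout."""
    return pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "Lb_um": [r.Lb for r in records],
            "Ld_um": [r.Ld for r in records],
            "Td_min": [r.Td for r in records],
            "rate": [r.rate for r in records],
            "Ti_min": [np.nan if r.Ti is None else r.Ti for r in records],
            "Tn_min": [np.nan if r.Tn is None else r.Tn for r in records],
            "n_origins": [np.nan if r.n_origins is None else r.n_origins for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> List[CellCycleRecord]:
    """Inverse of :func:`records_to_frame` (NaN -> absent)."""
    out: List[CellCycleRecord] = []
    for row in df.itertuples(index=False):
        ti = getattr(row, "Ti_min", np.nan)
        tn = getattr(row, "Tn_min", np.nan)
        no = getattr(row, "n_origins", np.nan)
        out.append(
            CellCycleRecord(
                generation=int(row.generation),
                Lb=float(row.Lb_um),
                Ld=float(row.Ld_um),
                Td=float(row.Td_min),
                rate=float(row.rate),
                Ti=None if pd.isna(ti) else float(ti),
                Tn=None if pd.isna(tn) else float(tn),
                n_origins=None if pd.isna(no) else int(no),
            )
        )
    return out


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format table of trajectory samples."""
    parts = []
    for tr in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "generation": tr.cycle_ref,
                    "t_min": tr.times,
                    "L_um": tr.lengths,
                    "extended": (tr.times > tr.Td).astype(int),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(parts, ignore_index=True)
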