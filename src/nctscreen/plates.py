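"""Plate layouts and plate-map I/O.

A plate map assigns each well of a 96-well plate a role (control arm or
test compound). Control roles used by the screen:

- ``vehicle_neg``: DMSO vehicle, no toxic dipeptide — the assay's
  negative control and the min anchor of the screen normalization.
- ``lmb_pos``: leptomycin-b exposed wells (XPO1 export blocked, full
  nuclear accumulation) — the positive control used for the Z' gate.
- ``empty_vector``: pcDNA3.1+ empty-vector transfection control.
- ``pr_control``: PR dipeptide-expressing wells without compound — the
  max anchor of the screen normalization (maximal transport disruption).
- ``test``: PR-expressing wells treated with a library compound.

DSB-assay cohorts use ``dsb_*`` roles and are laid out elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

ROLES = frozenset(
    {"vehicle_neg", "lmb_pos", "empty_vector", "pr_control", "test"}
)

WELL_RE = re.compile(r"^[A-H](0?[1-9]|1[0-2])$")

PLATEMAP_COLUMNS = ["plate", "well", "role", "compound_id", "dose"]


class PlateMapError(ValueError):
    """Raised for malformed or inconsistent plate maps."""


def _canon_well(well: str) -> str:
    """Normalize a well id to zero-padded form (A1 -> A01)."""
    well = well.strip().upper()
    if not WELL_RE.match(well):
        raise PlateMapError(f"malformed well id: {well!r}")
    return f"{well[0]}{int(well[1:]):02d}"


@dataclass
class PlateLayout:
    """One plate's well -> (role, compound, dose) assignment."""

    plate: str
    wells: pd.DataFrame = field(repr=False)  # columns: well, role, compound_id, dose

    def __post_init__(self) -> None:
        df = self.wells
        missing = {"well", "role"} - set(df.columns)
        if missing:
            raise PlateMapError(f"layout missing columns: {sorted(missing)}")
        df = df.copy()
        df["well"] = df["well"].map(_canon_well)
        if df["well"].duplicated().any():
            dupes = sorted(df.loc[df["well"].duplicated(), "well"])
            raise PlateMapError(f"duplicate wells in plate {self.plate}: {dupes}")
        bad = set(df["role"]) - ROLES - {r for r in set(df["role"]) if str(r).startswith("dsb_")}
        if bad:
            raise PlateMapError(f"unknown roles: {sorted(map(str, bad))}")
        for col in ("compound_id", "dose"):
            if col not in df.columns:
                df[col] = None
        self.wells = df.reset_index(drop=True)

    def roles(self) -> set[str]:
        return set(self.wells["role"])

    def wells_with_role(self, role: str) -> list[str]:
        return list(self.wells.loc[self.wells["role"] == role, "well"])

    def role_of(self, well: str) -> str:
        row = self.wells.loc[self.wells["well"] == _canon_well(well)]
        if row.empty:
            raise PlateMapError(f"well {well!r} not in plate {self.plate}")
        return str(row["role"].iloc[0])

    def __len__(self) -> int:
        return len(self.wells)

    def to_frame(self) -> pd.DataFrame:
        out = self.wells.copy()
        out.insert(0, "plate", self.plate)
        return out[PLATEMAP_COLUMNS]


def read_platemap(path) -> list[PlateLayout]:
    """Read a plate-map CSV (``plate,well,role,compound_id,dose``).

    Returns one :class:`PlateLayout` per distinct plate id. Duplicate
    wells within a plate, malformed well ids and unknown roles raise
    :class:`PlateMapError`.
    """
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "role": str})
    missing = {"plate", "well", "role"} - set(df.columns)
    if missing:
        raise PlateMapError(f"plate map missing columns: {sorted(missing)}")
    layouts = []
    for plate, grp in df.groupby("plate", sort=True):
        layouts.append(PlateLayout(plate=str(plate), wells=grp.drop(columns=["plate"])))
    return layouts


def default_screen_layout(plate: str = "P1") -> PlateLayout:
    """The default 96-well screening layout.

    Columns 1-2 hold the four control arms (4 wells each: vehicle_neg and
    lmb_pos in column 1, empty_vector and pr_control in column 2); columns
    3-12 hold 80 test wells with compound ids ``C001``..``C080``.
    """
    rows = "ABCDEFGH"
    records = []
    for i, r in enumerate(rows):
        records.append((f"{r}01", "vehicle_neg" if i < 4 else "lmb_pos", None, None))
        records.append((f"{r}02", "empty_vector" if i < 4 else "pr_control", None, None))
    k = 0
    for col in range(3, 13):
        for r in rows:
            k += 1
            records.append((f"{r}{col:02d}", "test", f"C{k:03d}", 3.0))
    wells = pd.DataFrame(records, columns=["well", "role", "compound_id", "dose"])
    return PlateLayout(plate=plate, wells=wells)
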