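"""Per-cell and per-well screen statistics: outlier removal, DPR-positive
calling, well summaries, 2-SD well filters, and the Z' plate-quality gate.

Conventions (documented once, used throughout):

- Sample statistics use the n-1 denominator.
- The +/-3-SD GFP outlier fences are computed per well (the analysis
  unit), from the plain mean/SD of valid cells, in a single pass.
- Well-level toxicity / expression filters compare each well's invalid
  and DPR-positive counts to the plate mean +/- 2 SD over all
  non-excluded wells (controls included).
- Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n| over control-well
  translocation indices; the absolute separation makes the statistic
  orientation-free. Plates pass at Z' >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plates import PlateLayout

#: minimum retained cells for a defined well translocation index
MIN_CELLS_PER_WELL = 10


class ControlError(ValueError):
    """Control wells missing or degenerate for the requested statistic."""


@dataclass(frozen=True)
class DprThresholds:
    """Intensity cutoffs calling a cell DPR-positive from its circle
    and/or ring immunostain means. ``rule='either'`` (the default)
    covers both nuclear (PR/GR) and cytoplasmic (GA) species."""

    circle_min: float = 0.0
    ring_min: float = 0.0
    rule: str = "either"  # "either" | "both"

    def __post_init__(self) -> None:
        if self.rule not in ("either", "both"):
            raise ValueError("rule must be 'either' or 'both'")
        if self.circle_min < 0 or self.ring_min < 0:
            raise ValueError("thresholds must be >= 0")


def remove_gfp_outliers(cells: pd.DataFrame, k: float = 3.0,
                        *, group_by: str = "well") -> pd.DataFrame:
    """Flag cells whose circle OR ring GFP mean is outside mean +/- k*SD.

    Fences are computed over the valid cells of each group (``well`` by
    default, ``plate`` optionally); outliers keep their rows but are
    excluded from well averaging. Zero-variance groups produce no
    outliers, and groups with fewer than two valid cells are left
    unflagged.
    """
    if group_by not in ("well", "plate"):
        raise ValueError("group_by must be 'well' or 'plate'")
    out = cells.copy()
    out["is_outlier"] = False
    keys = ["plate", group_by] if group_by != "plate" else ["plate"]
    keys = [c for c in dict.fromkeys(keys) if c in out.columns]
    for _, idx in out.groupby(keys, dropna=False).groups.items():
        sub = out.loc[idx]
        valid = sub[sub["is_valid"]]
        if len(valid) < 2:
            continue
        flags = np.zeros(len(sub), dtype=bool)
        for col in ("circle_gfp", "ring_gfp"):
            mu = valid[col].mean()
            sd = valid[col].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                continue
            vals = sub[col].to_numpy()
            flags |= (vals < mu - k * sd) | (vals > mu + k * sd)
        out.loc[idx, "is_outlier"] = flags & sub["is_valid"].to_numpy()
    return out


def call_dpr_positive(cells: pd.DataFrame,
                      thresholds: DprThresholds) -> pd.DataFrame:
    """Set ``is_dpr_positive`` from the configured circle/ring cutoffs."""
    for col in ("circle_dpr", "ring_dpr"):
        if col not in cells.columns:
            raise ValueError(
                "DPR thresholds configured but no DPR channel in cell table")
    out = cells.copy()
    circle_hit = out["circle_dpr"] >= thresholds.circle_min
    ring_hit = out["ring_dpr"] >= thresholds.ring_min
    if thresholds.rule == "either":
        out["is_dpr_positive"] = circle_hit | ring_hit
    else:
        out["is_dpr_positive"] = circle_hit & ring_hit
    return out


WELL_COLUMNS = [
    "plate", "well", "role", "compound_id", "dose",
    "n_cells_valid", "n_invalid", "n_dpr_positive",
    "ti_raw", "ti_norm", "excluded", "toxic", "low_expression",
]


def summarize_wells(cells: pd.DataFrame, layout: PlateLayout,
                    *, min_cells: int = MIN_CELLS_PER_WELL) -> pd.DataFrame:
    """Aggregate a cell table to per-well records.

    ``ti_raw`` is the mean translocation index over retained cells
    (valid and not outlier); wells with fewer than ``min_cells``
    retained cells are marked excluded with an undefined index. Every
    layout well appears in the output, even when it received no cells.
    """
    known = set(layout.wells["well"])
    cell_wells = set(cells["well"].unique()) if len(cells) else set()
    unknown = cell_wells - known
    if unknown:
        raise ValueError(f"cells reference wells not in layout: {sorted(unknown)}")

    has_dpr_flag = "is_dpr_positive" in cells.columns
    grouped = dict(tuple(cells.groupby("well"))) if len(cells) else {}
    rows = []
    for _, wrow in layout.wells.sort_values("well").iterrows():
        well = wrow["well"]
        sub = grouped.get(well)
        if sub is None:
            sub = cells.iloc[0:0]
        valid = sub[sub["is_valid"]]
        retained = valid[~valid["is_outlier"]] if "is_outlier" in valid.columns else valid
        n_valid = len(valid)
        excluded = len(retained) < min_cells
        rows.append({
            "plate": layout.plate, "well": well,
            "role": wrow["role"], "compound_id": wrow["compound_id"],
            "dose": wrow["dose"],
            "n_cells_valid": n_valid,
            "n_invalid": int((~sub["is_valid"]).sum()),
            "n_dpr_positive": int(valid["is_dpr_positive"].sum()) if has_dpr_flag and n_valid else 0,
            "ti_raw": float(retained["translocation_index"].mean()) if not excluded else np.nan,
            "ti_norm": np.nan,
            "excluded": excluded,
            "toxic": False,
            "low_expression": False,
        })
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def flag_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Apply the 2-SD well filters.

    ``toxic``: invalid-object count above plate mean + 2 SD (assumed
    cytotoxicity). ``low_expression``: DPR-positive count below plate
    mean - 2 SD (insufficient DPR expression). Statistics are taken over
    all non-excluded wells of each plate, controls included. Flagged
    wells are retained but are not considered during hit identification.
    """
    out = wells.copy()
    for plate, idx in out.groupby("plate").groups.items():
        sub = out.loc[idx]
        pool = sub[~sub["excluded"]]
        if len(pool) < 3:
            import warnings
            warnings.warn(f"plate {plate}: fewer than 3 wells, 2-SD flags not computed")
            continue
        mu_inv, sd_inv = pool["n_invalid"].mean(), pool["n_invalid"].std(ddof=1)
        mu_dpr, sd_dpr = pool["n_dpr_positive"].mean(), pool["n_dpr_positive"].std(ddof=1)
        toxic = (sub["n_invalid"] > mu_inv + 2 * sd_inv) & ~sub["excluded"]
        low = (sub["n_dpr_positive"] < mu_dpr - 2 * sd_dpr) & ~sub["excluded"]
        out.loc[idx, "toxic"] = toxic
        out.loc[idx, "low_expression"] = low
    return out


def z_prime_from_stats(mu_p: float, sigma_p: float,
                       mu_n: float, sigma_n: float) -> float:
    """Evaluate Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n| from control
    summary statistics."""
    if mu_p == mu_n:
        raise ControlError("controls not separated (mu_p == mu_n)")
    return 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)


def z_prime(pos_values, neg_values) -> float:
    """Plate-quality statistic Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|.

    ``pos_values`` / ``neg_values`` are the well-level translocation
    indices of the positive (export-blocked) and negative (vehicle)
    control arms; sample SDs use n-1. Z' <= 1 always; >= 0.5 marks a
    robust assay. Equal control means raise :class:`ControlError`.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ControlError("need >= 2 wells per control arm")
    return z_prime_from_stats(pos.mean(), pos.std(ddof=1),
                              neg.mean(), neg.std(ddof=1))


@dataclass
class PlateQCReport:
    plate: str
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    z_prime: float
    passed: bool
    well_flags: pd.DataFrame = field(repr=False)


def qc_plate(wells: pd.DataFrame, *, pos_role: str = "lmb_pos",
             neg_role: str = "vehicle_neg", gate: float = 0.5) -> PlateQCReport:
    """Compute the plate's Z' from its control wells and gate at >= 0.5.

    Plates failing the gate are removed from further (hit) analysis by
    the pipeline; the report records the control summaries and the
    per-well flag table either way.
    """
    plates = wells["plate"].unique()
    if len(plates) != 1:
        raise ValueError("qc_plate expects wells from a single plate")
    plate = str(plates[0])
    pos = wells[(wells["role"] == pos_role) & ~wells["excluded"]]["ti_raw"]
    neg = wells[(wells["role"] == neg_role) & ~wells["excluded"]]["ti_raw"]
    if len(pos) < 2 or len(neg) < 2:
        raise ControlError(
            f"plate {plate}: missing control arm ({pos_role}: {len(pos)}, "
            f"{neg_role}: {len(neg)})")
    zp = z_prime(pos, neg)
    flag_cols = ["well", "role", "excluded", "toxic", "low_expression"]
    return PlateQCReport(
        plate=plate,
        mu_p=float(pos.mean()), sigma_p=float(pos.std(ddof=1)),
        mu_n=float(neg.mean()), sigma_n=float(neg.std(ddof=1)),
        z_prime=float(zp), passed=bool(zp >= gate),
        well_flags=wells[flag_cols].reset_index(drop=True),
    )
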