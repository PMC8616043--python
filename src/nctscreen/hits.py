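"""Control normalization, per-well Z-factor scoring and hit calling.

The screen's readout chain per plate:

1. ``normalize_minmax``: min-max scale each well's translocation index
   to the in-plate control anchors, ti_norm = 100*(ti - m)/(M - m),
   where m / M are the mean indices of the min-anchor (vehicle) and
   max-anchor (PR or export-blocked) control wells. Anchor wells land
   at 0% and 100% by construction.
2. ``z_factor_scores``: per-well Z = (X - mu)/sigma against the mean
   and sample SD of all eligible test wells on the plate (flagged or
   excluded wells contribute to neither X nor mu/sigma).
3. ``call_hits``: a well is a hit when Z < -1.96 (the lower 2.5%
   normal quantile), it is unflagged, and its viability — valid-cell
   count as a percent of the PR-control mean — clears the floor. The
   top ``top_k`` hits are ranked by ascending Z, ties broken by higher
   viability then compound id.
4. ``confirm_hits``: replicate-level comparison of each compound against
   the PR control (Welch's t, Holm-adjusted) with direction and
   viability summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ControlError

#: default hit cut: lower 2.5% standard-normal quantile, 2 decimals
DEFAULT_HIT_THRESHOLD = -1.96


def default_hit_threshold() -> float:
    """Recompute the hit cut from the inverse normal CDF (rounded to 2
    decimals): the two-sided 5% point, lower tail."""
    return round(float(stats.norm.ppf(0.025)), 2)


@dataclass(frozen=True)
class NormalizationSpec:
    """Which control roles anchor 0% and 100% of the normalized scale."""

    min_role: str = "vehicle_neg"
    max_role: str = "pr_control"

    def __post_init__(self) -> None:
        if self.min_role == self.max_role:
            raise ValueError("min_role and max_role must differ")


def normalize_minmax(wells: pd.DataFrame,
                     spec: NormalizationSpec | None = None) -> pd.DataFrame:
    """Min-max normalize ``ti_raw`` to in-plate control anchors (percent).

    Applied per plate to every well, controls included. Raises
    :class:`ControlError` when an anchor role has no non-excluded well
    or the anchor means coincide (degenerate window).
    """
    spec = spec or NormalizationSpec()
    out = wells.copy()
    for plate, idx in out.groupby("plate").groups.items():
        sub = out.loc[idx]
        anchors = {}
        for role in (spec.min_role, spec.max_role):
            vals = sub[(sub["role"] == role) & ~sub["excluded"]]["ti_raw"]
            if len(vals) < 1:
                raise ControlError(f"plate {plate}: no usable {role!r} anchor wells")
            anchors[role] = float(vals.mean())
        m, big_m = anchors[spec.min_role], anchors[spec.max_role]
        if big_m == m:
            raise ControlError(f"plate {plate}: degenerate normalization window")
        out.loc[idx, "ti_norm"] = 100.0 * (sub["ti_raw"] - m) / (big_m - m)
    return out


def _eligible(wells: pd.DataFrame) -> pd.Series:
    return (
        (wells["role"] == "test")
        & ~wells["excluded"] & ~wells["toxic"] & ~wells["low_expression"]
    )


def z_factor_scores(wells: pd.DataFrame, *, value_col: str = "ti_norm",
                    leave_one_out: bool = False) -> pd.DataFrame:
    """Score eligible test wells: Z = (X - mu)/sigma per plate.

    mu and sigma (sample SD) are taken over the eligible test wells of
    the plate, the scored well included (set ``leave_one_out`` to
    exclude it). Ineligible wells get NaN. Raises on zero variance or
    fewer than 3 eligible wells per plate.
    """
    out = wells.copy()
    out["z_factor"] = np.nan
    for plate, idx in out.groupby("plate").groups.items():
        sub = out.loc[idx]
        elig = _eligible(sub)
        vals = sub.loc[elig, value_col].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(f"plate {plate}: need >= 3 eligible test wells")
        if not leave_one_out:
            mu = vals.mean()
            sigma = vals.std(ddof=1)
            if sigma == 0:
                raise ValueError(f"plate {plate}: no variance among test wells")
            out.loc[sub.index[elig], "z_factor"] = (vals - mu) / sigma
        else:
            n = len(vals)
            scores = np.empty(n)
            for i in range(n):
                rest = np.delete(vals, i)
                sd = rest.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"plate {plate}: no variance among test wells")
                scores[i] = (vals[i] - rest.mean()) / sd
            out.loc[sub.index[elig], "z_factor"] = scores
    return out


HIT_COLUMNS = ["compound_id", "plate", "well", "z_factor", "ti_norm",
               "viability", "is_hit", "rank"]


def compute_viability(wells: pd.DataFrame,
                      *, control_role: str = "pr_control") -> pd.DataFrame:
    """Viability = valid-cell count as percent of the plate's PR-control
    mean count (100% = survival equal to untreated PR-expressing wells)."""
    out = wells.copy()
    out["viability"] = np.nan
    for plate, idx in out.groupby("plate").groups.items():
        sub = out.loc[idx]
        ctrl = sub[(sub["role"] == control_role) & ~sub["excluded"]]["n_cells_valid"]
        if len(ctrl) < 1:
            raise ControlError(f"plate {plate}: no {control_role!r} wells for viability")
        out.loc[idx, "viability"] = 100.0 * sub["n_cells_valid"] / ctrl.mean()
    return out


def call_hits(scored_wells: pd.DataFrame, *,
              threshold: float = DEFAULT_HIT_THRESHOLD, top_k: int = 20,
              viability_floor: float = 100.0,
              control_role: str = "pr_control") -> pd.DataFrame:
    """Identify and rank hits among scored test wells.

    A hit reverses the PR-induced translocation (Z below ``threshold``)
    without worsening survival (viability >= ``viability_floor``, i.e.
    at least the PR-control mean by default) and carries no QC flag.
    Ranks 1..min(top_k, #hits) follow ascending Z; ties break toward
    higher viability, then lexicographic compound id. An empty candidate
    set returns an empty table.
    """
    wells = scored_wells
    if "viability" not in wells.columns or wells["viability"].isna().all():
        wells = compute_viability(wells, control_role=control_role)
    elig = _eligible(wells) & wells["z_factor"].notna()
    cand = wells[elig].copy()
    cand["is_hit"] = (cand["z_factor"] < threshold) & (cand["viability"] >= viability_floor)
    hits = cand[cand["is_hit"]].copy()
    hits = hits.sort_values(
        by=["z_factor", "viability", "compound_id"],
        ascending=[True, False, True], kind="mergesort")
    hits["rank"] = np.nan
    hits.iloc[:top_k, hits.columns.get_loc("rank")] = np.arange(
        1, min(top_k, len(hits)) + 1)
    return hits[HIT_COLUMNS].reset_index(drop=True)


CONFIRM_COLUMNS = ["compound_id", "n_replicates", "ti_norm_mean", "ti_norm_sd",
                   "count_mean", "count_sd", "t_stat", "p_value", "p_adjusted",
                   "restored", "viability_increased", "confirmed"]


def confirm_hits(replicate_wells: pd.DataFrame, *,
                 control_role: str = "pr_control",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Confirmatory-screen summary: per-compound replicate means vs the
    PR control by Welch's t with Holm adjustment across compounds.

    ``restored`` marks a shift back toward the vehicle baseline (lower
    normalized index than the control); ``confirmed`` requires both
    restoration and an adjusted p below ``alpha``.
    """
    ctrl = replicate_wells[replicate_wells["role"] == control_role]
    if len(ctrl) < 2:
        raise ControlError(f"need >= 2 {control_role!r} replicate wells")
    ctrl_ti = ctrl["ti_norm"].to_numpy(dtype=float)
    ctrl_counts = ctrl["n_cells_valid"].to_numpy(dtype=float)

    tests = replicate_wells[replicate_wells["role"] == "test"]
    rows = []
    for compound, grp in tests.groupby("compound_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"compound {compound}: need >= 2 replicates")
        ti = grp["ti_norm"].to_numpy(dtype=float)
        counts = grp["n_cells_valid"].to_numpy(dtype=float)
        t, p = stats.ttest_ind(ti, ctrl_ti, equal_var=False)
        rows.append({
            "compound_id": compound, "n_replicates": len(grp),
            "ti_norm_mean": ti.mean(), "ti_norm_sd": ti.std(ddof=1),
            "count_mean": counts.mean(), "count_sd": counts.std(ddof=1),
            "t_stat": float(t), "p_value": float(p),
            "restored": bool(ti.mean() < ctrl_ti.mean()),
            "viability_increased": bool(counts.mean() > ctrl_counts.mean()),
        })
    summary = pd.DataFrame(rows)
    if summary.empty:
        return pd.DataFrame(columns=CONFIRM_COLUMNS)
    summary["p_value"] = summary["p_value"].fillna(1.0)
    _, p_adj, _, _ = multipletests(summary["p_value"], method="holm")
    summary["p_adjusted"] = p_adj
    summary["confirmed"] = (summary["p_adjusted"] < alpha) & summary["restored"]
    return summary[CONFIRM_COLUMNS]
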