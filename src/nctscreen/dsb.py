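"""Nuclear gammaH2AX / TDP-43 intensity quantification for the DSB assay.

Workflow: binarize the DAPI channel and analyze particles (reusing the
screen's nucleus segmentation), redirect the measurement to the target
immunostain channel to get a mean nuclear intensity per cell, remove
Tukey-fence outliers per experimental group, then express group means on
a paired percent scale where each patient line's vehicle level is 100%
and its isogenic control's vehicle level is 0%. Compound doses are
picked by the 3-point rule: the dose with the greatest gammaH2AX
decrease wins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .segmentation import SegParams, segment_nuclei


class DegenerateWindowError(ValueError):
    """The two normalization anchors coincide."""


def nuclear_mean_intensity(dapi_image: np.ndarray, target_image: np.ndarray,
                           params: SegParams | None = None) -> pd.DataFrame:
    """Mean target-channel intensity over each segmented nucleus.

    Returns a table with ``nucleus_id``, nucleus geometry and
    ``mean_target_intensity``; one row per particle found in the DAPI
    mask.
    """
    dapi = np.asarray(dapi_image, dtype=float)
    target = np.asarray(target_image, dtype=float)
    if dapi.shape != target.shape:
        raise ValueError(
            f"image shape mismatch: {dapi.shape} vs {target.shape}")
    labels, objects = segment_nuclei(dapi, params)
    rows = []
    for _, obj in objects.iterrows():
        mask = labels == obj["object_id"]
        rows.append({
            "nucleus_id": int(obj["object_id"]),
            "centroid_r": obj["centroid_r"],
            "centroid_c": obj["centroid_c"],
            "area": obj["area"],
            "mean_target_intensity": float(target[mask].mean()),
            "is_outlier": False,
        })
    return pd.DataFrame(rows, columns=[
        "nucleus_id", "centroid_r", "centroid_c", "area",
        "mean_target_intensity", "is_outlier"])


def tukey_filter(values, *, k: float = 1.5, method: str = "linear"):
    """Tukey-fence outlier removal: flag values outside
    [Q1 - k*IQR, Q3 + k*IQR] in a single pass.

    ``method`` selects the quartile estimator: ``"linear"`` interpolates
    between order statistics (the spreadsheet default) or ``"hinges"``
    uses Tukey's hinges (median-split medians). Fewer than 4 values are
    returned unfiltered with a warning.

    Returns ``(retained, outlier_flags)`` as numpy arrays.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        warnings.warn("fewer than 4 values: Tukey filter skipped")
        return vals.copy(), np.zeros(vals.size, dtype=bool)
    if method == "linear":
        q1, q3 = np.quantile(vals, [0.25, 0.75])
    elif method == "hinges":
        s = np.sort(vals)
        n = s.size
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError("method must be 'linear' or 'hinges'")
    iqr = q3 - q1
    flags = (vals < q1 - k * iqr) | (vals > q3 + k * iqr)
    return vals[~flags], flags


def filter_cohort(table: pd.DataFrame, *, value_col: str = "mean_intensity",
                  group_cols=("line_id", "treatment", "replicate"),
                  method: str = "linear") -> pd.DataFrame:
    """Apply the Tukey filter per (line, treatment, replicate) group,
    before any averaging; outlier rows are flagged, not dropped."""
    out = table.copy()
    out["is_outlier"] = False
    group_cols = [c for c in group_cols if c in out.columns]
    for _, idx in out.groupby(group_cols, dropna=False).groups.items():
        vals = out.loc[idx, value_col].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, flags = tukey_filter(vals, method=method)
        out.loc[idx, "is_outlier"] = flags
    return out


def normalize_dsb(table: pd.DataFrame, *, value_col: str = "mean_intensity",
                  baseline_treatment: str = "vehicle") -> pd.DataFrame:
    """Paired patient/isogenic min-max normalization of group means.

    Within each pair (one patient line and its isogenic control), every
    (genotype, treatment, replicate) group mean ``g`` maps to

        pct(g) = 100 * (g - b) / (M - b)

    with ``b`` the isogenic+vehicle mean and ``M`` the patient+vehicle
    mean of that pair (outlier nuclei excluded). Anchors therefore sit
    at exactly 0% and 100% per pair; pooled summaries average the
    per-pair percentages. Coinciding anchors raise
    :class:`DegenerateWindowError`.

    Returns one row per (pair_id, line_id, genotype, treatment,
    replicate) with columns ``group_mean``, ``n_nuclei``, ``pct``.
    """
    retained = table[~table["is_outlier"]] if "is_outlier" in table.columns else table
    rows = []
    for pair, sub in retained.groupby("pair_id"):
        base = sub[(sub["genotype"] == "isogenic")
                   & (sub["treatment"] == baseline_treatment)][value_col]
        top = sub[(sub["genotype"] == "patient")
                  & (sub["treatment"] == baseline_treatment)][value_col]
        if len(base) < 1 or len(top) < 1:
            raise ValueError(f"pair {pair}: missing vehicle anchor group")
        b, m = float(base.mean()), float(top.mean())
        if m == b:
            raise DegenerateWindowError(
                f"pair {pair}: anchor means equal ({b}); cannot normalize")
        for keys, grp in sub.groupby(
                ["line_id", "genotype", "treatment", "replicate"], dropna=False):
            g = float(grp[value_col].mean())
            rows.append({
                "pair_id": pair, "line_id": keys[0], "genotype": keys[1],
                "treatment": keys[2], "replicate": keys[3],
                "group_mean": g, "n_nuclei": len(grp),
                "pct": 100.0 * (g - b) / (m - b),
            })
    return pd.DataFrame(rows)


def pool_normalized(norm: pd.DataFrame, *, by=("genotype", "treatment")) -> pd.DataFrame:
    """Pool per-pair normalized levels across the cohort (mean +/- SD of
    the per-(pair, replicate) percentages)."""
    by = list(by)
    agg = norm.groupby(by)["pct"].agg(["mean", "std", "count"]).reset_index()
    return agg.rename(columns={"mean": "pct_mean", "std": "pct_sd", "count": "n_groups"})


def select_dose(rows: pd.DataFrame, *, value_col: str = "mean_normalized_h2ax") -> pd.DataFrame:
    """3-point dose selection: per compound, pick the dose multiplier
    (1x, 10x, 100x IC50) with the lowest normalized gammaH2AX; ties
    break toward the lowest dose."""
    out = []
    for compound, grp in rows.groupby("compound", sort=True):
        doses = set(grp["dose_multiplier"])
        if doses != {1, 10, 100}:
            raise ValueError(
                f"compound {compound}: expected dose multipliers 1/10/100, got {sorted(doses)}")
        grp = grp.sort_values("dose_multiplier")  # tie -> lowest dose wins
        best = grp.loc[grp[value_col].idxmin()]
        out.append({"compound": compound,
                    "chosen_dose_multiplier": int(best["dose_multiplier"]),
                    value_col: float(best[value_col])})
    return pd.DataFrame(out)
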