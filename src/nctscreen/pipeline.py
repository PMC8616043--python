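"""End-to-end pipeline: simulate -> score -> QC -> hits, with provenance.

``run_screen`` executes the whole screening chain on simulated plates:
per-cell outlier removal, DPR-positive calling, well summarization,
2-SD flags, the Z' plate gate (failing plates are listed in the QC
report and excluded from hit calling), min-max normalization and
Z-factor hit calling. Every output table carries the configuration hash
and seed in ``DataFrame.attrs`` so a run can be traced to its inputs.
No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field

import pandas as pd
import yaml

from .hits import (DEFAULT_HIT_THRESHOLD, NormalizationSpec, call_hits,
                   compute_viability, normalize_minmax, z_factor_scores)
from .plates import PlateLayout, default_screen_layout
from .scoring import (ControlError, DprThresholds, call_dpr_positive,
                      flag_wells, qc_plate, remove_gfp_outliers,
                      summarize_wells)
from .simulate import ConditionEffect, PlateSimParams, simulate_plate


@dataclass
class RunConfig:
    """Configuration of one screening run (serializable to/from YAML)."""

    seed: int = 0
    n_plates: int = 1
    cells_per_well: float = 500.0
    n_true_restorers: int = 0
    restorer_effect: float = 0.6
    outlier_sd: float = 3.0
    dpr_circle_min: float = 80.0
    dpr_ring_min: float = 80.0
    min_role: str = "vehicle_neg"
    max_role: str = "pr_control"
    hit_threshold: float = DEFAULT_HIT_THRESHOLD
    top_k: int = 20
    viability_floor: float = 100.0
    z_prime_gate: float = 0.5
    extra_condition_effects: dict = dc_field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df.attrs["config_hash"] = config.digest()
    df.attrs["seed"] = config.seed
    return df


def run_screen(config: RunConfig, layouts: list[PlateLayout] | None = None) -> dict:
    """Run the full screening chain; returns a result bundle.

    Bundle keys: ``cells`` (per-cell table across plates), ``wells``
    (per-well table with flags and normalized indices), ``qc`` (per-plate
    Z' report rows), ``hits`` (ranked hit table from passing plates) and
    ``log`` (one structured line per stage with in/out counts).
    """
    if layouts is None:
        layouts = [default_screen_layout(f"P{i + 1}") for i in range(config.n_plates)]
    effects = {k: ConditionEffect(**v) if isinstance(v, dict) else v
               for k, v in config.extra_condition_effects.items()}

    log: list[dict] = []
    all_cells, all_wells, qc_rows = [], [], []
    passing_plates = []
    for i, layout in enumerate(layouts):
        params = PlateSimParams(
            layout=layout,
            cells_per_well=config.cells_per_well,
            condition_effects=effects,
            n_true_restorers=config.n_true_restorers,
            restorer_effect=config.restorer_effect,
            seed=config.seed + i,
        )
        cells, _truth = simulate_plate(params)
        log.append({"stage": "simulate", "plate": layout.plate,
                    "cells": len(cells)})

        cells = remove_gfp_outliers(cells, k=config.outlier_sd)
        cells = call_dpr_positive(cells, DprThresholds(
            circle_min=config.dpr_circle_min, ring_min=config.dpr_ring_min))
        log.append({"stage": "score_cells", "plate": layout.plate,
                    "outliers": int(cells["is_outlier"].sum()),
                    "dpr_positive": int(cells["is_dpr_positive"].sum())})

        wells = summarize_wells(cells, layout)
        wells = flag_wells(wells)
        try:
            report = qc_plate(wells, gate=config.z_prime_gate)
            qc_row = {"plate": layout.plate, "z_prime": report.z_prime,
                      "mu_p": report.mu_p, "sigma_p": report.sigma_p,
                      "mu_n": report.mu_n, "sigma_n": report.sigma_n,
                      "passed": report.passed,
                      "reason": "" if report.passed else
                      f"z_prime {report.z_prime:.3f} < gate {config.z_prime_gate}"}
        except ControlError as exc:
            report = None
            qc_row = {"plate": layout.plate, "z_prime": float("nan"),
                      "mu_p": float("nan"), "sigma_p": float("nan"),
                      "mu_n": float("nan"), "sigma_n": float("nan"),
                      "passed": False, "reason": str(exc)}
        qc_rows.append(qc_row)
        log.append({"stage": "qc", "plate": layout.plate,
                    "z_prime": qc_row["z_prime"], "passed": qc_row["passed"],
                    "excluded_wells": int(wells["excluded"].sum()),
                    "toxic": int(wells["toxic"].sum()),
                    "low_expression": int(wells["low_expression"].sum())})
        all_cells.append(cells)
        all_wells.append(wells)
        if qc_row["passed"]:
            passing_plates.append(layout.plate)

    wells = pd.concat(all_wells, ignore_index=True)
    cells = pd.concat(all_cells, ignore_index=True)

    hit_input = wells[wells["plate"].isin(passing_plates)]
    if len(hit_input):
        spec = NormalizationSpec(min_role=config.min_role, max_role=config.max_role)
        hit_input = normalize_minmax(hit_input, spec)
        hit_input = z_factor_scores(hit_input)
        hit_input = compute_viability(hit_input)
        hits = call_hits(hit_input, threshold=config.hit_threshold,
                         top_k=config.top_k,
                         viability_floor=config.viability_floor)
        wells = wells.copy()
        wells.loc[hit_input.index, ["ti_norm"]] = hit_input[["ti_norm"]]
        wells["z_factor"] = float("nan")
        wells.loc[hit_input.index, "z_factor"] = hit_input["z_factor"]
    else:
        hits = pd.DataFrame()
    log.append({"stage": "hits", "plates_scored": len(passing_plates),
                "n_hits": len(hits)})

    qc = pd.DataFrame(qc_rows)
    return {
        "cells": _stamp(cells, config),
        "wells": _stamp(wells, config),
        "qc": _stamp(qc, config),
        "hits": _stamp(hits, config),
        "log": log,
    }
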