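"""Seeded synthetic microscopy and plate data with known ground truth.

Three generators mirror the statistical structure the screening analysis
assumes:

``simulate_field``
    Renders multi-channel 2D fluorescence fields of U-2 OS-like cells:
    a DAPI channel of well-separated nuclear disks (dead cells smaller,
    brighter and irregular), a GFP biosensor channel whose per-cell
    nuclear/cytoplasmic partition is drawn from a Beta distribution, and
    an optional immunostain channel (dipeptide-repeat protein or
    gammaH2AX) restricted to transfected cells.

``simulate_plate``
    The image-free fast path: draws per-cell circle/ring measurements
    for every well of a plate layout directly from condition-specific
    distributions, so the well/plate statistics can be exercised at
    screen scale without rendering pixels.

``simulate_dsb_cohort``
    Per-nucleus mean gammaH2AX intensities for patient / isogenic
    motor-neuron lines under vehicle, compound and etoposide treatment.

All generators are deterministic in (params, seed).

Intensity model
---------------
Each live cell carries a total biosensor budget ``T`` (jittered around
``gfp_total_mean``) split by a Beta-distributed nuclear fraction ``f``:
the rendered nuclear mean is ``T*f`` and the cytoplasmic mean ``T*(1-f)``,
so the per-cell translocation index is ``T*(2f-1)`` — positive when the
sensor accumulates in the nucleus. Intensities are abstract counts in
``[0, 2**bit_depth - 1]``; images are kept as floats in memory and only
quantized when written to TIFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plates import PlateLayout


class FieldTooCrowdedError(RuntimeError):
    """Nucleus placement failed: field too crowded for the requested cells."""


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSimParams:
    """Parameters of one simulated imaging field.

    ``nuclear_fraction_dist`` are the Beta(alpha, beta) parameters of the
    per-cell nuclear fraction of the biosensor budget; the condition
    (vehicle vs export-blocked vs dipeptide-expressing) is encoded by
    where that Beta puts its mass.
    """

    field_shape: tuple[int, int] = (768, 768)
    n_cells: int = 40
    nucleus_radius_range: tuple[float, float] = (8.0, 13.0)
    dead_cell_fraction: float = 0.1
    dead_radius_factor: float = 0.45
    dead_intensity_factor: float = 2.0
    dead_irregularity: float = 0.3
    dapi_mean: float = 120.0
    gfp_total_mean: float = 60.0
    nuclear_fraction_dist: tuple[float, float] = (2.0, 6.0)
    transfection_efficiency: float = 0.7
    dpr_localization: str | None = None  # "nuclear" | "cytoplasmic" | None
    dpr_mean: float = 150.0
    noise_sd: float = 4.0
    bit_depth: int = 16
    cyto_extent: float = 2.0        # cytoplasm outer radius / nuclear radius
    placement_margin: float = 16.0  # extra center spacing beyond radii sum
    condition: str = "vehicle"

    def __post_init__(self) -> None:
        if not (0.0 <= self.dead_cell_fraction <= 1.0):
            raise ConfigError("dead_cell_fraction must be in [0, 1]")
        if not (0.0 <= self.transfection_efficiency <= 1.0):
            raise ConfigError("transfection_efficiency must be in [0, 1]")
        rmin, rmax = self.nucleus_radius_range
        if rmin < 2.0 or rmax < rmin:
            raise ConfigError("nucleus radii must satisfy 2 <= rmin <= rmax")
        if not (0.0 < self.dead_radius_factor < 1.0):
            raise ConfigError("dead_radius_factor must be in (0, 1)")
        if self.dead_intensity_factor <= 1.0:
            raise ConfigError("dead_intensity_factor must exceed 1")
        if self.dead_irregularity < 0.0:
            raise ConfigError("dead_irregularity must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")
        if self.dpr_localization not in (None, "nuclear", "cytoplasmic"):
            raise ConfigError("dpr_localization must be nuclear|cytoplasmic|None")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")

    @property
    def max_intensity(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass
class MultiChannelField:
    """One imaged field: per-channel 2D float rasters plus metadata."""

    channels: dict[str, np.ndarray]
    params: FieldSimParams
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


GROUND_TRUTH_COLUMNS = [
    "cell_id", "center_r", "center_c", "radius", "is_dead", "is_transfected",
    "true_nuc_gfp", "true_cyto_gfp", "true_translocation_index", "condition",
]

_MAX_PLACEMENT_ATTEMPTS_PER_CELL = 2000


def _place_nuclei(rng: np.random.Generator, params: FieldSimParams,
                  radii: np.ndarray) -> np.ndarray:
    """Rejection-sample non-overlapping centers; raise when too crowded."""
    h, w = params.field_shape
    centers = np.empty((len(radii), 2))
    for i, r in enumerate(radii):
        pad = r + 1.0
        for _ in range(_MAX_PLACEMENT_ATTEMPTS_PER_CELL):
            cand = np.array([rng.uniform(pad, h - pad), rng.uniform(pad, w - pad)])
            if i == 0:
                centers[0] = cand
                break
            d = np.linalg.norm(centers[:i] - cand, axis=1)
            if np.all(d > radii[:i] + r + params.placement_margin):
                centers[i] = cand
                break
        else:
            raise FieldTooCrowdedError(
                f"field too crowded: could not place nucleus {i + 1}/{len(radii)}"
            )
    return centers


def _disk_mask(shape, center, radius) -> tuple[slice, slice, np.ndarray]:
    """Boolean disk over its bounding box (pixel-center containment)."""
    h, w = shape
    r0 = max(int(math.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 2, h)
    c0 = max(int(math.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    return slice(r0, r1), slice(c0, c1), mask


def _irregular_mask(shape, center, radius, amplitude, rng):
    """Disk with a sinusoidal radial boundary perturbation (dead-cell shape)."""
    a1, a2 = rng.uniform(0.5, 1.0, size=2)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    rmax = radius * (1.0 + amplitude)
    h, w = shape
    r0 = max(int(math.floor(center[0] - rmax)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + rmax)) + 2, h)
    c0 = max(int(math.floor(center[1] - rmax)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + rmax)) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - center[0], cc - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = radius * (
        1.0 + amplitude * 0.5 * (a1 * np.sin(3 * theta + p1) + a2 * np.sin(5 * theta + p2))
    )
    return slice(r0, r1), slice(c0, c1), dist <= bound


def simulate_field(params: FieldSimParams, seed: int):
    """Render one multi-channel field and its per-cell ground truth.

    Returns ``(MultiChannelField, DataFrame)`` where the table has one
    row per simulated cell (:data:`GROUND_TRUTH_COLUMNS`). The DAPI and
    GFP channels are always present; an immunostain channel ``dpr`` is
    rendered when ``params.dpr_localization`` is set (restricted to
    transfected cells, in the configured compartment).
    """
    rng = np.random.default_rng(seed)
    shape = params.field_shape
    n = params.n_cells

    rmin, rmax = params.nucleus_radius_range
    radii_live = rng.uniform(rmin, rmax, size=n)
    # dead-cell count is fixed by rounding, assignment by seeded permutation
    n_dead = int(round(params.dead_cell_fraction * n))
    is_dead = np.zeros(n, dtype=bool)
    if n:
        is_dead[rng.permutation(n)[:n_dead]] = True
    radii = np.where(is_dead, radii_live * params.dead_radius_factor, radii_live)

    centers = _place_nuclei(rng, params, radii) if n else np.empty((0, 2))

    dapi_jit = rng.uniform(0.9, 1.1, size=n)
    dapi_levels = params.dapi_mean * dapi_jit
    dapi_levels[is_dead] *= params.dead_intensity_factor

    total = params.gfp_total_mean * rng.uniform(0.8, 1.2, size=n)
    alpha, beta = params.nuclear_fraction_dist
    # degenerate Beta endpoints: (a, 0) pins the fraction at 1 (fully
    # nuclear), (0, b) at 0 (fully cytoplasmic)
    if beta == 0:
        frac = np.ones(n)
    elif alpha == 0:
        frac = np.zeros(n)
    else:
        frac = rng.beta(alpha, beta, size=n) if n else np.empty(0)
    nuc_gfp = total * frac
    cyto_gfp = total * (1.0 - frac)

    is_transfected = rng.random(n) < params.transfection_efficiency

    dapi = np.zeros(shape)
    gfp = np.zeros(shape)
    want_dpr = params.dpr_localization is not None
    dpr = np.zeros(shape) if want_dpr else None

    nucleus_masks = []
    # cytoplasm bands first, nuclei last, so a neighbour's cytoplasm can
    # never overwrite a nucleus (keeps rendered nuclear means exact)
    for i in range(n):
        sl_r, sl_c, ann = _disk_mask(shape, centers[i], params.cyto_extent * radii[i])
        rr, cc = np.mgrid[sl_r, sl_c]
        inner = (rr - centers[i][0]) ** 2 + (cc - centers[i][1]) ** 2 <= radii[i] ** 2
        ann &= ~inner
        gfp[sl_r, sl_c][ann] = cyto_gfp[i]
        if want_dpr and is_transfected[i] and params.dpr_localization == "cytoplasmic":
            dpr[sl_r, sl_c][ann] = params.dpr_mean
    for i in range(n):
        if is_dead[i] and params.dead_irregularity > 0:
            sl_r, sl_c, mask = _irregular_mask(
                shape, centers[i], radii[i], params.dead_irregularity, rng)
        else:
            sl_r, sl_c, mask = _disk_mask(shape, centers[i], radii[i])
        dapi[sl_r, sl_c][mask] = dapi_levels[i]
        gfp[sl_r, sl_c][mask] = nuc_gfp[i]
        if want_dpr and is_transfected[i] and params.dpr_localization == "nuclear":
            dpr[sl_r, sl_c][mask] = params.dpr_mean
        nucleus_masks.append((sl_r, sl_c, mask))

    channels = {"dapi": dapi, "gfp": gfp}
    if want_dpr:
        channels["dpr"] = dpr
    if params.noise_sd > 0:
        for name in list(channels):
            channels[name] = channels[name] + rng.normal(
                0.0, params.noise_sd, size=shape)
    for name in list(channels):
        channels[name] = np.clip(channels[name], 0.0, params.max_intensity)

    truth = pd.DataFrame({
        "cell_id": np.arange(n),
        "center_r": centers[:, 0] if n else np.empty(0),
        "center_c": centers[:, 1] if n else np.empty(0),
        "radius": radii,
        "is_dead": is_dead,
        "is_transfected": is_transfected,
        "true_nuc_gfp": nuc_gfp,
        "true_cyto_gfp": cyto_gfp,
        "true_translocation_index": nuc_gfp - cyto_gfp,
        "condition": params.condition,
    }, columns=GROUND_TRUTH_COLUMNS)

    return MultiChannelField(channels=channels, params=params, seed=seed), truth


def simulate_dsb_field(nuclear_target_mean: float, seed: int,
                       params: FieldSimParams | None = None):
    """Two-channel (DAPI + nuclear immunostain) field for the DSB assay.

    The target channel (gammaH2AX or TDP-43 immunostain) is rendered as a
    uniform nuclear level ``nuclear_target_mean`` in every cell.
    """
    base = params or FieldSimParams()
    base = replace(base, dpr_localization="nuclear",
                   dpr_mean=nuclear_target_mean,
                   transfection_efficiency=1.0,
                   dead_cell_fraction=0.0)
    fld, truth = simulate_field(base, seed)
    fld.channels["h2ax"] = fld.channels.pop("dpr")
    return fld, truth


def default_validity_thresholds(params: FieldSimParams):
    """Validity thresholds that separate the generator's dead cells.

    Dead nuclei are rendered smaller (``dead_radius_factor``), brighter
    (``dead_intensity_factor``) and with perturbed boundaries, so
    thresholds midway between the live and dead ranges classify them
    perfectly at zero noise.
    """
    from .segmentation import ValidityThresholds

    rmin, _ = params.nucleus_radius_range
    _, rmax = params.nucleus_radius_range
    live_min_area = math.pi * rmin ** 2
    dead_max_area = math.pi * (params.dead_radius_factor * rmax * (1 + params.dead_irregularity)) ** 2
    live_max_dapi = params.dapi_mean * 1.1
    dead_min_dapi = params.dapi_mean * 0.9 * params.dead_intensity_factor
    return ValidityThresholds(
        max_mean_dapi=0.5 * (live_max_dapi + dead_min_dapi),
        min_area=0.5 * (live_min_area + dead_max_area),
        min_circularity=0.8,
    )


# ---------------------------------------------------------------------------
# Plate simulation (image-free)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionEffect:
    """Effect of a condition on its wells.

    ``delta`` shifts the well's expected translocation index in units of
    the vehicle-to-PR window (negative = toward the vehicle baseline,
    i.e. restored transport). ``viability`` multiplies the expected cell
    count. ``transfection`` overrides the plate transfection efficiency.
    """

    delta: float = 0.0
    viability: float = 1.0
    transfection: float | None = None


@dataclass
class PlateSimParams:
    """Whole-plate simulation: layout, per-condition effects, and the
    raw-intensity distributions per-cell measurements are drawn from.

    Raw translocation-index levels default to a cytoplasmic baseline
    (vehicle at -20 counts), full nuclear accumulation under export
    block (+28) and PR-induced accumulation (+20): a 40-count
    vehicle-to-PR window of 10 per-cell SDs, comfortably passing the
    Z' >= 0.5 plate gate at a few hundred cells per well.
    """

    layout: PlateLayout
    cells_per_well: float = 500.0          # Poisson mean of total cells per well
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    n_true_restorers: int = 0
    restorer_effect: float = 0.6           # fraction of window restored
    restorer_viability: float = 1.2
    seed: int = 0
    ti_vehicle: float = -20.0
    ti_pr: float = 20.0
    ti_lmb: float = 28.0
    cell_sd: float = 4.0                   # per-cell translocation-index SD
    well_sd: float = 0.5                   # well-level random shift (counts)
    ring_gfp_mean: float = 30.0
    ring_gfp_sd: float = 3.0
    dpr_pos_mean: float = 150.0
    dpr_pos_sd: float = 10.0
    dpr_bg_mean: float = 20.0
    dpr_bg_sd: float = 5.0
    transfection_efficiency: float = 0.7
    invalid_fraction: float = 0.05

    @property
    def window(self) -> float:
        return self.ti_pr - self.ti_vehicle


CELL_TABLE_COLUMNS = [
    "cell_id", "plate", "well", "role", "compound_id", "is_valid",
    "circle_gfp", "ring_gfp", "circle_dpr", "ring_dpr", "translocation_index",
]

_PR_ROLES = {"pr_control", "test"}  # wells transfected with the PR plasmid
_REQUIRED_CONTROL_ROLES = ("vehicle_neg", "lmb_pos", "pr_control")


def simulate_plate(params: PlateSimParams):
    """Draw a per-cell measurement table for every well of the layout.

    Returns ``(cells, well_truth)``: the cell table uses the same column
    convention as the image pipeline's feature extraction, and
    ``well_truth`` records each well's condition, planted effect and
    restorer status (the oracle for hit-recovery checks).
    """
    layout = params.layout
    for role in _REQUIRED_CONTROL_ROLES:
        if len(layout.wells_with_role(role)) < 2:
            raise ConfigError(
                f"layout must contain >= 2 wells with role {role!r}")
    rng = np.random.default_rng(params.seed)

    test_compounds = sorted(
        str(c) for c in layout.wells.loc[layout.wells["role"] == "test", "compound_id"].dropna().unique()
    )
    restorers: set[str] = set()
    if params.n_true_restorers > 0:
        if params.n_true_restorers > len(test_compounds):
            raise ConfigError("more restorers requested than test compounds")
        pick = rng.permutation(len(test_compounds))[: params.n_true_restorers]
        restorers = {test_compounds[i] for i in sorted(pick)}

    base_ti = {
        "vehicle_neg": params.ti_vehicle,
        "empty_vector": params.ti_vehicle,
        "lmb_pos": params.ti_lmb,
        "pr_control": params.ti_pr,
        "test": params.ti_pr,
    }

    cell_rows = []
    truth_rows = []
    cell_id = 0
    wells = layout.wells.sort_values("well").reset_index(drop=True)
    for _, wrow in wells.iterrows():
        well, role = wrow["well"], wrow["role"]
        compound = wrow["compound_id"]
        compound = None if pd.isna(compound) else str(compound)

        eff = ConditionEffect()
        if role in params.condition_effects:
            eff = params.condition_effects[role]
        if compound is not None and compound in params.condition_effects:
            eff = params.condition_effects[compound]
        elif compound in restorers:
            eff = ConditionEffect(delta=-params.restorer_effect,
                                  viability=params.restorer_viability)

        mu_ti = base_ti[role] + eff.delta * params.window
        mu_ti += rng.normal(0.0, params.well_sd)

        n_valid = rng.poisson(params.cells_per_well * eff.viability)
        n_invalid = rng.poisson(
            params.invalid_fraction * params.cells_per_well / max(eff.viability, 1e-9))
        p_transfect = (eff.transfection if eff.transfection is not None
                       else params.transfection_efficiency)
        has_dpr = role in _PR_ROLES

        n_total = n_valid + n_invalid
        ring = rng.normal(params.ring_gfp_mean, params.ring_gfp_sd, size=n_total)
        ti = rng.normal(mu_ti, params.cell_sd, size=n_total)
        circle = ring + ti
        transfected = (rng.random(n_total) < p_transfect) & has_dpr
        circle_dpr = np.where(
            transfected,
            rng.normal(params.dpr_pos_mean, params.dpr_pos_sd, size=n_total),
            rng.normal(params.dpr_bg_mean, params.dpr_bg_sd, size=n_total))
        ring_dpr = rng.normal(params.dpr_bg_mean, params.dpr_bg_sd, size=n_total)

        valid_flags = np.ones(n_total, dtype=bool)
        valid_flags[n_valid:] = False

        cell_rows.append(pd.DataFrame({
            "cell_id": np.arange(cell_id, cell_id + n_total),
            "plate": layout.plate, "well": well, "role": role,
            "compound_id": compound, "is_valid": valid_flags,
            "circle_gfp": circle, "ring_gfp": ring,
            "circle_dpr": circle_dpr, "ring_dpr": ring_dpr,
            "translocation_index": circle - ring,
        }))
        cell_id += n_total

        truth_rows.append({
            "plate": layout.plate, "well": well, "role": role,
            "compound_id": compound,
            "true_delta": eff.delta if role == "test" else 0.0,
            "is_restorer": compound in restorers if compound else False,
            "expected_ti_raw": base_ti[role] + eff.delta * params.window,
            "viability_multiplier": eff.viability,
        })

    if cell_rows:
        cells = pd.concat(cell_rows, ignore_index=True)[CELL_TABLE_COLUMNS]
    else:
        cells = pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    well_truth = pd.DataFrame(truth_rows)
    return cells, well_truth


def simulate_null_well_table(n_wells: int, seed: int, *, mean: float = 100.0,
                             sd: float = 10.0, plate: str = "NULL1") -> pd.DataFrame:
    """Well-level null screen: eligible test wells with iid Gaussian
    normalized translocation indices (for score-calibration checks)."""
    rng = np.random.default_rng(seed)
    n_digits = max(5, len(str(n_wells)))
    return pd.DataFrame({
        "plate": plate,
        "well": [f"W{i:0{n_digits}d}" for i in range(n_wells)],
        "role": "test",
        "compound_id": [f"C{i:0{n_digits}d}" for i in range(n_wells)],
        "dose": np.nan,
        "n_cells_valid": 500,
        "n_invalid": 0,
        "n_dpr_positive": 350,
        "ti_raw": rng.normal(mean, sd, size=n_wells),
        "ti_norm": rng.normal(mean, sd, size=n_wells),
        "excluded": False,
        "toxic": False,
        "low_expression": False,
    })


# ---------------------------------------------------------------------------
# DSB (gammaH2AX) cohort simulation
# ---------------------------------------------------------------------------

def simulate_dsb_cohort(pairs, treatments, effects, seed: int, *,
                        n_nuclei: int = 300, n_replicates: int = 3,
                        intensity_sd: float = 10.0,
                        line_sd: float = 0.03,
                        replicate_sd: float = 0.02) -> pd.DataFrame:
    """Per-nucleus mean gammaH2AX intensities for a patient/isogenic cohort.

    Parameters
    ----------
    pairs:
        List of ``(patient_line_id, isogenic_line_id)`` tuples; each pair
        shares a pair id used later for paired normalization.
    treatments:
        Treatment labels (must include ``"vehicle"``).
    effects:
        Mapping ``(genotype, treatment) -> mean nuclear intensity`` with
        genotype in {"patient", "isogenic"}; every combination of the
        two genotypes with every treatment must be present.
    seed:
        Drives all sampling; identical inputs give identical tables.

    A multiplicative line factor (SD ``line_sd``) scales all of one
    line's groups together, emulating staining-batch differences that
    paired normalization is meant to cancel.
    """
    if "vehicle" not in treatments:
        raise ConfigError('treatments must include "vehicle"')
    for geno in ("patient", "isogenic"):
        for trt in treatments:
            if (geno, trt) not in effects:
                raise ConfigError(f"effects missing combination {(geno, trt)!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for pair_idx, (patient, isogenic) in enumerate(pairs):
        for line_id, geno in ((patient, "patient"), (isogenic, "isogenic")):
            line_factor = rng.normal(1.0, line_sd)
            for trt in treatments:
                mu = effects[(geno, trt)] * line_factor
                for rep in range(1, n_replicates + 1):
                    rep_mu = mu * rng.normal(1.0, replicate_sd)
                    vals = np.clip(
                        rng.normal(rep_mu, intensity_sd, size=n_nuclei), 0.0, None)
                    for k, v in enumerate(vals):
                        rows.append((line_id, geno, pair_idx, trt, rep, k, float(v)))
    return pd.DataFrame(rows, columns=[
        "line_id", "genotype", "pair_id", "treatment", "replicate",
        "nucleus_id", "mean_intensity",
    ])
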