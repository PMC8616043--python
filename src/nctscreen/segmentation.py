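"""DAPI-driven nucleus segmentation and circle/ring feature extraction.

The segmentation follows the classic high-content recipe: Gaussian
smooth, global threshold (Otsu by default), binarize, fill holes, drop
tiny components, 8-connected labeling. Each labeled nucleus yields an
"object" whose size, DAPI brightness and circularity feed the validity
classifier (condensed dead-cell nuclei are small, bright and irregular).
For every valid nucleus a "circle" mask (the nucleus pixels themselves)
and a "ring" mask (a morphological annulus around it, standing in for
perinuclear cytoplasm) are built; per-channel mean intensities over the
two masks give the cell's translocation index

    TI = mean GFP over circle - mean GFP over ring,

positive when the biosensor accumulates in the nucleus.

Geometry conventions: coordinates are 0-based (row, col) pixel centers;
perimeter uses the Crofton estimator (4 directions), for which the
circularity 4*pi*A/P^2 of a digitized disk can exceed 1 by up to
``CIRCULARITY_EPS`` = 0.1 at small radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

logger = logging.getLogger(__name__)

#: discretization slack on the 4*pi*A/P^2 circularity of digitized disks
CIRCULARITY_EPS = 0.1


@dataclass(frozen=True)
class SegParams:
    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"      # "otsu" | "fixed"
    fixed_threshold: float = 0.0
    min_object_area: int = 20
    fill_holes: bool = True
    ring_gap: int = 1
    ring_width: int = 4

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")
        if self.ring_gap < 0:
            raise ValueError("ring_gap must be >= 0")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")


@dataclass(frozen=True)
class ValidityThresholds:
    """An object is invalid iff it is too bright, too small, or too
    aberrant: mean_dapi > max_mean_dapi OR area < min_area OR
    circularity < min_circularity."""

    max_mean_dapi: float = np.inf
    min_area: float = 0.0
    min_circularity: float = 0.0


OBJECT_COLUMNS = [
    "object_id", "well", "field", "centroid_r", "centroid_c",
    "area", "perimeter", "circularity", "mean_dapi", "border", "is_valid",
]


def segment_nuclei(dapi_image: np.ndarray, params: SegParams | None = None,
                   *, well: str | None = None, field_id: int = 0):
    """Segment nuclei from a DAPI channel.

    Returns ``(label_mask, objects)``: an int32 label image with dense
    labels 1..N (8-connectivity) and an object table
    (:data:`OBJECT_COLUMNS`). A constant image under Otsu yields zero
    objects rather than an error. ``is_valid`` is initialized True and
    assigned later by :func:`classify_objects`.
    """
    params = params or SegParams()
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dapi_image must be 2D")

    smoothed = gaussian(img, sigma=params.smoothing_sigma,
                        preserve_range=True) if params.smoothing_sigma > 0 else img
    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return np.zeros(img.shape, dtype=np.int32), _empty_objects()
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    binary = smoothed > thr
    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    labels = label(binary, connectivity=2)
    # drop small components, then relabel densely
    if labels.max():
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= params.min_object_area)
        keep = keep[keep != 0]
        mask = np.isin(labels, keep) & (labels > 0)
        labels = label(mask, connectivity=2)
    labels = labels.astype(np.int32)

    h, w = img.shape
    rows = []
    for prop in regionprops(labels, intensity_image=img):
        perimeter = prop.perimeter_crofton
        circ = 4.0 * np.pi * prop.area / perimeter ** 2 if perimeter > 0 else 0.0
        minr, minc, maxr, maxc = prop.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        rows.append((
            int(prop.label), well, field_id,
            float(prop.centroid[0]), float(prop.centroid[1]),
            float(prop.area), float(perimeter), float(circ),
            float(prop.intensity_mean), bool(border), True,
        ))
    return labels, pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def _empty_objects() -> pd.DataFrame:
    return pd.DataFrame(columns=OBJECT_COLUMNS)


def classify_objects(objects: pd.DataFrame,
                     thresholds: ValidityThresholds) -> pd.DataFrame:
    """Assign ``is_valid`` by the dead-cell rule (total: never raises).

    Invalid objects are retained in the table — their counts feed the
    well-level toxicity filter — but are excluded from transport scoring
    downstream.
    """
    out = objects.copy()
    if out.empty:
        return out
    invalid = (
        (out["mean_dapi"] > thresholds.max_mean_dapi)
        | (out["area"] < thresholds.min_area)
        | (out["circularity"] < thresholds.min_circularity)
    )
    out["is_valid"] = ~invalid
    return out


def make_circle_ring_masks(label_mask: np.ndarray,
                           params: SegParams | None = None):
    """Build per-object circle and ring masks.

    The circle is the object's own labeled pixels. The candidate ring is
    the dilation by ``ring_gap + ring_width`` minus the dilation by
    ``ring_gap``; pixels claimed by more than one candidate ring, or
    belonging to any nucleus, are dropped from every ring (contested
    pixels are assigned to no one, which keeps the result independent of
    object order). Returns ``{label: (circle_mask, ring_mask, border)}``
    with boolean full-frame masks; ``border`` is True when the
    candidate ring was clipped at the image bounds.
    """
    params = params or SegParams()
    labels = np.asarray(label_mask)
    n = int(labels.max())
    any_circle = labels > 0
    outer_fp = disk(params.ring_gap + params.ring_width)
    inner_fp = disk(params.ring_gap) if params.ring_gap > 0 else None
    h, w = labels.shape
    pad = params.ring_gap + params.ring_width

    candidates = {}
    claim_count = np.zeros(labels.shape, dtype=np.int16)
    for lab in range(1, n + 1):
        obj = labels == lab
        rs, cs = np.nonzero(obj)
        r0, r1 = rs.min(), rs.max() + 1
        c0, c1 = cs.min(), cs.max() + 1
        er0, er1 = max(r0 - pad, 0), min(r1 + pad, h)
        ec0, ec1 = max(c0 - pad, 0), min(c1 + pad, w)
        border = (r0 - pad < 0) or (c0 - pad < 0) or (r1 + pad > h) or (c1 + pad > w)
        crop = obj[er0:er1, ec0:ec1]
        outer = ndi.binary_dilation(crop, structure=outer_fp)
        inner = ndi.binary_dilation(crop, structure=inner_fp) if inner_fp is not None else crop
        ring_crop = outer & ~inner & ~crop
        ring = np.zeros(labels.shape, dtype=bool)
        ring[er0:er1, ec0:ec1] = ring_crop
        candidates[lab] = (obj, ring, border)
        claim_count[ring] += 1

    uncontested = claim_count <= 1
    masks = {}
    for lab, (circle, ring, border) in candidates.items():
        masks[lab] = (circle, ring & uncontested & ~any_circle, border)
    return masks


CELL_COLUMNS_BASE = ["object_id", "well", "field", "border",
                     "translocation_index", "is_valid", "is_outlier",
                     "is_dpr_positive"]


def extract_features(channels: dict[str, np.ndarray], masks,
                     objects: pd.DataFrame | None = None,
                     *, gfp_channel: str = "gfp") -> pd.DataFrame:
    """Per-cell mean intensities over circle and ring masks.

    ``channels`` maps channel name -> 2D image (all the same shape);
    columns ``circle_<name>`` / ``ring_<name>`` are emitted per channel,
    plus ``translocation_index`` = circle - ring means of the GFP
    channel. Cells whose ring is empty (fully contested) are dropped and
    the count logged. When ``objects`` is given, its ``well``/``field``/
    ``is_valid`` annotations are carried over by ``object_id``.
    """
    shapes = {ch.shape for ch in channels.values()}
    if len(shapes) > 1:
        raise ValueError(f"channel shape mismatch: {sorted(shapes)}")
    if gfp_channel not in channels:
        raise ValueError(f"GFP channel {gfp_channel!r} missing")

    meta = {}
    if objects is not None and not objects.empty:
        meta = objects.set_index("object_id")[["well", "field", "is_valid"]].to_dict("index")

    rows = []
    n_empty = 0
    for lab, (circle, ring, border) in sorted(masks.items()):
        if not ring.any():
            n_empty += 1
            continue
        rec = {
            "object_id": lab,
            "well": meta.get(lab, {}).get("well"),
            "field": meta.get(lab, {}).get("field", 0),
            "border": bool(border),
            "is_valid": bool(meta.get(lab, {}).get("is_valid", True)),
            "is_outlier": False,
            "is_dpr_positive": False,
        }
        for name, img in channels.items():
            rec[f"circle_{name}"] = float(img[circle].mean())
            rec[f"ring_{name}"] = float(img[ring].mean())
        rec["translocation_index"] = rec[f"circle_{gfp_channel}"] - rec[f"ring_{gfp_channel}"]
        rows.append(rec)
    if n_empty:
        logger.info("dropped %d cells with empty (fully contested) rings", n_empty)

    cols = CELL_COLUMNS_BASE + [f"{p}_{name}" for name in channels for p in ("circle", "ring")]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[[c for c in cols if c in df.columns]]


def segment_field(field, seg_params: SegParams | None = None,
                  validity: ValidityThresholds | None = None,
                  *, well: str | None = None, field_id: int = 0) -> pd.DataFrame:
    """Convenience wrapper: segment a MultiChannelField end to end.

    Runs segment_nuclei on the DAPI channel, classifies validity, builds
    circle/ring masks and extracts per-cell features for every channel.
    """
    seg_params = seg_params or SegParams()
    labels, objects = segment_nuclei(field.channels["dapi"], seg_params,
                                     well=well, field_id=field_id)
    if validity is not None:
        objects = classify_objects(objects, validity)
    masks = make_circle_ring_masks(labels, seg_params)
    return extract_features(field.channels, masks, objects)
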