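"""Trait measurements and quality metrics from binary segmentations.

Length is the pixel count of the morphological skeleton (centrelines of the
mask), suitable for total root length in calibrated images.  Region
properties (centroid, area, equivalent diameter, perimeter, eccentricity)
come from connected-component analysis with 8-connectivity, so diagonal
strands of thin structures stay joined.  Counts can be filtered by a minimum
equivalent diameter in millimetres (given a px-per-mm calibration — e.g.
biopores below 2 mm are conventionally excluded) and/or a minimum area in
pixels (useful for suppressing small false-positive nodule detections).

Segmentation quality against a reference (typically the *corrected
segmentation*: the prediction with the annotator's corrections applied) is
reported as dice, recall, precision and accuracy per image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

from .nn import BACKGROUND, FOREGROUND
from .store import decode_annotation, read_mask

CONNECTIVITY = 2  # 8-connectivity for component labelling


# ---------------------------------------------------------------------------
# length


def extract_length(mask: np.ndarray, diagonal_correction: bool = False) -> float:
    """Centreline length of a binary mask.

    By default this is the raw count of skeleton pixels.  With
    ``diagonal_correction`` the count weights diagonal skeleton steps by
    sqrt(2) (off by default; the raw count is the conventional output).
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return 0.0
    skel = skeletonize(m)
    if not diagonal_correction:
        return float(skel.sum())
    # geodesic-style correction: count diagonal-only neighbour links as sqrt(2)
    s = skel.astype(np.uint8)
    straight = ((s[:, 1:] & s[:, :-1]).sum() + (s[1:] & s[:-1]).sum())
    diag = ((s[1:, 1:] & s[:-1, :-1]).sum() + (s[1:, :-1] & s[:-1, 1:]).sum())
    return float(s.sum() + (np.sqrt(2) - 1.0) * max(0, diag - straight))


def lengths_for_folder(seg_dir) -> pd.DataFrame:
    rows = [
        {"image_name": p.name, "length_px": extract_length(read_mask(p))}
        for p in sorted(Path(seg_dir).glob("*.png"))
    ]
    return pd.DataFrame(rows, columns=["image_name", "length_px"])


# ---------------------------------------------------------------------------
# region properties


@dataclass(frozen=True)
class RegionRecord:
    image_name: str
    centroid_row: float
    centroid_col: float
    area_px: int
    equivalent_diameter_px: float
    equivalent_diameter_mm: float | None
    perimeter_px: float
    eccentricity: float


def extract_region_props(
    mask: np.ndarray,
    image_name: str = "",
    px_per_mm: float | None = None,
) -> list[RegionRecord]:
    """One record per 8-connected foreground region."""
    if px_per_mm is not None and px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    labels = skmeasure.label(np.asarray(mask) > 0, connectivity=CONNECTIVITY)
    records = []
    for r in skmeasure.regionprops(labels):
        d_px = r.equivalent_diameter_area
        records.append(RegionRecord(
            image_name=image_name,
            centroid_row=float(r.centroid[0]),
            centroid_col=float(r.centroid[1]),
            area_px=int(r.area),
            equivalent_diameter_px=float(d_px),
            equivalent_diameter_mm=(float(d_px) / px_per_mm
                                    if px_per_mm is not None else None),
            perimeter_px=float(r.perimeter),
            eccentricity=float(r.eccentricity),
        ))
    return records


def region_props_for_folder(seg_dir, px_per_mm: float | None = None) -> pd.DataFrame:
    rows = []
    for p in sorted(Path(seg_dir).glob("*.png")):
        rows += [vars(r) for r in
                 extract_region_props(read_mask(p), p.name, px_per_mm)]
    cols = ["image_name", "centroid_row", "centroid_col", "area_px",
            "equivalent_diameter_px", "equivalent_diameter_mm",
            "perimeter_px", "eccentricity"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# counts


def extract_count(
    mask: np.ndarray,
    min_diameter_mm: float | None = None,
    min_area_px: float | None = None,
    px_per_mm: float | None = None,
) -> int:
    """Number of connected regions surviving the (conjunctive) size filters."""
    if min_diameter_mm is not None and px_per_mm is None:
        raise ValueError("a diameter filter in mm requires px_per_mm calibration")
    regions = extract_region_props(mask, px_per_mm=px_per_mm)
    n = 0
    for r in regions:
        if min_diameter_mm is not None and r.equivalent_diameter_mm < min_diameter_mm:
            continue
        if min_area_px is not None and r.area_px < min_area_px:
            continue
        n += 1
    return n


def counts_for_folder(
    seg_dir,
    min_diameter_mm: float | None = None,
    min_area_px: float | None = None,
    px_per_mm: float | None = None,
) -> pd.DataFrame:
    rows = [
        {"image_name": p.name,
         "count": extract_count(read_mask(p), min_diameter_mm, min_area_px, px_per_mm)}
        for p in sorted(Path(seg_dir).glob("*.png"))
    ]
    return pd.DataFrame(rows, columns=["image_name", "count"])


# ---------------------------------------------------------------------------
# corrected segmentation & metrics


def corrected_segmentation(prediction: np.ndarray, annotation: np.ndarray) -> np.ndarray:
    """Apply corrective labels to a prediction: fg->1, bg->0, undefined kept."""
    prediction = (np.asarray(prediction) > 0).astype(np.uint8)
    annotation = np.asarray(annotation)
    if prediction.shape != annotation.shape:
        raise ValueError("prediction and annotation dimensions differ")
    out = prediction.copy()
    out[annotation == FOREGROUND] = 1
    out[annotation == BACKGROUND] = 0
    return out


@dataclass(frozen=True)
class MetricsRecord:
    image_name: str
    dice: float
    recall: float
    precision: float
    accuracy: float


def segmentation_metrics(
    prediction: np.ndarray, reference: np.ndarray, image_name: str = ""
) -> MetricsRecord:
    """Pixelwise dice, recall, precision and accuracy of prediction vs reference.

    Empty-denominator conventions: 0/0 -> 1 (perfect vacuous agreement),
    otherwise x/0 cannot occur (denominators are TP+FN, TP+FP, total).
    """
    p = np.asarray(prediction) > 0
    r = np.asarray(reference) > 0
    if p.shape != r.shape:
        raise ValueError("prediction and reference dimensions differ")
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    tn = int((~p & ~r).sum())
    total = tp + fp + fn + tn

    def ratio(num, den):
        return 1.0 if den == 0 else num / den

    return MetricsRecord(
        image_name=image_name,
        dice=ratio(2 * tp, 2 * tp + fp + fn),
        recall=ratio(tp, tp + fn),
        precision=ratio(tp, tp + fp),
        accuracy=ratio(tp + tn, total),
    )


def metrics_for_folder(seg_dir, annot_dirs) -> pd.DataFrame:
    """Metrics of each segmentation against its corrected segmentation.

    ``annot_dirs`` is one directory or a list (e.g. the project's train and
    val annotation folders); images without an annotation are skipped.
    """
    if isinstance(annot_dirs, (str, Path)):
        annot_dirs = [annot_dirs]
    rows = []
    for p in sorted(Path(seg_dir).glob("*.png")):
        ann_path = None
        for d in annot_dirs:
            cand = Path(d) / p.name
            if cand.exists():
                ann_path = cand
                break
        if ann_path is None:
            continue
        pred = read_mask(p)
        ann = decode_annotation(ann_path)
        ref = corrected_segmentation(pred, ann)
        rows.append(vars(segmentation_metrics(pred, ref, p.name)))
    cols = ["image_name", "dice", "recall", "precision", "accuracy"]
    return pd.DataFrame(rows, columns=cols)
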