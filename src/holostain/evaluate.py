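"""Staining quality metrics.

Image level: mean SSIM between network output and stain target.  Cell
level: predicted cells are connected components of the thresholded stain;
ground-truth tumor cells are matched to components by centroid distance,
giving TP/FN; PBMCs overlapped by surplus components become FP, the rest
TN; precision, recall, F1 and accuracy follow from the pooled
(micro-averaged) counts.

Correctly detected tumor cells are true positives, missed tumor cells
false negatives; correctly rejected PBMCs are true negatives and falsely
stained PBMCs false positives — counting is per cell, not per pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops

from . import io
from .preprocess import MASK_THRESHOLD
from .simulate import PBMC, TUMOR, CellRecord

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PredictedCell",
    "ssim",
    "extract_predicted_cells",
    "count_confusion",
    "prf_accuracy",
    "evaluate_run",
]


@dataclass
class ConfusionCounts:
    """Cell-level tallies: TP + FN covers the evaluated tumor cells,
    TN + FP the evaluated PBMCs."""

    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FN + other.FN,
            self.TN + other.TN,
            self.FP + other.FP,
        )

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetricsReport:
    """Evaluation summary for one split: mean SSIM, pooled cell-level
    rates (None where undefined, e.g. precision with no positive calls),
    and the raw counts they derive from."""

    ssim_mean: float
    ssim_per_image: List[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]
    counts: ConfusionCounts
    n_images: int
    per_image: List[dict] = dc_field(default_factory=list)
    config: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = self.counts.to_dict()
        return d

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        d = self.to_dict()
        per_image = d.pop("per_image")
        io.write_json(out_dir / "metrics.json", d)
        if per_image:
            import pandas as pd

            pd.DataFrame(per_image).to_csv(out_dir / "per_image.csv", index=False)


# ----------------------------------------------------------------------
# SSIM
# ----------------------------------------------------------------------

def ssim(
    a: np.ndarray,
    b: np.ndarray,
    sigma: float = 1.5,
    win_size: int = 11,
    K1: float = 0.01,
    K2: float = 0.03,
    data_range: float = 1.0,
) -> float:
    """Structural similarity index with the standard parameterization
    (11-tap Gaussian window, sigma 1.5, K1=0.01, K2=0.03): mean local SSIM
    over the interior of the image (border of half a window excluded).
    Symmetric in its two arguments; 1.0 iff the images are identical."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if min(a.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}-pixel SSIM window")
    truncate = 3.5  # radius int(3.5*1.5 + 0.5) = 5 -> 11-tap window

    def filt(x):
        return gaussian_filter(x, sigma, truncate=truncate)

    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    mu_a, mu_b = filt(a), filt(b)
    saa = filt(a * a) - mu_a * mu_a
    sbb = filt(b * b) - mu_b * mu_b
    sab = filt(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + C1) * (2 * sab + C2)) / (
        (mu_a**2 + mu_b**2 + C1) * (saa + sbb + C2)
    )
    pad = win_size // 2
    return float(s[pad:-pad, pad:-pad].mean())


# ----------------------------------------------------------------------
# Cell extraction and confusion counting
# ----------------------------------------------------------------------

@dataclass
class PredictedCell:
    centroid: Tuple[float, float]  # (row, col), intensity-weighted
    area: int
    coords: np.ndarray  # (n, 2) pixel coordinates


def extract_predicted_cells(
    stain: np.ndarray,
    threshold: float = MASK_THRESHOLD,
    min_area_px: int = 0,
) -> List[PredictedCell]:
    """Connected components (8-connectivity) of ``stain >= threshold``,
    dropping components smaller than ``min_area_px``.  An empty list is a
    valid result (a clean 1000:1 crop may contain no tumor cell)."""
    stain = np.asarray(stain, dtype=np.float64)
    lab = label(stain >= threshold, connectivity=2)
    out: List[PredictedCell] = []
    for rp in regionprops(lab, intensity_image=stain):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid_weighted
        out.append(
            PredictedCell(centroid=(float(cy), float(cx)), area=int(rp.area), coords=rp.coords)
        )
    return out


def _cells_for_crop(
    cells: Sequence[CellRecord],
    crop_origin: Tuple[int, int],
    crop_shape: Tuple[int, int],
) -> Tuple[List[CellRecord], List[CellRecord]]:
    """Partition field cells into (evaluated, margin) for a crop.

    Evaluated cells have their centroid inside the crop.  Margin cells sit
    outside but their footprint intersects the crop: they appear partially
    in the stain yet belong to a neighbouring crop's census, so predicted
    components they explain are ignored rather than counted as errors.
    Cell coordinates are returned in the crop frame.
    """
    r0, c0 = crop_origin
    h, w = crop_shape
    evaluated, margin = [], []
    for c in cells:
        row, col = c.row - r0, c.col - c0
        inside = 0 <= row < h and 0 <= col < w
        shifted = CellRecord(c.kind, row, col, c.radius_px, c.peak_phase)
        if inside:
            evaluated.append(shifted)
        else:
            near_r = min(max(row, 0), h - 1)
            near_c = min(max(col, 0), w - 1)
            if np.hypot(row - near_r, col - near_c) <= c.radius_px:
                margin.append(shifted)
    return evaluated, margin


def count_confusion(
    pred: Sequence[PredictedCell],
    cells: Sequence[CellRecord],
    crop_origin: Tuple[int, int] = (0, 0),
    crop_shape: Optional[Tuple[int, int]] = None,
    min_coverage: float = 0.25,
) -> ConfusionCounts:
    """Count TP/FN/TN/FP cells for one stain image.

    Counting is per cell, matching how classification accuracy is defined:
    a tumor cell is correctly classified (TP) when the stain covers at
    least ``min_coverage`` of its visible footprint, otherwise FN.  A
    single merged component may thereby validate every adherent tumor
    cell it covers.  Each surplus component — one whose pixels touch no
    tumor footprint — is assessed once: the nearest PBMC whose footprint
    it overlaps (ties by index) becomes a FP; remaining PBMCs are TN.
    Components explained by margin cells (footprints reaching in from a
    neighbouring crop) are ignored.
    """
    if crop_shape is None:
        extent = 1
        for c in cells:
            extent = max(extent, int(np.ceil(c.row + c.radius_px)) + 1,
                         int(np.ceil(c.col + c.radius_px)) + 1)
        for p in pred:
            if len(p.coords):
                extent = max(extent, int(p.coords.max()) + 1)
        crop_shape = (extent, extent)
        evaluated, margin = list(cells), []
    else:
        evaluated, margin = _cells_for_crop(cells, crop_origin, crop_shape)
    tumors = [c for c in evaluated if c.kind == TUMOR]
    pbmcs = [c for c in evaluated if c.kind == PBMC]

    h, w = crop_shape
    stained = np.zeros((h, w), dtype=bool)
    for p in pred:
        if len(p.coords):
            stained[p.coords[:, 0], p.coords[:, 1]] = True

    def footprint_pixels(cell: CellRecord):
        r0 = max(0, int(np.floor(cell.row - cell.radius_px)))
        r1 = min(h, int(np.ceil(cell.row + cell.radius_px)) + 1)
        c0 = max(0, int(np.floor(cell.col - cell.radius_px)))
        c1 = min(w, int(np.ceil(cell.col + cell.radius_px)) + 1)
        if r1 <= r0 or c1 <= c0:
            return None
        yy = np.arange(r0, r1)[:, None] - cell.row
        xx = np.arange(c0, c1)[None, :] - cell.col
        inside = yy**2 + xx**2 <= cell.radius_px**2
        return (slice(r0, r1), slice(c0, c1)), inside

    tp = 0
    tumor_map = np.zeros((h, w), dtype=bool)
    for t in tumors:
        fp_ = footprint_pixels(t)
        if fp_ is None:
            continue
        window, inside = fp_
        tumor_map[window] |= inside
        visible = int(inside.sum())
        covered = int((stained[window] & inside).sum())
        if visible > 0 and covered >= min_coverage * visible:
            tp += 1
    fn = len(tumors) - tp

    margin_map = np.zeros((h, w), dtype=bool)
    for m in margin:
        fp_ = footprint_pixels(m)
        if fp_ is not None:
            window, inside = fp_
            margin_map[window] |= inside

    fp_pbmcs: set = set()
    for p in pred:
        if not len(p.coords):
            continue
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        if tumor_map[rows, cols].any():
            continue  # stains (part of) a tumor cell: not a surplus blob
        if margin_map[rows, cols].any():
            continue  # explained by a neighbouring crop's cell
        # nearest PBMC whose footprint overlaps the component's pixels
        best: Optional[Tuple[float, int]] = None
        for bi, b in enumerate(pbmcs):
            if bi in fp_pbmcs:
                continue
            dpix = np.hypot(rows - b.row, cols - b.col)
            if dpix.min() <= b.radius_px:
                dcent = float(np.hypot(b.row - p.centroid[0], b.col - p.centroid[1]))
                if best is None or (dcent, bi) < best:
                    best = (dcent, bi)
        if best is not None:
            fp_pbmcs.add(best[1])

    fp = len(fp_pbmcs)
    tn = len(pbmcs) - fp
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def prf_accuracy(
    c: ConfusionCounts,
) -> Tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """Precision TP/(TP+FP), recall TP/(FN+TP), F1 = 2PR/(P+R), accuracy
    (TP+TN)/total.  Division-by-zero cases return None (an explicit
    undefined flag), never a silent 0."""
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    recall = c.TP / (c.FN + c.TP) if (c.FN + c.TP) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (c.TP + c.TN) / c.total if c.total > 0 else None
    return precision, recall, f1, accuracy


# ----------------------------------------------------------------------
# Run evaluation
# ----------------------------------------------------------------------

Predictor = Callable[[np.ndarray, dict], np.ndarray]


def evaluate_run(
    predictor: Predictor,
    manifest: dict,
    base_dir: str | Path,
    split: str = "test",
    threshold: float = MASK_THRESHOLD,
    min_area_px: Optional[int] = None,
    field_cells: Optional[Dict[str, List[CellRecord]]] = None,
    out_dir: Optional[str | Path] = None,
) -> MetricsReport:
    """Evaluate a stain predictor over one manifest split.

    ``predictor(input_array, entry) -> stain map`` is called per example
    (wrap a trained model with :func:`make_unet_predictor`).  Per-image
    SSIM against the stored target is averaged; confusion counts are
    pooled over all images and the rates computed once on the pooled
    counts (micro-averaging).
    """
    from .dataset import load_field_cells

    base_dir = Path(base_dir)
    entries = [e for e in manifest["entries"] if e["split"] == split]
    if not entries:
        raise ValueError(f"split {split!r} is empty")
    if min_area_px is None:
        min_area_px = int(manifest["config"].get("mask", {}).get("min_area_px", 0))
    if field_cells is None:
        field_cells = load_field_cells(manifest, base_dir)

    missing = [
        str(p)
        for e in entries
        for p in (e["paths"]["input"], e["paths"]["target"])
        if not (base_dir / p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing example files: {missing[:5]}")

    ssim_vals: List[float] = []
    pooled = ConfusionCounts()
    per_image: List[dict] = []
    for e in entries:
        x = io.read_image(base_dir / e["paths"]["input"]).astype(np.float64)
        target = io.read_image(base_dir / e["paths"]["target"]).astype(np.float64)
        stain = np.asarray(predictor(x, e), dtype=np.float64)
        if stain.shape != target.shape:
            raise ValueError(
                f"predictor output {stain.shape} does not match target {target.shape}"
            )
        s = ssim(stain, target)
        pred_cells = extract_predicted_cells(stain, threshold, min_area_px)
        counts = count_confusion(
            pred_cells,
            field_cells[e["field_id"]],
            crop_origin=tuple(e["crop_origin"]),
            crop_shape=target.shape,
        )
        pooled = pooled + counts
        ssim_vals.append(s)
        per_image.append(
            {"example_id": e["example_id"], "ssim": s, **counts.to_dict()}
        )

    precision, recall, f1, accuracy = prf_accuracy(pooled)
    if accuracy is None:
        warnings.warn("no cells evaluated; cell-level metrics undefined", stacklevel=2)
    report = MetricsReport(
        ssim_mean=float(np.mean(ssim_vals)),
        ssim_per_image=ssim_vals,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        counts=pooled,
        n_images=len(entries),
        per_image=per_image,
        config={
            "split": split,
            "threshold": threshold,
            "min_area_px": int(min_area_px),
        },
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def make_unet_predictor(model) -> Predictor:
    """Adapt a trained U-net to the ``evaluate_run`` predictor signature."""
    from .unet import predict

    return lambda x, entry: predict(model, x)
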