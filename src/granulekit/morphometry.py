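"""Granule segmentation and shape/localization statistics.

A liquid-like condensate is held together by weak interactions and rounded
up by surface tension, so its projected outline is nearly circular; solid
aggregates are irregular. The central statistic is

    circularity = 4 * pi * Area / Perimeter**2

(1 for a perfect circle, smaller the more the outline deviates). The module
also provides the supporting measurements used to characterize granule
states: thresholding + particle analysis (object counts and sizes over
time), the foci-to-cytoplasm intensity ratio, and fusion-event detection in
time-lapse stacks.

Perimeters are measured with the Crofton formula (4 directions), the
estimator that is asymptotically unbiased for smooth outlines — the
relevant regime when scoring droplet roundness. Raw pixel-edge counting
would inflate perimeters by ~4/pi and systematically depress circularity,
and marching-squares contour length carries a persistent ~5% staircase
bias; Crofton instead slightly under-measures shapes with long
axis-aligned straight edges, a regime droplets never occupy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import skimage.filters
import skimage.measure
import skimage.segmentation

__all__ = [
    "LabelImage",
    "GranuleObject",
    "FusionEvent",
    "circularity",
    "segment_granules",
    "measure_objects",
    "measure_table",
    "foci_to_cytoplasm_ratio",
    "count_size_timeseries",
    "detect_fusions",
]


def circularity(area: float, perimeter: float) -> float:
    """``4 * pi * area / perimeter**2``; 1 for a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("circularity: area and perimeter must be > 0")
    return 4.0 * math.pi * area / perimeter**2


@dataclass
class LabelImage:
    """2-D integer label map (0 = background, labels contiguous from 1)."""

    labels: np.ndarray
    pixel_size: float = 1.0  # µm / pixel
    frame: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels: must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size: must be > 0")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class GranuleObject:
    label: int
    area_px: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]  # (row, col), 0-based
    mean_intensity: float


@dataclass
class FusionEvent:
    frame: int  # frame at which the merged object first exists
    parent_labels: tuple[int, ...]
    child_label: int
    parent_area_px: float
    child_area_px: float


def _contour_perimeter(mask: np.ndarray) -> float:
    """Crofton (4-direction) boundary length of a binary object mask."""
    return float(skimage.measure.perimeter_crofton(mask.astype(np.uint8), directions=4))


def segment_granules(
    image: np.ndarray,
    threshold_method: str = "otsu",
    manual_threshold: float | None = None,
    min_area: float = 0.0,
    max_area: float = math.inf,
    circ_min: float = 0.0,
    circ_max: float = 1.0,
    pixel_size: float = 1.0,
    mask: np.ndarray | None = None,
) -> LabelImage:
    """Threshold + particle analysis with size and circularity windows.

    The defaults (size 0..inf, circularity 0..1) pass every particle. For
    window filtering the measured circularity is capped at 1 — small
    discretization overshoots above 1 never exclude a round object —
    while :func:`measure_objects` reports the uncapped value.

    Parameters
    ----------
    threshold_method
        'otsu' (computed on the in-``mask`` histogram when a mask is
        given) or 'manual' (requires ``manual_threshold``).
    mask
        Optional region (e.g. a cell mask) restricting both the threshold
        computation and the segmentation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_granules: image must be 2-D grayscale")
    if threshold_method == "manual":
        if manual_threshold is None:
            raise ValueError("segment_granules: manual method requires manual_threshold")
        thr = float(manual_threshold)
    elif threshold_method == "otsu":
        values = image[mask] if mask is not None else image.ravel()
        thr = float(skimage.filters.threshold_otsu(values))
    else:
        raise ValueError(f"segment_granules: unknown threshold_method {threshold_method!r}")

    fg = image > thr
    if mask is not None:
        fg &= mask.astype(bool)
    raw = skimage.measure.label(fg, connectivity=2)  # 8-connected

    keep = np.zeros(raw.max() + 1, dtype=bool)
    for prop in skimage.measure.regionprops(raw):
        area = prop.area
        if not (min_area <= area <= max_area):
            continue
        obj_mask = raw == prop.label
        perim = _contour_perimeter(obj_mask)
        circ = min(circularity(float(area), perim), 1.0) if perim > 0 else 0.0
        if circ_min <= circ <= circ_max:
            keep[prop.label] = True

    filtered = np.where(keep[raw], raw, 0)
    relabeled, _, _ = skimage.segmentation.relabel_sequential(filtered)
    return LabelImage(labels=relabeled.astype(np.int32), pixel_size=pixel_size)


def measure_objects(labels: LabelImage, image: np.ndarray | None = None) -> list[GranuleObject]:
    """Per-object area, contour perimeter, circularity and mean intensity.

    Circularity is reported unclamped: rasterized shapes can measure
    slightly above 1 and that overshoot is informative for convergence
    checks.
    """
    lab = labels.labels
    if image is not None:
        image = np.asarray(image, dtype=float)
        if image.shape != lab.shape:
            raise ValueError(f"measure_objects: image shape {image.shape} != labels shape {lab.shape}")
    px = labels.pixel_size
    out = []
    for prop in skimage.measure.regionprops(lab, intensity_image=image):
        perim = _contour_perimeter(lab == prop.label)
        area = float(prop.area)
        out.append(GranuleObject(
            label=int(prop.label),
            area_px=area,
            area_um2=area * px**2,
            perimeter_px=perim,
            perimeter_um=perim * px,
            circularity=circularity(area, perim),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            mean_intensity=float(prop.intensity_mean) if image is not None else float("nan"),
        ))
    return out


def measure_table(labels: LabelImage, image: np.ndarray | None = None) -> pd.DataFrame:
    """:func:`measure_objects` as a DataFrame (one row per object)."""
    objs = measure_objects(labels, image)
    return pd.DataFrame([{
        "frame": labels.frame,
        "label": o.label,
        "area_px": o.area_px,
        "area_um2": o.area_um2,
        "perimeter_px": o.perimeter_px,
        "perimeter_um": o.perimeter_um,
        "circularity": o.circularity,
        "centroid_row": o.centroid[0],
        "centroid_col": o.centroid[1],
        "mean_intensity": o.mean_intensity,
    } for o in objs])


def foci_to_cytoplasm_ratio(
    image: np.ndarray,
    cell_mask: np.ndarray,
    foci_mask: np.ndarray,
    background_level: float = 0.0,
) -> float:
    """Mean focus intensity over mean cytoplasmic (cell minus foci) intensity.

    Both means are background-subtracted; high ratios indicate strong
    partitioning of the protein into foci.
    """
    image = np.asarray(image, dtype=float)
    cell = np.asarray(cell_mask, dtype=bool)
    foci = np.asarray(foci_mask, dtype=bool)
    if np.any(foci & ~cell):
        raise ValueError("foci_to_cytoplasm_ratio: foci mask must lie within the cell mask")
    cyto = cell & ~foci
    if not foci.any():
        raise ValueError("foci_to_cytoplasm_ratio: empty foci mask")
    if not cyto.any():
        raise ValueError("foci_to_cytoplasm_ratio: no cytoplasm left outside the foci")
    denom = float(image[cyto].mean()) - background_level
    if denom <= 0:
        raise ValueError("foci_to_cytoplasm_ratio: nonpositive background-subtracted cytoplasm mean")
    return (float(image[foci].mean()) - background_level) / denom


def count_size_timeseries(
    stack: np.ndarray,
    cell_masks: np.ndarray | Sequence[np.ndarray],
    pixel_size: float = 1.0,
    **segment_kwargs,
) -> pd.DataFrame:
    """Per-frame per-cell granule counts and mean sizes.

    ``cell_masks`` is a static cell label image (0 = outside any cell) or
    one label image per frame. Returns one row per (frame, cell) with
    granule_count and mean_area_um2 (NaN when the cell has no granules),
    plus per-frame population rows (cell_id = -1) carrying the mean count
    across cells and its standard error.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    static = isinstance(cell_masks, np.ndarray) and np.asarray(cell_masks).ndim == 2
    rows = []
    for k, frame in enumerate(stack):
        cells = np.asarray(cell_masks if static else cell_masks[k])
        cell_ids = np.unique(cells[cells > 0])
        if cell_ids.size == 0:
            raise ValueError("count_size_timeseries: no cells in the mask")
        counts = []
        for cid in cell_ids:
            seg = segment_granules(frame, mask=cells == cid, pixel_size=pixel_size, **segment_kwargs)
            objs = measure_objects(seg)
            n_obj = len(objs)
            counts.append(n_obj)
            rows.append({
                "frame": k, "cell_id": int(cid), "granule_count": n_obj,
                "mean_area_um2": float(np.mean([o.area_um2 for o in objs])) if n_obj else float("nan"),
                "total_area_um2": float(np.sum([o.area_um2 for o in objs])) if n_obj else 0.0,
            })
        counts = np.asarray(counts, dtype=float)
        sem = float(counts.std(ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else float("nan")
        rows.append({"frame": k, "cell_id": -1, "granule_count": float(counts.mean()),
                     "mean_area_um2": float("nan"), "total_area_um2": float("nan"),
                     "count_sem": sem})
    return pd.DataFrame(rows)


def detect_fusions(
    label_images: Sequence[LabelImage],
    max_displacement: float = 5.0,
    area_tolerance: float = 0.25,
) -> list[FusionEvent]:
    """Detect granule fusion events by greedy nearest-centroid linking.

    Each object in frame t is linked to the nearest centroid in frame t+1
    within ``max_displacement`` pixels. A fusion event is recorded when two
    or more tracks map onto one object whose area matches the summed
    parent areas within ``area_tolerance`` (relative).
    """
    events: list[FusionEvent] = []
    prev = None
    for k, lab in enumerate(label_images):
        props = {p.label: (np.asarray(p.centroid), float(p.area))
                 for p in skimage.measure.regionprops(lab.labels)}
        if prev is not None:
            assignments: dict[int, list[int]] = {}
            for plabel, (pcent, _) in prev.items():
                best, best_d = None, max_displacement
                for clabel, (ccent, _) in props.items():
                    d = float(np.hypot(*(ccent - pcent)))
                    if d <= best_d:
                        best, best_d = clabel, d
                if best is not None:
                    assignments.setdefault(best, []).append(plabel)
            for child, parents in assignments.items():
                if len(parents) < 2:
                    continue
                parent_area = sum(prev[p][1] for p in parents)
                child_area = props[child][1]
                if abs(child_area - parent_area) <= area_tolerance * parent_area:
                    events.append(FusionEvent(
                        frame=k,
                        parent_labels=tuple(sorted(parents)),
                        child_label=child,
                        parent_area_px=parent_area,
                        child_area_px=child_area,
                    ))
        prev = props
    return events
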