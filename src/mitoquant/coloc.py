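"""LC3 puncta counting and object-based mitochondria-LC3 colocalization.

A mitochondrial object co-localizes with LC3 when at least ``overlap_min`` of
its pixels fall inside LC3-positive pixels (object-based colocalization with
mitochondria as the reference set). The per-cell integrated-intensity ratio
(mCherry over LC3 within LC3-positive pixels) is emitted as a secondary
readout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .classify import MitoObject, _background_corrected
from .segment import DEFAULT_PARAMS, SegmentationParams, _safe_otsu
from .types import ImageField, LabelMap

log = logging.getLogger(__name__)

DEFAULT_OVERLAP_MIN = 0.5


@dataclass(frozen=True)
class ColocRecord:
    cell_id: int
    n_lc3: int
    n_mito: int
    n_mito_lc3: int
    coloc_fraction: float  # n_mito_lc3 / n_mito
    intensity_ratio: float  # sum mCherry / sum LC3 over LC3+ pixels in the cell


def segment_lc3(field: ImageField, params: SegmentationParams = DEFAULT_PARAMS) -> LabelMap:
    """Detect LC3 punctae; same spot-detection recipe as mitochondrial objects.

    Raises KeyError naming the role when the LC3 channel is absent.
    """
    ch = field.channel("lc3").astype(np.float64)
    resid = np.clip(ch - float(np.median(ch)), 0.0, None)
    sm = ndi.gaussian_filter(resid, params.mito_smooth_sigma)
    thr = _safe_otsu(sm[sm > 0])
    if thr is None:
        log.warning("lc3 channel is flat; returning zero punctae")
        return LabelMap(np.zeros(field.shape, dtype=np.int32), kind="lc3")
    lab, n = ndi.label(sm > thr, structure=np.ones((3, 3), int))
    if n == 0:
        return LabelMap(np.zeros(field.shape, dtype=np.int32), kind="lc3")
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= params.min_object_size)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelMap(remap[lab], kind="lc3")


def lc3_per_cell(lc3: LabelMap, cells: LabelMap) -> tuple[pd.DataFrame, float]:
    """LC3 puncta count per cell (by puncta centroid) and the field mean."""
    if lc3.shape != cells.shape:
        raise ValueError("label maps must share one shape")
    counts = {int(c): 0 for c in cells.ids}
    ids = lc3.ids
    if ids.size:
        centroids = ndi.center_of_mass(np.ones_like(lc3.labels), lc3.labels, ids)
        for cy, cx in centroids:
            host = int(cells.labels[int(cy), int(cx)])
            if host in counts:
                counts[host] += 1
    df = pd.DataFrame(
        {"cell_id": list(counts), "n_lc3": list(counts.values())}
    ).sort_values("cell_id", ignore_index=True)
    mean = float(df.n_lc3.mean()) if len(df) else 0.0
    return df, mean


def mito_lc3_coloc(
    mito_objects: list[MitoObject],
    mito: LabelMap,
    lc3: LabelMap,
    cells: LabelMap,
    field: ImageField,
    overlap_min: float = DEFAULT_OVERLAP_MIN,
) -> list[ColocRecord]:
    """Object-based colocalization of mitochondrial objects with LC3.

    Cells without mitochondrial objects have an undefined coloc_fraction and
    are excluded from the returned records (counted in the log).
    """
    if not (0.0 < overlap_min <= 1.0):
        raise ValueError("overlap_min must lie in (0, 1]")
    lc3_pos = lc3.labels > 0
    lc3_count, _ = lc3_per_cell(lc3, cells)
    lc3_n = dict(zip(lc3_count.cell_id, lc3_count.n_lc3))

    overlaps: dict[int, tuple[int, int]] = {}  # cell -> (n_mito, n_coloc)
    lab = mito.labels
    ids = mito.ids
    if ids.size:
        area = ndi.sum_labels(np.ones_like(lab), lab, ids)
        inside = ndi.sum_labels(lc3_pos.astype(np.float64), lab, ids)
        frac = dict(zip(ids, inside / np.maximum(area, 1)))
    else:
        frac = {}
    for obj in mito_objects:
        if obj.cell_id <= 0:
            continue
        n, k = overlaps.get(obj.cell_id, (0, 0))
        hit = frac.get(obj.object_id, 0.0) >= overlap_min
        overlaps[obj.cell_id] = (n + 1, k + int(hit))

    mch = _background_corrected(field.channel("mcherry"))
    lc3_ch = _background_corrected(field.channel("lc3"))

    records: list[ColocRecord] = []
    skipped = 0
    for cid in (int(c) for c in cells.ids):
        n, k = overlaps.get(cid, (0, 0))
        if n == 0:
            skipped += 1
            continue
        sel = (cells.labels == cid) & lc3_pos
        lc3_sum = float(lc3_ch[sel].sum())
        ratio = float(mch[sel].sum() / lc3_sum) if lc3_sum > 0 else float("nan")
        records.append(
            ColocRecord(
                cell_id=cid,
                n_lc3=lc3_n.get(cid, 0),
                n_mito=n,
                n_mito_lc3=k,
                coloc_fraction=k / n,
                intensity_ratio=ratio,
            )
        )
    if skipped:
        log.debug("excluded %d cells without mito objects from coloc fractions", skipped)
    return records


def coloc_table(records: list[ColocRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
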