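"""Ratio classification of mitochondrial objects and the per-cell mitophagy rate.

Each segmented mitochondrial structure gets background-corrected integrated
intensities in the EGFP and mCherry channels; the EGFP/mCherry ratio decides
its class: below the threshold the green fluorophore is quenched and the
object is a "red-only" structure (an acidified mitolysosome), otherwise it is
a "yellow" (cytosolic-pH) mitochondrion. The mitophagy readout of a cell is
its red-only count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import ImageField, LabelMap

log = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 0.3  # EGFP/mCherry; red_only below, yellow at/above


@dataclass(frozen=True)
class MitoObject:
    object_id: int
    cell_id: int  # 0 = unassigned (centroid on background)
    area_px: int
    integrated_egfp: float
    integrated_mcherry: float
    ratio: float
    label: str  # "yellow" | "red_only"


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    cell_area_px: int
    n_yellow: int
    n_red_only: int
    border_touching: bool

    @property
    def mitophagy_index(self) -> int:
        return self.n_red_only


@dataclass(frozen=True)
class FieldSummary:
    mean_red_only_per_cell: float
    n_cells: int
    n_objects: int


class NoCellsError(RuntimeError):
    """Raised when a field summary is requested but no cell qualifies."""


def _background_corrected(ch: np.ndarray) -> np.ndarray:
    """Median background subtraction; fields are mostly background pixels."""
    return np.clip(ch.astype(np.float64) - float(np.median(ch)), 0.0, None)


def measure_and_classify(
    field: ImageField,
    mito: LabelMap,
    cells: LabelMap,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[MitoObject]:
    """Integrate both reporter channels per object and classify yellow/red-only.

    Objects whose background-corrected mCherry integral is zero cannot carry
    the reporter and are dropped (counted in the log). An object is assigned
    to the cell under its mCherry-weighted centroid; a centroid on background
    leaves it unassigned (cell_id 0).
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    if mito.shape != field.shape or cells.shape != field.shape:
        raise ValueError("label maps must match the field shape")
    ids = mito.ids
    if ids.size == 0:
        return []
    egfp = _background_corrected(field.channel("egfp"))
    mch = _background_corrected(field.channel("mcherry"))
    lab = mito.labels
    areas = ndi.sum_labels(np.ones_like(lab), lab, ids)
    e_int = ndi.sum_labels(egfp, lab, ids)
    m_int = ndi.sum_labels(mch, lab, ids)
    centroids = ndi.center_of_mass(mch + 1e-12, lab, ids)

    out: list[MitoObject] = []
    n_dropped = 0
    for oid, area, ei, mi, (cy, cx) in zip(ids, areas, e_int, m_int, centroids):
        if mi <= 0:
            n_dropped += 1
            continue
        # tie-break: a centroid on a boundary is resolved by the integer pixel
        # it falls in (row-major floor), deterministically
        cell_id = int(cells.labels[int(cy), int(cx)])
        ratio = float(ei / mi)
        out.append(
            MitoObject(
                object_id=int(oid),
                cell_id=cell_id,
                area_px=int(area),
                integrated_egfp=float(ei),
                integrated_mcherry=float(mi),
                ratio=ratio,
                label="red_only" if ratio < ratio_threshold else "yellow",
            )
        )
    if n_dropped:
        log.debug("dropped %d objects with zero corrected mCherry", n_dropped)
    return out


def mitophagy_rate(
    objects: list[MitoObject],
    cells: LabelMap,
    exclude_border: bool = True,
) -> tuple[list[CellRecord], FieldSummary]:
    """Per-cell yellow/red-only counts and the field-level mitophagy rate.

    The field summary is the mean red-only count over included cells; border
    cells are excluded by default because truncated cytoplasm biases counts.
    Raises :class:`NoCellsError` when no cell qualifies.
    """
    border = cells.border_labels()
    counts: dict[int, dict[str, int]] = {
        int(cid): {"yellow": 0, "red_only": 0} for cid in cells.ids
    }
    for obj in objects:
        if obj.cell_id in counts:
            counts[obj.cell_id][obj.label] += 1
    areas = ndi.sum_labels(np.ones_like(cells.labels), cells.labels, cells.ids)

    records = [
        CellRecord(
            cell_id=int(cid),
            cell_area_px=int(a),
            n_yellow=counts[int(cid)]["yellow"],
            n_red_only=counts[int(cid)]["red_only"],
            border_touching=int(cid) in border,
        )
        for cid, a in zip(cells.ids, areas)
    ]
    included = [r for r in records if not (exclude_border and r.border_touching)]
    if not included:
        raise NoCellsError("no cells left after border exclusion; field mean undefined")
    summary = FieldSummary(
        mean_red_only_per_cell=float(np.mean([r.n_red_only for r in included])),
        n_cells=len(included),
        n_objects=len(objects),
    )
    return records, summary


def objects_table(objects: list[MitoObject]) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in objects])


def cells_table(records: list[CellRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if not df.empty:
        df["mitophagy_index"] = df["n_red_only"]
    return df
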