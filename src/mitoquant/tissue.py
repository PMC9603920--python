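"""Spinal-cord tissue readouts: p62 and TOMM20 stained area per motor neuron.

Motor-neuron (MN) boundaries come either from externally provided masks
(mirroring manual delineation on the TOMM20 stain) or from an automatic
threshold of the smoothed TOMM20 channel. Marker-positive area is an Otsu
threshold restricted to the union of MN masks, intersected with each MN.
Aggregation follows the hierarchical mean-of-means scheme: MN -> stack
(section) mean -> animal mean -> group mean +/- SEM over animals, with n at
the animal level, never pooled over MN.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import _safe_otsu
from .types import ImageField, LabelMap

log = logging.getLogger(__name__)

MN_MIN_AREA = 300  # px; size gate for automatic MN detection
EXPECTED_MN_PER_STACK = (10, 15)


@dataclass(frozen=True)
class GroupAggregate:
    group: str
    animal_means: dict[str, float]
    mean: float
    sem: float  # nan when < 2 animals
    n_animals: int


def delineate_mn(
    field: ImageField,
    mode: str = "provided_masks",
    masks: Optional[LabelMap] = None,
    mn_min_area: int = MN_MIN_AREA,
) -> LabelMap:
    """MN label map, from provided masks (passthrough) or TOMM20 thresholding."""
    if mode == "provided_masks":
        if masks is None:
            raise ValueError("provided_masks mode requires a masks LabelMap")
        if masks.shape != field.shape:
            raise ValueError("MN masks do not match the field shape")
        return masks
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    if "tomm20" not in field.channels:
        raise KeyError("auto MN delineation requires a tomm20 channel")
    ch = ndi.gaussian_filter(field.channel("tomm20").astype(np.float64), 2.0)
    thr = _safe_otsu(ch)
    if thr is None:
        log.warning("tomm20 channel is flat; no MN detected")
        return LabelMap(np.zeros(field.shape, dtype=np.int32), kind="mn")
    mask = ndi.binary_fill_holes(ch > thr)
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    out = np.zeros(field.shape, dtype=np.int32)
    nxt = 1
    for lid in range(1, n + 1):
        m = lab == lid
        if m.sum() >= mn_min_area:
            out[m] = nxt
            nxt += 1
    return LabelMap(out, kind="mn")


def marker_area_per_mn(
    field: ImageField,
    mn: LabelMap,
    marker: str,
) -> pd.DataFrame:
    """Marker-positive area (px) within each MN.

    Positivity threshold: Otsu over the marker channel restricted to the MN
    union; a flat-inside-union channel yields zero (all-background) or full
    (uniform positive signal) areas. Warns when the MN count per stack falls
    outside the expected 10-15 range. Columns: mn_id, mn_area_px,
    <marker>_area_px, <marker>_fraction.
    """
    if marker not in field.channels:
        raise KeyError(f"marker channel {marker!r} missing")
    if mn.shape != field.shape:
        raise ValueError("MN label map does not match the field shape")
    n_mn = mn.n_labels
    lo, hi = EXPECTED_MN_PER_STACK
    if n_mn and not (lo <= n_mn <= hi):
        log.warning("%d MN in stack; expected %d-%d", n_mn, lo, hi)
    ch = field.channel(marker).astype(np.float64)
    union = mn.labels > 0
    vals = ch[union]
    if vals.size == 0:
        return pd.DataFrame(columns=["mn_id", "mn_area_px", f"{marker}_area_px", f"{marker}_fraction"])
    thr = _safe_otsu(vals)
    if thr is None:
        # flat within the union: uniformly positive if above zero, else empty
        pos = np.full(field.shape, bool(vals.max() > 0))
    else:
        pos = ch > thr
    rows = []
    for mid in (int(m) for m in mn.ids):
        mask = mn.labels == mid
        area = int(mask.sum())
        if area == 0:
            log.debug("MN %d has zero area; excluded", mid)
            continue
        marker_area = int((pos & mask).sum())
        rows.append(
            {
                "mn_id": mid,
                "mn_area_px": area,
                f"{marker}_area_px": marker_area,
                f"{marker}_fraction": marker_area / area,
            }
        )
    return pd.DataFrame(rows)


def aggregate_hierarchical(
    records: pd.DataFrame,
    value: str,
    group_col: str = "group",
    animal_col: str = "animal_id",
    stack_col: str = "stack_id",
) -> list[GroupAggregate]:
    """Mean-of-means aggregation: MN -> stack -> animal -> group mean +/- SEM.

    The group mean is always the mean of per-animal means (never pooled over
    MN); SEM is reported over animals and undefined (nan, with a warning) for
    groups with fewer than two animals.
    """
    for col in (group_col, animal_col, stack_col, value):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    out = []
    for group, gdf in records.groupby(group_col, sort=True):
        stack_means = gdf.groupby([animal_col, stack_col], sort=True)[value].mean()
        animal_means = stack_means.groupby(level=0).mean()
        n = int(animal_means.size)
        mean = float(animal_means.mean())
        if n >= 2:
            sem = float(animal_means.std(ddof=1) / np.sqrt(n))
        else:
            log.warning("group %r has %d animal(s); SEM undefined", group, n)
            sem = float("nan")
        out.append(
            GroupAggregate(
                group=str(group),
                animal_means={str(k): float(v) for k, v in animal_means.items()},
                mean=mean,
                sem=sem,
                n_animals=n,
            )
        )
    return out
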