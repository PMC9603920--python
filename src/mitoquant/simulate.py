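"""Synthetic fluorescence microscopy with exact ground truth.

Emulates the tandem mCherry-EGFP mitophagy reporter assay: cells carry a
perinuclear mitochondrial network visible in both the EGFP and mCherry
channels ("yellow"), plus a Poisson-distributed number of acidified
mitolysosomes that have lost EGFP and appear in mCherry only ("red-only").
Treatments scale the acidified rate (inducers up, inhibitors down); a
lysosomal block (BafA1-like) converts the induced excess into dual-channel
objects, leaving only the basal steady-state red-only population. Optional
LC3 puncta are planted free in the cytoplasm and/or covering a stated
fraction of mitochondrial objects, so object-based colocalization has a
known answer. A tissue mode renders motor-neuron somata with p62 puncta and
a TOMM20 cytoplasmic fill of exactly known area.

Every field is paired with a :class:`~mitoquant.types.GroundTruth` holding
label images and per-cell counts that match the rendered pixels exactly, so
each downstream stage has a testing oracle. Identical (config, effect, seed)
yields bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label

from .types import GroundTruth, ImageField, LabelMap

# Rendering amplitudes (arbitrary fluorescence units). Per-object brightness is
# jittered by the same factor in both reporter channels so the EGFP/mCherry
# ratio stays informative about acidification, not expression level.
NUCLEUS_AMP = 150.0
NETWORK_AMP = 100.0
PUNCTUM_AMP = 120.0
CYTO_HAZE = 6.0  # diffuse out-of-focus reporter signal across the cell body
LC3_AMP = 110.0
P62_AMP = 130.0
TOMM20_AMP = 100.0
_CELL_GAP = 4  # minimum clearance between neighbouring cell disks, px
_DISK2 = np.array(  # radius-2 disk structuring element
    [[0, 0, 1, 0, 0], [0, 1, 1, 1, 0], [1, 1, 1, 1, 1], [0, 1, 1, 1, 0], [0, 0, 1, 0, 0]],
    dtype=bool,
)


class PackingError(ValueError):
    """Cells cannot be placed without violating the field-area budget."""


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian acquisition noise.

    poisson_scaling converts intensity units to expected photon counts
    (larger = more photons = less shot noise); 0 disables shot noise.
    gaussian_sd is additive read noise in intensity units.
    """

    gaussian_sd: float = 2.0
    poisson_scaling: float = 0.5

    @property
    def is_noise_free(self) -> bool:
        return self.gaussian_sd == 0 and self.poisson_scaling == 0


NOISE_FREE = NoiseModel(gaussian_sd=0.0, poisson_scaling=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated reporter field."""

    field_shape: tuple[int, int] = (456, 456)
    n_cells: int = 100
    cell_radius_px: tuple[float, float] = (16.0, 1.5)  # mean, sd
    mito_segments_per_cell: int = 4
    acidified_rate: float = 1.0  # expected basal red-only puncta per cell
    lc3_puncta_per_cell: float = 0.0
    lc3_mito_overlap_fraction: float = 0.0
    psf_sigma_px: float = 0.8
    noise_model: NoiseModel = dc_field(default_factory=NoiseModel)
    bleedthrough: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.acidified_rate < 0 or self.lc3_puncta_per_cell < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.lc3_mito_overlap_fraction <= 1.0):
            raise ValueError("lc3_mito_overlap_fraction must lie in [0, 1]")
        if not (0.0 <= self.bleedthrough <= 1.0):
            raise ValueError("bleedthrough must lie in [0, 1]")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be >= 0")
        mean_area = np.pi * self.cell_radius_px[0] ** 2
        budget = 0.8 * self.field_shape[0] * self.field_shape[1]
        if mean_area * self.n_cells > budget:
            raise PackingError(
                f"mean cell area x n_cells = {mean_area * self.n_cells:.0f} px "
                f"exceeds 80% of the field area ({budget:.0f} px)"
            )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative treatment acting on the acidified-puncta rate.

    acidified_multiplier > 1 models an inducer (e.g. the iron chelator DFP);
    a value in [0, 1) models an inhibitor. lysosomal_block models a V-ATPase
    inhibitor added late in the treatment: the induced excess re-acquires
    EGFP (rendered dual-channel) while the pre-existing basal red-only
    population persists. lc3_multiplier scales the free LC3 puncta rate.
    """

    label: str = "control"
    acidified_multiplier: float = 1.0
    dose: float = 0.0  # informational, µM
    lysosomal_block: bool = False
    lc3_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.acidified_multiplier < 0:
            raise ValueError("acidified_multiplier must be >= 0")
        if self.lc3_multiplier < 0:
            raise ValueError("lc3_multiplier must be >= 0")


CONTROL = TreatmentEffect()


def _grid_slots(shape: tuple[int, int], n: int, r_max: float) -> tuple[float, list]:
    """Jittered-grid placement slots guaranteeing non-overlapping disks."""
    pitch = 2.0 * r_max + _CELL_GAP
    gy = int(shape[0] // pitch)
    gx = int(shape[1] // pitch)
    if gy * gx < n:
        raise PackingError(
            f"cannot place {n} cells of max radius {r_max:.1f} px on a "
            f"{shape[0]}x{shape[1]} field ({gy * gx} slots available)"
        )
    slots = [
        ((iy + 0.5) * pitch, (ix + 0.5) * pitch) for iy in range(gy) for ix in range(gx)
    ]
    return pitch, slots


def _disk_mask_coords(center, radius, shape):
    """Pixel coordinates of a filled disk, clipped to `shape` (row, col arrays)."""
    cy, cx = center
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)) + 1, shape[0])
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)) + 1, shape[1])
    if y1 <= y0 or x1 <= x0:
        return np.empty(0, int), np.empty(0, int)
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    inside = yy * yy + xx * xx <= radius * radius
    rr, cc = np.nonzero(inside)
    return rr + y0, cc + x0


def _paint_disk(arr: np.ndarray, center: tuple[float, float], radius: float, value) -> None:
    rr, cc = _disk_mask_coords(center, radius, arr.shape)
    arr[rr, cc] = value


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(img, dtype=np.float64)
    if noise.poisson_scaling > 0:
        out = out.copy()
        pos = out > 0  # Poisson(0) = 0, so only positive pixels need draws
        out[pos] = rng.poisson(out[pos] * noise.poisson_scaling) / noise.poisson_scaling
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


def _place_punctum(
    rng: np.random.Generator,
    allowed_base: np.ndarray,
    grid_y: np.ndarray,
    grid_x: np.ndarray,
    placed: list,
    radius: float,
    shrink: np.ndarray,
    margin: float = 3.0,
):
    """Pick a punctum centre from `allowed_base` shrunk by `shrink` >= radius+margin
    and a pairwise clearance of `margin` from every already-placed punctum.

    `shrink` is the distance of each candidate pixel to the nearest statically
    forbidden region; puncta placed earlier are handled incrementally, so
    placement is exact without repeated distance transforms.
    """
    allowed = allowed_base & (shrink > radius + margin)
    for (py, px), pr_old in placed:
        d2 = (grid_y - py) ** 2 + (grid_x - px) ** 2
        allowed &= d2 > (radius + pr_old + margin) ** 2
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        return None
    pick = idx[rng.integers(idx.size)]
    return np.unravel_index(pick, allowed.shape)


def _enforce_min_gap(mask: np.ndarray, min_gap: float) -> np.ndarray:
    """Drop smaller connected pieces lying closer than `min_gap` to a kept one.

    Guarantees that every pair of distinct rendered structures is separated by
    at least `min_gap` pixels, so connectivity is unambiguous after any
    realistic blur and truth objects correspond 1:1 to detectable components.
    """
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    order = sorted(range(1, n + 1), key=lambda i: (-sizes[i], i))
    kept = np.zeros_like(mask)
    for lid in order:
        comp = lab == lid
        if kept.any():
            gap = ndi.distance_transform_edt(~kept)[comp].min()
            if gap < min_gap:
                continue
        kept |= comp
    return kept


def generate_field(
    config: SimulationConfig, effect: TreatmentEffect = CONTROL
) -> tuple[ImageField, GroundTruth]:
    """Render one reporter field and its exact ground truth.

    Raises :class:`PackingError` when the requested cells cannot be placed.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.field_shape
    r_mean, r_sd = config.cell_radius_px
    r_lo, r_hi = max(6.0, r_mean - 3 * r_sd), r_mean + 3 * r_sd

    pitch, slots = _grid_slots((H, W), config.n_cells, r_hi)
    order = rng.permutation(len(slots))[: config.n_cells]

    cells = np.zeros((H, W), dtype=np.int32)
    nuclei = np.zeros((H, W), dtype=np.int32)
    mito = np.zeros((H, W), dtype=np.int32)
    lc3_lab = np.zeros((H, W), dtype=np.int32)
    egfp = np.zeros((H, W), dtype=np.float64)
    mch = np.zeros((H, W), dtype=np.float64)
    nuc_ch = np.zeros((H, W), dtype=np.float64)
    lc3_ch = np.zeros((H, W), dtype=np.float64)

    object_class: dict[int, str] = {}
    rows = []
    next_mito = 1
    next_lc3 = 1
    want_lc3 = config.lc3_puncta_per_cell > 0 or config.lc3_mito_overlap_fraction > 0
    lam_basal = config.acidified_rate
    lam_eff = lam_basal * effect.acidified_multiplier

    struct8 = np.ones((3, 3), bool)
    for idx, slot_i in enumerate(order):
        cid = idx + 1
        r = float(np.clip(rng.normal(r_mean, r_sd), r_lo, r_hi))
        sy, sx = slots[slot_i]
        j = max(0.0, pitch / 2.0 - r - _CELL_GAP / 2.0)
        cy = float(np.clip(sy + rng.uniform(-j, j), r + 1, H - r - 2))
        cx = float(np.clip(sx + rng.uniform(-j, j), r + 1, W - r - 2))

        # all per-cell work happens on a local crop around the cell disk
        y0, y1 = max(int(cy - r) - 4, 0), min(int(cy + r) + 5, H)
        x0, x1 = max(int(cx - r) - 4, 0), min(int(cx + r) + 5, W)
        win = (slice(y0, y1), slice(x0, x1))
        lsh = (y1 - y0, x1 - x0)
        ly, lx = cy - y0, cx - x0

        gyv = np.arange(lsh[0], dtype=np.float64)[:, None]
        gxv = np.arange(lsh[1], dtype=np.float64)[None, :]
        radial = np.hypot(gyv - ly, gxv - lx)
        cell_mask = radial <= r
        cells[win][cell_mask] = cid

        r_nuc = 0.32 * r
        ny = ly + rng.uniform(-1.5, 1.5)
        nx = lx + rng.uniform(-1.5, 1.5)
        nuc_mask = np.zeros(lsh, dtype=bool)
        _paint_disk(nuc_mask, (ny, nx), r_nuc, True)
        nuclei[win][nuc_mask] = cid
        nuc_ch[win][nuc_mask] = NUCLEUS_AMP * rng.uniform(0.9, 1.1)

        nuc_pad = np.zeros(lsh, dtype=bool)
        _paint_disk(nuc_pad, (ny, nx), r_nuc + 2, True)

        # --- acidified (red-only) puncta, plus blocked dual-channel puncta --
        # Puncta are placed first so the Poisson count law is not truncated by
        # the network footprint; the network is carved around them below.
        if effect.lysosomal_block:
            n_red = rng.poisson(lam_basal)
            n_block = rng.poisson(max(lam_eff - lam_basal, 0.0))
        else:
            n_red = rng.poisson(lam_eff)
            n_block = 0

        shrink = r - radial  # exact distance to the cell boundary (disk geometry)
        allowed_base = radial >= r_nuc + 1
        puncta_specs = [("red_only")] * n_red + [("yellow")] * n_block
        placed = []  # (pos, pr, class)
        placed_geo = []
        n_red_placed = 0
        n_yellow_puncta = 0
        for pclass in puncta_specs:
            pr = float(rng.integers(2, 4))  # blob radius 2-3 px
            pos = _place_punctum(rng, allowed_base, gyv, gxv, placed_geo, pr, shrink)
            if pos is None:
                continue
            placed.append((pos, pr, pclass))
            placed_geo.append((pos, pr))
            if pclass == "red_only":
                n_red_placed += 1
            else:
                n_yellow_puncta += 1

        # --- perinuclear mitochondrial network (dual channel, "yellow") -----
        net = np.zeros(lsh, dtype=bool)
        for _ in range(config.mito_segments_per_cell):
            a1 = rng.uniform(0, 2 * np.pi)
            a2 = a1 + rng.uniform(-1.3, 1.3)
            ann_lo = r_nuc + 2
            ann_hi = max(r - 3, ann_lo + 0.5)
            rad1 = rng.uniform(ann_lo, ann_hi)
            rad2 = rng.uniform(ann_lo, ann_hi)
            p1 = (int(round(ly + rad1 * np.sin(a1))), int(round(lx + rad1 * np.cos(a1))))
            p2 = (int(round(ly + rad2 * np.sin(a2))), int(round(lx + rad2 * np.cos(a2))))
            rr, cc = draw_line(*p1, *p2)
            keep = (rr >= 0) & (rr < lsh[0]) & (cc >= 0) & (cc < lsh[1])
            net[rr[keep], cc[keep]] = True
        net = ndi.binary_dilation(net, structure=struct8)
        # carve a clearance moat so puncta stay distinct connected components
        moat = np.zeros(lsh, dtype=bool)
        for pos, pr, _pclass in placed:
            rr, cc = _disk_mask_coords(pos, pr + 3.5, lsh)
            moat[rr, cc] = True
        net &= cell_mask & ~nuc_pad & ~moat
        # opening removes sub-width slivers and necks left by carving, then
        # the gap rule keeps remaining pieces unambiguously separate
        net = ndi.binary_opening(net, structure=struct8, border_value=0)
        net = _enforce_min_gap(net, min_gap=3.5)

        net_cc, n_net_raw = cc_label(net, return_num=True, connectivity=2)
        n_net = 0
        for k in range(1, n_net_raw + 1):
            comp = net_cc == k
            if comp.sum() < 10:  # shards this small blur below detectability
                net[comp] = False
                continue
            mito[win][comp] = next_mito
            object_class[next_mito] = "yellow"
            amp = NETWORK_AMP * rng.uniform(0.85, 1.15)
            egfp[win][comp] += amp
            mch[win][comp] += amp
            next_mito += 1
            n_net += 1

        for pos, pr, pclass in placed:
            rr, cc = _disk_mask_coords(pos, pr, lsh)
            mito[win][rr, cc] = next_mito
            object_class[next_mito] = pclass
            amp = PUNCTUM_AMP * rng.uniform(0.85, 1.15)
            mch[win][rr, cc] += amp
            if pclass == "yellow":
                egfp[win][rr, cc] += amp
            next_mito += 1

        # --- free LC3 puncta (not touching mitochondria) --------------------
        n_lc3_free_placed = 0
        if want_lc3:
            static = (
                ndi.binary_dilation(mito[win] > 0, structure=struct8)
                | nuc_pad
                | ~cell_mask
            )
            shrink_lc3 = ndi.distance_transform_edt(~static)
            placed_lc3: list = []
            n_free = rng.poisson(config.lc3_puncta_per_cell * effect.lc3_multiplier)
            for _ in range(n_free):
                pr = float(rng.integers(2, 4))
                pos = _place_punctum(
                    rng, cell_mask, gyv, gxv, placed_lc3, pr, shrink_lc3
                )
                if pos is None:
                    continue
                placed_lc3.append((pos, pr))
                rr, cc = _disk_mask_coords(pos, pr, lsh)
                lc3_lab[win][rr, cc] = next_lc3
                lc3_ch[win][rr, cc] += LC3_AMP * rng.uniform(0.85, 1.15)
                next_lc3 += 1
                n_lc3_free_placed += 1

        rows.append(
            dict(
                cell_id=cid,
                nucleus_row=ny + y0,
                nucleus_col=nx + x0,
                n_red_only=n_red_placed,
                n_yellow=n_net + n_yellow_puncta,
                n_lc3=n_lc3_free_placed,  # coverage puncta added below
                n_lc3_on_mito=0,
            )
        )

    per_cell = pd.DataFrame(rows)

    # --- LC3 coverage of a stated fraction of mitochondrial objects ---------
    if config.lc3_mito_overlap_fraction > 0 and next_mito > 1:
        mito_ids = np.arange(1, next_mito)
        covered = mito_ids[rng.random(mito_ids.size) < config.lc3_mito_overlap_fraction]
        obj_slices = ndi.find_objects(mito)
        for oid in covered:
            sl = obj_slices[oid - 1]
            if sl is None:
                continue
            pad = 3
            sl2 = (
                slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, H)),
                slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, W)),
            )
            comp = mito[sl2] == oid
            # LC3 painted exactly on the object mask keeps the generator's
            # >= 3 px separation guarantees for the LC3 channel too
            lc3_lab[sl2][comp] = next_lc3
            lc3_ch[sl2][comp] = np.maximum(lc3_ch[sl2][comp], LC3_AMP * rng.uniform(0.85, 1.15))
            next_lc3 += 1
            host = int(np.bincount(cells[sl2][comp]).argmax())
            if host > 0:
                i = per_cell.index[per_cell.cell_id == host][0]
                per_cell.loc[i, "n_lc3"] += 1
                per_cell.loc[i, "n_lc3_on_mito"] += 1

    # recount n_yellow from the label map so truth matches rendered objects
    # even after tiny-component pruning
    if object_class:
        ids = np.array(sorted(object_class))
        classes = np.array([object_class[i] for i in ids])
        host_cell = ndi.labeled_comprehension(
            cells, mito, ids, lambda v: np.bincount(v.astype(int)).argmax(), int, 0
        )
        for j, cid in enumerate(per_cell.cell_id):
            mine = host_cell == cid
            per_cell.loc[j, "n_yellow"] = int((classes[mine] == "yellow").sum())
            per_cell.loc[j, "n_red_only"] = int((classes[mine] == "red_only").sum())

    # diffuse haze over the cell body helps cell segmentation mimic real images
    cell_body = cells > 0
    egfp[cell_body] += CYTO_HAZE
    mch[cell_body] += CYTO_HAZE

    if config.psf_sigma_px > 0:
        s = config.psf_sigma_px
        egfp = ndi.gaussian_filter(egfp, s)
        mch = ndi.gaussian_filter(mch, s)
        nuc_ch = ndi.gaussian_filter(nuc_ch, s)
        if want_lc3:
            lc3_ch = ndi.gaussian_filter(lc3_ch, s)

    b = config.bleedthrough
    if b > 0:
        egfp, mch = egfp + b * mch, mch + b * egfp

    noise = config.noise_model
    channels = {
        "nuclei": _apply_noise(nuc_ch, noise, rng),
        "egfp": _apply_noise(egfp, noise, rng),
        "mcherry": _apply_noise(mch, noise, rng),
    }
    if want_lc3:
        channels["lc3"] = _apply_noise(lc3_ch, noise, rng)

    fld = ImageField(channels=channels, provenance=f"sim:seed={config.seed}:{effect.label}")
    truth = GroundTruth(
        per_cell=per_cell,
        masks={
            "cells": LabelMap(cells, kind="cells"),
            "nuclei": LabelMap(nuclei, kind="nuclei"),
            "mito": LabelMap(mito, kind="mito"),
            "lc3": LabelMap(lc3_lab, kind="lc3"),
        },
        object_class=object_class,
    )
    return fld, truth


def generate_dose_series(
    config: SimulationConfig, effects: list[TreatmentEffect]
) -> list[tuple[ImageField, GroundTruth]]:
    """One field per treatment; field i uses seed ``config.seed + i``.

    A single-effect series is identical to one :func:`generate_field` call.
    """
    if not effects:
        raise ValueError("effects list is empty")
    doses = [e.dose for e in effects]
    if any(b < a for a, b in zip(doses, doses[1:])):
        raise ValueError("effects must be ordered by non-decreasing dose")
    return [
        generate_field(config.replace(seed=config.seed + i), eff)
        for i, eff in enumerate(effects)
    ]


# --------------------------------------------------------------------------
# tissue mode: motor-neuron somata with p62 puncta and TOMM20 fill
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueConfig:
    """Conditions for one simulated spinal-cord section (max-projected stack)."""

    field_shape: tuple[int, int] = (240, 320)
    n_mn: int = 12
    mn_radius_px: tuple[float, float] = (24.0, 3.0)
    p62_puncta_per_mn: float = 8.0
    p62_punctum_radius_px: float = 2.0
    tomm20_fill_fraction: float = 0.7
    psf_sigma_px: float = 0.8
    noise_model: NoiseModel = dc_field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mn < 1:
            raise ValueError("n_mn must be >= 1")
        if not (0.0 <= self.tomm20_fill_fraction <= 1.0):
            raise ValueError("tomm20_fill_fraction must lie in [0, 1]")
        if self.p62_puncta_per_mn < 0:
            raise ValueError("p62_puncta_per_mn must be >= 0")

    def replace(self, **kw) -> "TissueConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TissueEffect:
    """Group-level scaling of the tissue truth (e.g. transgenic p62 decrease)."""

    label: str = "WT"
    p62_multiplier: float = 1.0
    tomm20_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.p62_multiplier < 0 or self.tomm20_multiplier < 0:
            raise ValueError("multipliers must be >= 0")


def generate_tissue_section(
    config: TissueConfig, effect: TissueEffect = TissueEffect()
) -> tuple[ImageField, GroundTruth]:
    """Render one section with per-MN truth areas (px) for p62 and TOMM20."""
    rng = np.random.default_rng(config.seed)
    H, W = config.field_shape
    r_mean, r_sd = config.mn_radius_px
    r_lo, r_hi = max(10.0, r_mean - 3 * r_sd), r_mean + 3 * r_sd
    pitch, slots = _grid_slots((H, W), config.n_mn, r_hi)
    order = rng.permutation(len(slots))[: config.n_mn]

    mn = np.zeros((H, W), dtype=np.int32)
    dapi = np.zeros((H, W), dtype=np.float64)
    p62 = np.zeros((H, W), dtype=np.float64)
    tomm = np.zeros((H, W), dtype=np.float64)
    rows = []

    fill = min(config.tomm20_fill_fraction * effect.tomm20_multiplier, 1.0)
    lam_p62 = config.p62_puncta_per_mn * effect.p62_multiplier

    for idx, slot_i in enumerate(order):
        mid = idx + 1
        r = float(np.clip(rng.normal(r_mean, r_sd), r_lo, r_hi))
        sy, sx = slots[slot_i]
        j = max(0.0, pitch / 2.0 - r - _CELL_GAP / 2.0)
        cy = float(np.clip(sy + rng.uniform(-j, j), r + 1, H - r - 2))
        cx = float(np.clip(sx + rng.uniform(-j, j), r + 1, W - r - 2))
        rr, cc = _disk_mask_coords((cy, cx), r, (H, W))
        mn[rr, cc] = mid
        _paint_disk(dapi, (cy + rng.uniform(-2, 2), cx + rng.uniform(-2, 2)), 0.3 * r,
                    NUCLEUS_AMP * rng.uniform(0.9, 1.1))

        # TOMM20: exactly round(fill * area) pixels nearest the soma centre
        area = rr.size
        k = int(round(fill * area))
        if k > 0:
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            sel = np.argsort(d2, kind="stable")[:k]
            tomm[rr[sel], cc[sel]] = TOMM20_AMP
        tomm_area = k

        n_p = rng.poisson(lam_p62)
        pr = config.p62_punctum_radius_px
        y0, x0 = max(int(cy - r) - 2, 0), max(int(cx - r) - 2, 0)
        y1, x1 = min(int(cy + r) + 3, H), min(int(cx + r) + 3, W)
        gyv = np.arange(y1 - y0, dtype=np.float64)[:, None]
        gxv = np.arange(x1 - x0, dtype=np.float64)[None, :]
        radial = np.hypot(gyv - (cy - y0), gxv - (cx - x0))
        shrink = r - radial  # distance to soma boundary
        placed_p62: list = []
        for _ in range(n_p):
            pos = _place_punctum(
                rng, radial <= r, gyv, gxv, placed_p62, pr, shrink, margin=1.0
            )
            if pos is None:
                continue
            placed_p62.append((pos, pr))
            rr2, cc2 = _disk_mask_coords((pos[0] + y0, pos[1] + x0), pr, (H, W))
            p62[rr2, cc2] = P62_AMP
        p62_area = int(((p62 > 0) & (mn == mid)).sum())

        rows.append(
            dict(mn_id=mid, mn_area_px=int(area), p62_area_px=p62_area, tomm20_area_px=tomm_area)
        )

    if config.psf_sigma_px > 0:
        s = config.psf_sigma_px
        dapi = ndi.gaussian_filter(dapi, s)
        p62 = ndi.gaussian_filter(p62, s)
        tomm = ndi.gaussian_filter(tomm, s)

    noise = config.noise_model
    fld = ImageField(
        channels={
            "nuclei": _apply_noise(dapi, noise, rng),
            "p62": _apply_noise(p62, noise, rng),
            "tomm20": _apply_noise(tomm, noise, rng),
        },
        provenance=f"sim-tissue:seed={config.seed}:{effect.label}",
    )
    truth = GroundTruth(
        per_cell=pd.DataFrame(),
        masks={"mn": LabelMap(mn, kind="mn")},
        tissue_truth=pd.DataFrame(rows),
    )
    return fld, truth


def generate_tissue_cohort(
    config: TissueConfig,
    group_effects: dict[str, TissueEffect],
    n_animals_per_group: int = 4,
    stacks_per_animal: int = 4,
    base_seed: int = 0,
) -> list[dict]:
    """Sections for a multi-animal cohort; seeds advance by a running counter.

    Returns one record per section: group, animal_id, stack_id, field, truth.
    """
    out = []
    counter = 0
    for group, eff in group_effects.items():
        for a in range(n_animals_per_group):
            animal_id = f"{group}-a{a + 1}"
            for s in range(stacks_per_animal):
                fld, truth = generate_tissue_section(
                    config.replace(seed=base_seed + counter), eff
                )
                out.append(
                    dict(group=group, animal_id=animal_id, stack_id=f"{animal_id}-s{s + 1}",
                         field=fld, truth=truth)
                )
                counter += 1
    return out
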