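"""Shared fixtures: small simulated fields with ground truth, and helpers to
match detected objects/cells back to the simulator's truth labels."""
from __future__ import annotations

import numpy as np
import pytest

from mitoquant import simulate as sim
from mitoquant.pipeline import quantify_field

# a 4x4 grid of default-size cells fits a 200x200 field
SMALL = dict(field_shape=(200, 200), n_cells=16)


@pytest.fixture(scope="session")
def small_nf():
    """Noise-free small field with moderate mitophagy, plus its truth."""
    cfg = sim.SimulationConfig(**SMALL, acidified_rate=3.0,
                               noise_model=sim.NOISE_FREE, seed=11)
    fld, truth = sim.generate_field(cfg)
    return cfg, fld, truth


@pytest.fixture(scope="session")
def small_noisy():
    cfg = sim.SimulationConfig(**SMALL, acidified_rate=3.0, seed=12)
    fld, truth = sim.generate_field(cfg)
    return cfg, fld, truth


@pytest.fixture(scope="session")
def small_nf_quant(small_nf):
    _, fld, truth = small_nf
    return fld, truth, quantify_field(fld)


def map_cells_to_truth(det_cells, truth):
    """detected cell label -> truth cell label, by majority pixel overlap."""
    tc = truth.masks["cells"].labels
    out = {}
    for cid in det_cells.ids:
        votes = np.bincount(tc[det_cells.labels == cid])
        out[int(cid)] = int(votes.argmax())
    return out


def map_objects_to_truth(det_mito, truth):
    """detected mito label -> truth mito label (majority overlap; 0 = none)."""
    tm = truth.masks["mito"].labels
    out = {}
    for oid in det_mito.ids:
        votes = np.bincount(tm[det_mito.labels == oid])
        out[int(oid)] = int(votes.argmax())
    return out


def per_cell_count_errors(result, truth):
    """Absolute red-only count error per detected (non-border) cell."""
    truth_red = dict(zip(truth.per_cell.cell_id, truth.per_cell.n_red_only))
    c2t = map_cells_to_truth(result.cells, truth)
    errors = []
    for rec in result.cell_records:
        if rec.border_touching:
            continue
        t_id = c2t[rec.cell_id]
        if t_id == 0:
            continue
        errors.append(abs(truth_red[t_id] - rec.n_red_only))
    return np.asarray(errors)
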