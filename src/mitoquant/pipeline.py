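"""End-to-end conveniences tying segmentation, classification and statistics
together; this is what the CLI, the analysis drivers and the acceptance
checks call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import simulate
from .classify import (
    DEFAULT_RATIO_THRESHOLD,
    CellRecord,
    FieldSummary,
    MitoObject,
    cells_table,
    measure_and_classify,
    mitophagy_rate,
)
from .segment import DEFAULT_PARAMS, SegmentationParams, segment_cells, segment_mito_objects, segment_nuclei
from .stats import ConditionSummary, screen_report
from .types import GroundTruth, ImageField, LabelMap


@dataclass
class QuantResult:
    nuclei: LabelMap
    cells: LabelMap
    mito: LabelMap
    objects: list[MitoObject]
    cell_records: list[CellRecord]
    summary: FieldSummary

    @property
    def cells_df(self) -> pd.DataFrame:
        return cells_table(self.cell_records)


def quantify_field(
    field: ImageField,
    params: SegmentationParams = DEFAULT_PARAMS,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    exclude_border: bool = True,
) -> QuantResult:
    """Full reporter quantification of one field: nuclei -> cells -> mito ->
    classify -> per-cell mitophagy rate."""
    nuclei = segment_nuclei(field, params)
    cells = segment_cells(field, nuclei, params)
    mito = segment_mito_objects(field, cells, params)
    objects = measure_and_classify(field, mito, cells, ratio_threshold)
    records, summary = mitophagy_rate(objects, cells, exclude_border=exclude_border)
    return QuantResult(nuclei, cells, mito, objects, records, summary)


def measure_condition(
    config: simulate.SimulationConfig,
    effect: simulate.TreatmentEffect,
    n_fields: int = 3,
    seed: int = 0,
    **quant_kw,
) -> ConditionSummary:
    """Simulate and quantify replicate fields of one condition.

    Field f of condition uses seed ``seed + f``; the replicate unit is the
    field mean (mimicking independent experiments).
    """
    means = []
    for f in range(n_fields):
        fld, _ = simulate.generate_field(config.replace(seed=seed + f), effect)
        means.append(quantify_field(fld, **quant_kw).summary.mean_red_only_per_cell)
    return ConditionSummary(condition=effect.label, replicate_means=tuple(means))


def run_screen(
    config: simulate.SimulationConfig,
    compound_multipliers: dict[str, float],
    inducer_multiplier: float = 3.0,
    n_fields: int = 3,
    seed: int = 0,
    threshold: float = 50.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[ConditionSummary]]:
    """Emulate the high-content screen: control, inducer, and co-treatments.

    Every compound is co-applied with the inducer, so its effective rate
    multiplier is ``inducer_multiplier * compound_multiplier``. Per-condition
    seeds advance by a deterministic counter over conditions and fields.
    """
    conditions = [simulate.TreatmentEffect("control", 1.0),
                  simulate.TreatmentEffect("inducer", inducer_multiplier)]
    for name, mult in compound_multipliers.items():
        conditions.append(
            simulate.TreatmentEffect(name, inducer_multiplier * mult)
        )
    summaries = []
    for i, eff in enumerate(conditions):
        summaries.append(
            measure_condition(config, eff, n_fields=n_fields, seed=seed + 1000 * i)
        )
    report = screen_report(
        summaries, control_label="control", inducer_label="inducer",
        threshold=threshold, rng=rng or np.random.default_rng(seed),
    )
    return report, summaries
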