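"""Core in-memory containers shared by the simulator and the quantification pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Channel roles the pipeline understands. ``nuclei``, ``egfp`` and ``mcherry`` are
#: required for reporter quantification; the rest are optional add-ons.
KNOWN_ROLES = ("nuclei", "egfp", "mcherry", "lc3", "p62", "tomm20")


@dataclass
class ImageField:
    """One multi-channel field of view.

    channels maps a role name (e.g. ``"mcherry"``) to a 2-D float raster. All
    rasters share one pixel grid; intensities are non-negative in arbitrary
    fluorescence units.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel rasters disagree in shape: {sorted(shapes)}")
        for role, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel role {role!r} missing; present: {sorted(self.channels)}"
            ) from None


@dataclass
class LabelMap:
    """Integer label image; 0 is background, labels are positive integers."""

    labels: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)

    def border_labels(self) -> set[int]:
        """Labels touching the image border."""
        edge = np.concatenate(
            [self.labels[0], self.labels[-1], self.labels[:, 0], self.labels[:, -1]]
        )
        return set(int(v) for v in np.unique(edge) if v > 0)


@dataclass
class GroundTruth:
    """Simulator-emitted truth for one field; the testing oracle.

    per_cell columns: cell_id, nucleus_row, nucleus_col, n_red_only, n_yellow,
    n_lc3, n_lc3_on_mito. object_class maps a mito label to "yellow"/"red_only".
    """

    per_cell: pd.DataFrame
    masks: dict[str, LabelMap]
    object_class: dict[int, str] = field(default_factory=dict)
    tissue_truth: Optional[pd.DataFrame] = None
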