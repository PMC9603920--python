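"""File formats: multi-page TIFF fields with a channel-role sidecar, label-map
TIFFs, CSV tables, JSON summaries and run manifests.

A field on disk is ``<name>.tif`` (one page per channel, float32) plus
``<name>.channels.json`` recording the channel order and provenance; the
sidecar can be replaced by an explicit role list at read time. No operation
mutates input files.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import ImageField, LabelMap


def write_field(field: ImageField, path: str | Path) -> Path:
    """Write a field as a multi-page float32 TIFF plus its channel sidecar."""
    path = Path(path)
    roles = list(field.channels)
    tifffile.imwrite(
        path,
        np.stack([field.channels[r].astype(np.float32) for r in roles]),
        photometric="minisblack",
    )
    sidecar = path.with_suffix(".channels.json")
    sidecar.write_text(
        json.dumps({"channels": roles, "pixel_size": field.pixel_size,
                    "provenance": field.provenance}, indent=2)
    )
    return path


def read_field(path: str | Path, roles: Optional[Sequence[str]] = None) -> ImageField:
    """Read a multi-page TIFF; channel roles from the sidecar or `roles`.

    Integer rasters (e.g. 16-bit acquisitions) are promoted to float32 so all
    downstream intensity handling happens on one scale.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    sidecar = path.with_suffix(".channels.json")
    if roles is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"{sidecar} missing and no channel roles given; cannot resolve pages"
            )
        meta = json.loads(sidecar.read_text())
        roles = meta["channels"]
    if len(roles) != stack.shape[0]:
        raise ValueError(
            f"{len(roles)} roles for {stack.shape[0]} TIFF pages in {path.name}"
        )
    channels = {r: np.asarray(p, dtype=np.float32) for r, p in zip(roles, stack)}
    return ImageField(
        channels=channels,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        provenance=str(meta.get("provenance", str(path))),
    )


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    return path


def read_labels(path: str | Path, kind: str = "") -> LabelMap:
    return LabelMap(np.asarray(tifffile.imread(Path(path)), dtype=np.int32), kind=kind)


def read_mn_polygons(path: str | Path, shape: tuple[int, int]) -> LabelMap:
    """Rasterize a motor-neuron ROI file (JSON) into an MN label map.

    Format: ``{"rois": [{"mn_id": 1, "vertices": [[row, col], ...]}, ...]}``,
    one closed polygon per MN, vertices in pixel coordinates.
    """
    from skimage.draw import polygon as draw_polygon

    doc = json.loads(Path(path).read_text())
    labels = np.zeros(shape, dtype=np.int32)
    for roi in doc["rois"]:
        verts = np.asarray(roi["vertices"], dtype=float)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        labels[rr, cc] = int(roi["mn_id"])
    return LabelMap(labels, kind="mn")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path


def write_manifest(path: str | Path, *, command: str, parameters: dict, seed: Optional[int],
                   inputs: Sequence[str] = (), outputs: Sequence[str] = ()) -> Path:
    """Machine-readable record from which a run can be reconstructed."""
    import mitoquant

    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "versions": {
            "mitoquant": mitoquant.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    return write_json(manifest, path)
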