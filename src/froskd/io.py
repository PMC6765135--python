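"""Reading and writing the on-disk formats.

Stacks go to multi-page 16-bit TIFF (one file per field, labeled and
control), label masks to integer TIFF, ground truth to JSON and the
simulation config to YAML.  Intensities are rounded and clipped to the
uint16 range on write; keep ``photons_per_molecule`` modest if lossless
round-trips matter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List

import numpy as np
import tifffile
import yaml

from .simulate import GroundTruthCell, SimulatedField, SimulatedPopulation, SimulationConfig

__all__ = [
    "write_population",
    "read_fields",
    "read_ground_truth",
    "load_config",
    "dump_config",
]


def _to_uint16(stack: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_population(population: SimulatedPopulation, outdir) -> None:
    """Write stacks, masks, ground truth and config under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, fld in enumerate(population.fields):
        tifffile.imwrite(outdir / f"labeled_{i:03d}.tif", _to_uint16(fld.labeled))
        tifffile.imwrite(outdir / f"control_{i:03d}.tif", _to_uint16(fld.control))
        tifffile.imwrite(outdir / f"mask_{i:03d}.tif", fld.mask.astype(np.uint16))
    truth = [dataclasses.asdict(c) for c in population.cells]
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    dump_config(population.config, outdir / "config.yaml")


def read_fields(directory) -> List[SimulatedField]:
    """Read labeled/control/mask TIFF triplets written by :func:`write_population`."""
    directory = Path(directory)
    fields = []
    for labeled_path in sorted(directory.glob("labeled_*.tif")):
        idx = labeled_path.stem.split("_")[-1]
        labeled = tifffile.imread(labeled_path).astype(float)
        control_path = directory / f"control_{idx}.tif"
        control = tifffile.imread(control_path).astype(float) if control_path.exists() else np.zeros_like(labeled)
        mask = tifffile.imread(directory / f"mask_{idx}.tif")
        fields.append(SimulatedField(labeled=labeled, control=control, mask=mask))
    if not fields:
        raise FileNotFoundError(f"no labeled_*.tif stacks under {directory}")
    return fields


def read_ground_truth(path) -> List[GroundTruthCell]:
    raw = json.loads(Path(path).read_text())
    cells = []
    for entry in raw:
        entry["dot_position"] = tuple(entry["dot_position"])
        entry["nucleus_center"] = tuple(entry["nucleus_center"])
        cells.append(GroundTruthCell(**entry))
    return cells


def load_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("cell_semi_axis_y", "cell_semi_axis_x"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def dump_config(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    for key in ("cell_semi_axis_y", "cell_semi_axis_x"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
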