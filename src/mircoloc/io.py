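"""File I/O: TIFF stacks with channel-role metadata, ground-truth and
result CSV tables, and YAML/JSON round-tripping of parameters."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CHANNEL_ROLES, ImageStack, RoleError
from .simulate import GroundTruth, SimulationParams


def write_stack(stack: ImageStack, path) -> Path:
    """Write an ImageStack as a multi-page TIFF.

    The C x Z x H x W layout, channel roles and pixel size go into a JSON
    image description, so a round-trip restores the stack bit-exactly.
    Bytes are deterministic for identical inputs (no timestamps written).
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "shape": list(stack.data.shape),
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "pixel_size_nm": stack.pixel_size_nm,
    }
    tifffile.imwrite(path, stack.data, photometric="minisblack",
                     description=json.dumps(meta, sort_keys=True))
    return path


def read_stack(path, channel_roles: Mapping[int, str] | None = None,
               pixel_size_nm: float | None = None,
               require: tuple[str, ...] = CHANNEL_ROLES) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` (or any C/Z TIFF
    plus a sidecar channel map).

    ``channel_roles`` / ``pixel_size_nm`` override or substitute missing
    file metadata.  Raises :class:`RoleError` naming any role in
    ``require`` that cannot be resolved.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if "shape" in meta:
        data = data.reshape(meta["shape"])
    if data.ndim == 3:  # single channel or single z: promote conservatively
        data = data[:, None, :, :]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {data.shape} as (C, Z, H, W)")

    roles: dict[int, str] = {}
    if "channel_roles" in meta:
        roles = {int(k): v for k, v in meta["channel_roles"].items()}
    if channel_roles is not None:
        roles = dict(channel_roles)
    missing = [r for r in require if r not in roles.values()]
    if missing:
        raise RoleError(f"role unresolved: {', '.join(missing)}")

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError("pixel size not in metadata; pass pixel_size_nm")
    return ImageStack(data=data, channel_roles=roles, pixel_size_nm=float(px))


# ---------------------------------------------------------------------------
# ground truth and tables


def write_ground_truth(truth: GroundTruth, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": out_dir / "truth_spots.csv",
        "cells": out_dir / "truth_cells.csv",
        "per_cell": out_dir / "truth_per_cell.csv",
    }
    truth.spots.to_csv(paths["spots"], index=False, na_rep="NA")
    truth.cells.to_csv(paths["cells"], index=False, na_rep="NA")
    truth.per_cell_truth.to_csv(paths["per_cell"], index=False, na_rep="NA")
    return paths


def read_ground_truth(out_dir) -> GroundTruth:
    out_dir = Path(out_dir)
    spots = pd.read_csv(out_dir / "truth_spots.csv")
    cells = pd.read_csv(out_dir / "truth_cells.csv")
    per_cell = pd.read_csv(out_dir / "truth_per_cell.csv")
    return GroundTruth(spots=spots, cells=cells, per_cell_truth=per_cell)


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir,
                 manifest: Mapping | None = None) -> dict[str, Path]:
    """Write result tables as CSV with stable headers plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="NA")
        paths[name] = p
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
        paths["manifest"] = p
    return paths


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# parameters / config


def save_params(params: SimulationParams, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
    return path


def load_params(path) -> SimulationParams:
    return SimulationParams.from_dict(yaml.safe_load(Path(path).read_text()))
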