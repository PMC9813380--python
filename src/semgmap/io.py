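"""Delimited-text artifacts and their JSON sidecars.

Recordings travel as CSV matrices (samples x 64 columns, header
``ch00..ch63``) with a companion ``<name>.json`` sidecar holding the
sampling rate, grid geometry and generator metadata. Map stacks are one
CSV per condition (t rows x 64 pixel columns, header ``px_<r>_<c>``) plus
a sidecar with the segmentation scheme, normalization constant and window
starts. Numeric round-trips are lossless (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .grid import ElectrodeGrid
from .maps import ActivationMapStack, SegmentationScheme
from .simulate import Recording

_FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording_csv(rec: Recording, path) -> Path:
    path = Path(path)
    header = ",".join(f"ch{ch:02d}" for ch in range(rec.n_channels))
    np.savetxt(path, rec.data, fmt=_FLOAT_FMT, delimiter=",", header=header, comments="")
    sidecar = {
        "fs_hz": rec.fs_hz,
        "grid": rec.grid.to_dict(),
        "meta": _jsonable(rec.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording_csv(path) -> Recording:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    grid = ElectrodeGrid.from_dict(sidecar["grid"])
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        n_cols = len(header.split(","))
        if n_cols != grid.n_channels:
            raise FormatError(
                f"line 1: expected {grid.n_channels} columns, found {n_cols}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(",")
            if len(cells) != n_cols:
                raise FormatError(
                    f"line {lineno}: expected {n_cols} columns, found {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric cell ({exc})") from exc
    if not rows:
        raise FormatError("recording file contains a header but no samples")
    return Recording(
        data=np.asarray(rows, dtype=float),
        fs_hz=sidecar["fs_hz"],
        grid=grid,
        meta=sidecar.get("meta", {}),
    )


def write_stack_csv(stack: ActivationMapStack, grid: ElectrodeGrid, path) -> Path:
    path = Path(path)
    vectors = stack.as_vectors(grid)
    header = ",".join(f"px_{r}_{c}" for r, c in grid.channel_order)
    np.savetxt(path, vectors, fmt=_FLOAT_FMT, delimiter=",", header=header, comments="")
    sidecar = {
        "scheme": {
            "window_ms": stack.scheme.window_ms,
            "overlap_pct": stack.scheme.overlap_pct,
            "N": stack.scheme.N,
            "R": stack.scheme.R,
        },
        "norm_constant": stack.norm_constant,
        "intensity": stack.intensity,
        "window_starts": stack.window_starts.tolist(),
        "grid": grid.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack_csv(path) -> tuple[ActivationMapStack, ElectrodeGrid]:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    grid = ElectrodeGrid.from_dict(sidecar["grid"])
    vectors = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if vectors.shape[1] != grid.n_channels:
        raise FormatError(
            f"expected {grid.n_channels} pixel columns, found {vectors.shape[1]}"
        )
    scheme = SegmentationScheme(**sidecar["scheme"])
    stack = ActivationMapStack(
        maps=grid.to_image(vectors),
        scheme=scheme,
        window_starts=np.asarray(sidecar["window_starts"], dtype=int),
        norm_constant=sidecar["norm_constant"],
        intensity=sidecar["intensity"],
    )
    return stack, grid


def write_feature_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
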