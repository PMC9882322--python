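"""File I/O: calibrated float TIFFs with YAML sidecars, trace and binding CSVs.

Pixel calibration is carried in a YAML sidecar next to each image
(``image.tif`` + ``image.yaml``) rather than in TIFF resolution tags, which
are unreliable across writers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import HeightMap
from .errors import ParameterError


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_height_map(path, hm: HeightMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, hm.grid.astype(np.float32))
    meta = {
        "rx_nm": float(hm.rx),
        "ry_nm": float(hm.ry),
        "background_nm": None if hm.background is None else float(hm.background),
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_height_map(path) -> HeightMap:
    path = Path(path)
    grid = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    if not side.exists():
        raise ParameterError(f"missing calibration sidecar {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    return HeightMap(
        grid=grid,
        rx=float(meta["rx_nm"]),
        ry=float(meta["ry_nm"]),
        background=meta.get("background_nm"),
    )


def write_multichannel(path, image: np.ndarray, pixel_size_nm: float) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({"pixel_size_nm": float(pixel_size_nm)}, fh, sort_keys=True)


def read_multichannel(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    image = tifffile.imread(path).astype(float)
    side = _sidecar(path)
    if not side.exists():
        raise ParameterError(f"missing calibration sidecar {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    return image, float(meta["pixel_size_nm"])


def write_traces_csv(path, times: np.ndarray, counts: np.ndarray) -> None:
    """Long-format trace table: trace_id, time_s, mean_counts."""
    counts = np.atleast_2d(counts)
    rows = []
    for i, trace in enumerate(counts):
        for t, v in zip(times, trace):
            rows.append({"trace_id": i, "time_s": float(t), "mean_counts": float(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path)
    required = {"trace_id", "time_s", "mean_counts"}
    if not required.issubset(df.columns):
        raise ParameterError(f"trace CSV must have columns {sorted(required)}")
    out = {}
    for tid, sub in df.groupby("trace_id", sort=True):
        sub = sub.sort_values("time_s")
        out[int(tid)] = (sub["time_s"].to_numpy(), sub["mean_counts"].to_numpy())
    return out
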