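"""File formats: single-channel TIFF images, headered CSV vector fields,
JSON/YAML configs and metrics."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracking import DisplacementField

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_config",
    "write_config",
    "write_metrics",
]

FIELD_COLUMNS = ["x", "y", "u", "v", "score", "status"]


def read_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got shape {img.shape}")
    return np.asarray(img)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def write_field(path: str | Path, field: DisplacementField) -> None:
    df = pd.DataFrame(
        {
            "x": field.x,
            "y": field.y,
            "u": field.u,
            "v": field.v,
            "score": field.score,
            "status": field.status.astype(str),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_field(path: str | Path) -> DisplacementField:
    df = pd.read_csv(path)
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing vector-field columns {missing}")
    return DisplacementField(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        u=df["u"].to_numpy(float),
        v=df["v"].to_numpy(float),
        score=df["score"].to_numpy(float),
        status=df["status"].to_numpy(object),
    )


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return cfg


def write_config(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=False))


def write_metrics(path: str | Path, metrics: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(metrics, indent=2, default=default))
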