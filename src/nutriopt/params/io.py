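"""Parameter file round-trips: YAML (canonical), JSON, and a flat CSV export.

The on-disk schema is versioned with a top-level ``schema_version`` key.
Numpy arrays serialize as nested lists; :class:`Uncertain` values serialize
as ``{value, lo, hi, dist}`` mappings.
"""

from __future__ import annotations

import json
from dataclasses import fields, is_dataclass
from pathlib import Path
from typing import get_type_hints

import numpy as np
import pandas as pd
import yaml

from .model import (
    CauseParams,
    ParameterDraw,
    Uncertain,
    SCHEMA_VERSION,
)


def _encode(obj):
    if isinstance(obj, Uncertain):
        return {"value": obj.value, "lo": obj.lo, "hi": obj.hi, "dist": obj.dist}
    if is_dataclass(obj):
        return {f.name: _encode(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _decode(cls, data):
    if cls is Uncertain:
        return Uncertain(**data)
    if is_dataclass(cls):
        hints = get_type_hints(cls)
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            kwargs[f.name] = _decode_field(cls, f.name, hints[f.name], data[f.name])
        return cls(**kwargs)
    return data


def _decode_field(cls, name, hint, value):
    if hint is np.ndarray:
        return np.asarray(value, dtype=float)
    if hint is Uncertain:
        return Uncertain(**value)
    if is_dataclass(hint):
        return _decode(hint, value)
    if hint is dict or getattr(hint, "__origin__", None) is dict:
        # Dict-valued fields: causes (CauseParams), coverage baselines
        # (Uncertain), and plain float maps.
        if cls.__name__ == "ParameterDraw" and name == "causes":
            return {k: CauseParams(**v) for k, v in value.items()}
        if cls.__name__ == "CoverageSpec" and name == "baseline":
            return {k: Uncertain(**v) for k, v in value.items()}
        return dict(value)
    return value


def draw_to_dict(draw: ParameterDraw) -> dict:
    return _encode(draw)


def draw_from_dict(data: dict) -> ParameterDraw:
    version = data.get("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    return _decode(ParameterDraw, data)


def save_parameters(draw: ParameterDraw, path: str | Path) -> None:
    """Write a parameter file; format chosen by extension (.yaml/.yml/.json)."""
    path = Path(path)
    data = draw_to_dict(draw)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        raise ValueError(f"unknown parameter file extension: {path.suffix}")


def load_parameters(path: str | Path) -> ParameterDraw:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ValueError(f"unknown parameter file extension: {path.suffix}")
    return draw_from_dict(data)


def export_flat_rates(draw: ParameterDraw, path: str | Path | None = None) -> pd.DataFrame:
    """Flatten every numeric parameter into a tidy (parameter, index, value) CSV."""
    rows = []

    def walk(prefix, obj):
        enc = obj
        if isinstance(enc, Uncertain):
            rows.append((prefix, "", enc.value))
            return
        if is_dataclass(enc):
            for f in fields(enc):
                walk(f"{prefix}.{f.name}".lstrip("."), getattr(enc, f.name))
            return
        if isinstance(enc, dict):
            for k, v in enc.items():
                walk(f"{prefix}.{k}".lstrip("."), v)
            return
        if isinstance(enc, np.ndarray):
            for idx, v in np.ndenumerate(enc):
                rows.append((prefix, ",".join(map(str, idx)), float(v)))
            return
        if isinstance(enc, (int, float, np.floating, np.integer)):
            rows.append((prefix, "", float(enc)))

    walk("", draw)
    df = pd.DataFrame(rows, columns=["parameter", "index", "value"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
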