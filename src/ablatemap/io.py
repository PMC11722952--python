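"""File formats: TIFF stacks + YAML sidecars, CSV tables, JSON summaries.

Movies travel as two single-channel multi-page TIFF stacks (``green.tif``,
``red.tif``) with a ``meta.yaml`` sidecar carrying ``frame_rate`` (Hz),
``pixel_size`` (um/px) and the electrode geometry — one interleaved
multi-channel stack would be ambiguous across TIFF dialects. Tables are
UTF-8 comma-separated CSV with mandatory headers and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .movie import Movie
from .protocol import StimulusProtocol
from .segmentation import CellROI, LabelMap
from .spatial import CellResponseRecord, ElectrodeGeometry, PopulationSummary
from .synthetic import GroundTruthCell, SyntheticScene

__all__ = [
    "write_movie", "read_movie", "write_ground_truth", "read_ground_truth",
    "write_results", "read_records", "validate_summary", "SUMMARY_SCHEMA_PATH",
]

SUMMARY_SCHEMA_PATH = Path(__file__).parent / "summary_schema.json"


def write_movie(movie: Movie, outdir: str | Path,
                extra_meta: dict | None = None) -> dict[str, Path]:
    """Write green/red TIFF stacks plus the YAML metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"green": outdir / "green.tif", "meta": outdir / "meta.yaml"}
    tifffile.imwrite(paths["green"], movie.green.astype(np.float32))
    if movie.red is not None:
        paths["red"] = outdir / "red.tif"
        tifffile.imwrite(paths["red"], movie.red.astype(np.float32))
    meta = {"frame_rate": float(movie.frame_rate),
            "pixel_size": float(movie.pixel_size)}
    meta.update(movie.meta)
    if extra_meta:
        meta.update(extra_meta)
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(_jsonable(meta), fh)
    return paths


def read_movie(indir: str | Path) -> Movie:
    """Read a movie directory written by :func:`write_movie`.

    Raises with the offending field named on missing metadata or
    channel-shape mismatches.
    """
    indir = Path(indir)
    meta_path = indir / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("frame_rate", "pixel_size"):
        if key not in meta:
            raise ValueError(f"metadata field '{key}' is required in meta.yaml")
    green = tifffile.imread(indir / "green.tif")
    red_path = indir / "red.tif"
    red = tifffile.imread(red_path) if red_path.exists() else None
    if red is not None and red.shape != green.shape:
        raise ValueError(
            f"channel frame mismatch: green {green.shape} vs red {red.shape}"
        )
    frame_rate = float(meta.pop("frame_rate"))
    pixel_size = float(meta.pop("pixel_size"))
    return Movie(green=green, red=red, frame_rate=frame_rate,
                 pixel_size=pixel_size, meta=meta)


def write_ground_truth(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Ground truth as a JSON cells array plus a 16-bit label TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = [dataclasses.asdict(c) for c in scene.cells]
    payload = {
        "config": _jsonable(dataclasses.asdict(scene.config)),
        "protocol": dataclasses.asdict(scene.protocol),
        "astrocytes": scene.astrocytes.tolist(),
        "cells": _jsonable(cells),
    }
    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    lbl_path = outdir / "true_labels.tif"
    tifffile.imwrite(lbl_path, scene.label_image.astype(np.uint16))
    return {"ground_truth": gt_path, "labels": lbl_path}


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_results(records: list[CellResponseRecord], summary: PopulationSummary,
                  labelmap: LabelMap, outdir: str | Path,
                  traces: np.ndarray | None = None,
                  dff: np.ndarray | None = None,
                  provenance: dict | None = None) -> dict[str, Path]:
    """Write per-cell records CSV, summary JSON, label TIFF and traces CSV.

    The records CSV has one row per cell; column meanings are in the
    header names (distances in um, times in s, dF/F dimensionless).
    Traces go to long format (cell, frame, F, dff).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in records:
        row = dataclasses.asdict(r)
        row["plateau_intervals"] = ";".join(f"{a}-{b}"
                                           for a, b in r.plateau_intervals)
        rows.append(row)
    rec_df = pd.DataFrame(
        rows, columns=[f.name for f in dataclasses.fields(CellResponseRecord)]
    )
    paths["records"] = outdir / "records.csv"
    rec_df.to_csv(paths["records"], index=False)

    sdict = _jsonable(dataclasses.asdict(summary))
    if provenance:
        sdict["provenance"] = _jsonable(provenance)
    validate_summary(sdict)
    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(sdict, fh, indent=1)

    paths["labels"] = outdir / "labels.tif"
    tifffile.imwrite(paths["labels"], labelmap.label_image.astype(np.uint16))

    if traces is not None:
        n_cells, T = traces.shape
        long = pd.DataFrame({
            "cell": np.repeat(np.arange(1, n_cells + 1), T),
            "frame": np.tile(np.arange(T), n_cells),
            "F": traces.ravel(),
            "dff": dff.ravel() if dff is not None else np.nan,
        })
        paths["traces"] = outdir / "traces.csv"
        long.to_csv(paths["traces"], index=False)
    return paths


def read_records(path: str | Path) -> list[CellResponseRecord]:
    """Parse a records CSV back into record objects (round-trip of write)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        ivs = []
        if isinstance(row["plateau_intervals"], str) and row["plateau_intervals"]:
            ivs = [tuple(map(int, p.split("-")))
                   for p in row["plateau_intervals"].split(";")]
        out.append(CellResponseRecord(
            cell_id=int(row["cell_id"]), distance=float(row["distance"]),
            responded=bool(row["responded"]),
            time_to_peak=_opt_float(row["time_to_peak"]),
            sustained=bool(row["sustained"]),
            dff_at_5min=_opt_float(row["dff_at_5min"]),
            plateau_intervals=ivs,
            first_train=(None if pd.isna(row["first_train"])
                         else int(row["first_train"])),
            red_uptake=bool(row["red_uptake"]),
        ))
    return out


def validate_summary(summary: dict) -> None:
    """Structural check of a summary dict against the shipped JSON schema.

    Covers required keys, primitive types and nullability — the subset of
    JSON Schema the summary actually uses. Raises ValueError on the first
    violation.
    """
    with open(SUMMARY_SCHEMA_PATH) as fh:
        schema = json.load(fh)
    _check_object(summary, schema, "summary")


_TYPES = {"number": (int, float), "integer": int, "string": str,
          "boolean": bool, "array": list, "object": dict, "null": type(None)}


def _check_object(obj: dict, schema: dict, where: str) -> None:
    if not isinstance(obj, dict):
        raise ValueError(f"{where}: expected an object")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{where}: missing required key '{key}'")
    for key, sub in schema.get("properties", {}).items():
        if key not in obj:
            continue
        val = obj[key]
        types = sub.get("type", [])
        if isinstance(types, str):
            types = [types]
        if types:
            allowed = tuple(t for name in types for t in np.atleast_1d(_TYPES[name]))
            if isinstance(val, bool) and "boolean" not in types:
                raise ValueError(f"{where}.{key}: boolean not allowed")
            if not isinstance(val, allowed):
                raise ValueError(
                    f"{where}.{key}: {type(val).__name__} not in {types}"
                )
        if isinstance(val, dict) and "properties" in sub:
            _check_object(val, sub, f"{where}.{key}")


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and tuples to JSON types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
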