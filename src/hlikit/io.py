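"""Readers and writers for fields, label maps, cell tables and results.

Formats:

* fields — multi-page TIFF, one page per channel, channel names and pixel
  size in the ImageDescription JSON;
* label maps — single-page 16-bit TIFF with kind/pixel_size metadata;
* cell tables — CSV (UTF-8, comma, header, no index) in a fixed column
  order, provenance (plate/well/field) as leading columns;
* reference profiles, ROC curves, screen summaries — versioned JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
import tifffile

from .morphometry import FEATURE_COLUMNS, CellTable
from .screen import ScreenResult
from .segmentation import LabelMap
from .synthgen import FieldImage, GroundTruthCell, PopulationSpec

log = logging.getLogger("hlikit")

PROVENANCE_COLUMNS = ["plate", "well", "field"]


def write_field(path, field: FieldImage) -> None:
    """Write a FieldImage as a multi-page TIFF with JSON metadata."""
    names = list(field.channels)
    stack = np.stack([field.channels[n] for n in names]).astype(np.float32)
    meta = {
        "channels": names,
        "pixel_size_um": field.pixel_size,
        "provenance": field.provenance,
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta, default=str))


def read_field(
    path,
    channel_map: dict[str, str] | None = None,
    pixel_size: float | None = None,
) -> FieldImage:
    """Read a multi-channel TIFF back into a FieldImage.

    ``channel_map`` maps canonical channel names to the names stored in the
    file (identity by default); a requested channel missing from the file is
    an error listing what is available.  A ``pixel_size`` argument overrides
    the file metadata, with a logged warning on conflict.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            meta = {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channels") or [f"channel_{i}" for i in range(stack.shape[0])]
    available = {name: stack[i] for i, name in enumerate(names)}

    channel_map = channel_map or {name: name for name in names}
    channels = {}
    for canonical, stored in channel_map.items():
        if stored not in available:
            raise KeyError(
                f"channel {stored!r} not found in {path}; available: {sorted(available)}"
            )
        channels[canonical] = available[stored]

    file_px = meta.get("pixel_size_um")
    if pixel_size is not None and file_px is not None and abs(pixel_size - file_px) > 1e-9:
        log.warning(
            "pixel_size %.4g from config overrides %.4g from %s metadata",
            pixel_size, file_px, path,
        )
    px = pixel_size if pixel_size is not None else (file_px or 1.0)
    return FieldImage(
        channels=channels, pixel_size=float(px),
        provenance={"path": str(path), **meta.get("provenance", {})},
    )


def write_label_map(path, labelmap: LabelMap) -> None:
    if labelmap.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    meta = {"kind": labelmap.kind, "pixel_size_um": labelmap.pixel_size}
    tifffile.imwrite(path, labelmap.labels.astype(np.uint16), description=json.dumps(meta))


def read_label_map(path, kind: str | None = None, pixel_size: float | None = None) -> LabelMap:
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray().astype(np.int32)
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    return LabelMap(
        labels=labels,
        kind=kind or meta.get("kind", "cells"),
        pixel_size=float(pixel_size or meta.get("pixel_size_um", 1.0)),
    )


def write_cell_table(path, table: CellTable) -> None:
    """CSV with fixed column order; provenance identifiers lead."""
    df = table.df.copy()
    for col in reversed(PROVENANCE_COLUMNS):
        df.insert(0, col, table.provenance.get(col, ""))
    ordered = PROVENANCE_COLUMNS + [c for c in FEATURE_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False)


def read_cell_table(path, pixel_size: float = 1.0) -> CellTable:
    df = pd.read_csv(path)
    prov = {}
    for col in PROVENANCE_COLUMNS:
        if col in df.columns:
            values = df[col].dropna().unique()
            if len(values) == 1:
                prov[col] = values[0]
            df = df.drop(columns=[col])
    for col in ("gate_nuclear", "gate_cell", "gate_albumin"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    return CellTable(df=df, provenance=prov, pixel_size=pixel_size)


def write_ground_truth(path, cells: list[GroundTruthCell]) -> None:
    """Companion CSV for a rendered field: one row per ground-truth cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "cell_id", "x_um", "y_um",
                "cell_a_um", "cell_b_um", "cell_theta",
                "nuc_a_um", "nuc_b_um", "nuc_theta",
                "true_class", "is_polyploid", "true_albumin_mfi", "is_gfp", "true_gfp_mfi",
            ]
        )
        for c in cells:
            writer.writerow(
                [
                    c.cell_id, c.centroid[0], c.centroid[1],
                    *c.cell_ellipse, *c.nuclear_ellipse,
                    c.true_class, int(c.is_polyploid), c.true_albumin_mfi,
                    int(c.is_gfp), c.true_gfp_mfi,
                ]
            )


def write_spec_sidecar(path, spec: PopulationSpec) -> None:
    """JSON sidecar recording the generating spec and seed."""
    def encode(obj):
        if isinstance(obj, PopulationSpec):
            d = asdict(obj)
            if d.get("mixture_components"):
                d["mixture_components"] = [
                    {"spec": encode(s), "weight": w} for s, w in obj.mixture_components
                ]
            return d
        return obj

    with open(path, "w") as fh:
        json.dump({"schema": "hlikit.population_spec/1", "spec": encode(spec)}, fh,
                  indent=2, default=str)


def write_screen_result(prefix, result: ScreenResult) -> None:
    """CSV per-condition summary + JSON overview for a scored plate."""
    prefix = str(prefix)
    per_cond = result.per_condition.copy()
    per_cond["hit"] = per_cond["condition"].isin(result.hits)
    for col in ("mean_hli", "sd_hli"):
        per_cond[col] = per_cond[col].map(lambda v: float(f"{v:.6g}"))
    per_cond.to_csv(prefix + "_conditions.csv", index=False)
    result.per_well.to_csv(prefix + "_wells.csv", index=False)
    summary = {
        "schema": "hlikit.screen_result/1",
        "plate_id": result.plate_id,
        "round": result.round,
        "control": result.control_summary,
        "hli_threshold": result.hli_threshold,
        "require_above_control": result.require_above_control,
        "hits": result.hits,
    }
    with open(prefix + "_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
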