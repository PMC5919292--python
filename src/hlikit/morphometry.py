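"""Per-cell morphometry and mean-fluorescence-intensity features.

Features feeding the Hepatocyte Likeness Index:

* ``nuclear_area``, ``cell_area`` — pixel counts × pixel_size² (µm²);
* ``nuclear_width``, ``cell_width`` — minor-axis length of the
  second-central-moment ellipse of the mask (µm);
* ``symmetry`` — minor/major axis ratio of the cell ellipse, in (0, 1];
* ``mfi_<channel>`` — mean intensity over the cell mask minus the channel
  background, clamped at 0 (GFP is measured over the nucleus mask because
  the HUVEC label is nuclear);
* ``is_polyploid`` — nuclear area above ``factor`` × the mononucleate modal
  area (area proxy for DNA content; adult hepatocytes are ~30% polyploid).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table

from .segmentation import LabelMap, estimate_background

if TYPE_CHECKING:  # pragma: no cover
    from .synthgen import FieldImage

__all__ = ["CellTable", "FEATURE_COLUMNS", "extract_features", "call_polyploidy", "modal_nuclear_area"]

#: canonical column order for serialized tables
FEATURE_COLUMNS = [
    "cell_id",
    "nuclear_area",
    "nuclear_width",
    "cell_area",
    "cell_width",
    "symmetry",
    "mfi_albumin",
    "mfi_gfp",
    "is_polyploid",
    "gate_nuclear",
    "gate_cell",
    "gate_albumin",
    "assigned_class",
]

MORPHOLOGY_FEATURES = ["nuclear_area", "nuclear_width", "cell_area", "cell_width", "symmetry"]


@dataclass
class CellTable:
    """Per-cell feature records for one field or well.

    ``df`` holds one row per cell with unique ``cell_id``; ``provenance``
    identifies plate/well/field and records processing notes.
    """

    df: pd.DataFrame
    provenance: dict = dc_field(default_factory=dict)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if "cell_id" in self.df.columns and self.df["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique within a CellTable")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy(), dict(self.provenance), self.pixel_size)

    def require(self, *columns: str) -> None:
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise KeyError(f"CellTable is missing required column(s): {missing}")


def concat_tables(tables: list[CellTable]) -> CellTable:
    """Stack tables from multiple fields of one well, renumbering cell_ids."""
    if not tables:
        raise ValueError("no tables to concatenate")
    frames = []
    offset = 0
    for t in tables:
        df = t.df.copy()
        df["cell_id"] = df["cell_id"] + offset
        offset = int(df["cell_id"].max()) if len(df) else offset
        frames.append(df)
    prov = dict(tables[0].provenance)
    prov["n_fields"] = len(tables)
    return CellTable(pd.concat(frames, ignore_index=True), prov, tables[0].pixel_size)


def _moment_features(labels: np.ndarray, pixel_size: float, prefix: str) -> pd.DataFrame:
    props = regionprops_table(
        labels, properties=("label", "area", "axis_major_length", "axis_minor_length")
    )
    df = pd.DataFrame(props).rename(columns={"label": "cell_id"})
    df[f"{prefix}_area"] = df.pop("area") * pixel_size**2
    major = df.pop("axis_major_length") * pixel_size
    minor = df.pop("axis_minor_length") * pixel_size
    df[f"{prefix}_width"] = minor
    df[f"{prefix}_major"] = major
    return df


def extract_features(
    field: "FieldImage",
    nuclei: LabelMap,
    cells: LabelMap | None,
    background_per_channel: dict[str, float] | None = None,
) -> CellTable:
    """Measure one record per cell from a field and its label maps.

    ``nuclei`` and ``cells`` must be in register: identical label sets with
    each nucleus contained in its cell (a cell without a nucleus is an
    error).  With ``cells=None`` a nuclear-only table is returned (used e.g.
    for ploidy surveys that do not need cell bodies).  Backgrounds default to
    the per-channel median outside all objects.
    """
    px = nuclei.pixel_size
    for name, ch in field.channels.items():
        if ch.shape != nuclei.labels.shape:
            raise ValueError(f"channel {name!r} shape {ch.shape} != label shape")

    nuc_df = _moment_features(nuclei.labels, px, "nuclear")

    if cells is None:
        df = nuc_df.drop(columns=["nuclear_major"])
        prov = {"mode": "nuclear_only"}
        return CellTable(df.reset_index(drop=True), prov, px)

    if cells.labels.shape != nuclei.labels.shape:
        raise ValueError("nuclei and cells label maps differ in shape")
    nuc_ids = set(nuclei.ids().tolist())
    cell_ids = set(cells.ids().tolist())
    if nuc_ids != cell_ids:
        missing = sorted(cell_ids - nuc_ids)[:5]
        extra = sorted(nuc_ids - cell_ids)[:5]
        raise ValueError(
            "nuclei and cells label maps are not in register "
            f"(cells without nucleus: {missing}, orphan nuclei: {extra}); "
            "run segmentation.filter_nuclei_to_cells first"
        )

    cell_df = _moment_features(cells.labels, px, "cell")
    df = nuc_df.merge(cell_df, on="cell_id", validate="one_to_one")
    major = df.pop("cell_major")
    df["symmetry"] = np.where(major > 0, df["cell_width"] / major, 1.0).clip(0.0, 1.0)
    df = df.drop(columns=["nuclear_major"])

    if background_per_channel is None:
        background_per_channel = {
            name: estimate_background(ch, cells) for name, ch in field.channels.items()
        }
    ids = np.sort(np.asarray(sorted(cell_ids), dtype=np.int64))
    for name, ch in field.channels.items():
        bg = background_per_channel.get(name, 0.0)
        if bg < 0:
            raise ValueError(f"background for channel {name!r} must be >= 0")
        mask_labels = nuclei.labels if name == "gfp" else cells.labels
        means = ndi.mean(np.asarray(ch, dtype=np.float64), labels=mask_labels, index=ids)
        df[f"mfi_{name}"] = np.maximum(np.asarray(means) - bg, 0.0)

    prov = dict(field.provenance)
    prov["background"] = {k: float(v) for k, v in background_per_channel.items()}
    order = ["cell_id", "nuclear_area", "nuclear_width", "cell_area", "cell_width", "symmetry"]
    order += [c for c in df.columns if c not in order]
    return CellTable(df[order].reset_index(drop=True), prov, px)


def modal_nuclear_area(nuclear_areas: np.ndarray) -> float:
    """Mode of the nuclear-area histogram (Freedman–Diaconis bins).

    With a polyploid subpopulation the histogram is bimodal; the global mode
    sits on the (majority) mononucleate component, which is what the ploidy
    threshold must be anchored to.
    """
    areas = np.asarray(nuclear_areas, dtype=float)
    areas = areas[np.isfinite(areas)]
    if areas.size == 0:
        raise ValueError("no nuclear areas to take a mode of")
    if np.ptp(areas) <= 1e-12:
        return float(areas[0])
    counts, edges = np.histogram(areas, bins="fd")
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def call_polyploidy(
    table: CellTable,
    reference_mode_area: float | None = None,
    factor: float = 1.5,
) -> CellTable:
    """Flag polyploid nuclei by area threshold.

    A nucleus is polyploid when ``nuclear_area > factor × reference_mode_area``.
    The reference defaults to the modal nuclear area of the table itself,
    which for a 1×/2× area mixture puts ``factor = 1.5`` midway between the
    modes.  Returns a new table with ``is_polyploid`` set.
    """
    if not factor > 1.0:
        raise ValueError("factor must be > 1")
    out = table.copy()
    if len(out) == 0:
        out.df["is_polyploid"] = pd.Series(dtype=bool)
        return out
    out.require("nuclear_area")
    if reference_mode_area is None:
        reference_mode_area = modal_nuclear_area(out.df["nuclear_area"].to_numpy())
    if not reference_mode_area > 0:
        raise ValueError("reference_mode_area must be > 0")
    out.df["is_polyploid"] = out.df["nuclear_area"].to_numpy() > factor * reference_mode_area
    out.provenance["polyploidy_mode_area"] = float(reference_mode_area)
    out.provenance["polyploidy_factor"] = float(factor)
    return out
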