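"""Synthetic fluorescence-field generator with per-cell ground truth.

Cell populations are modelled as non-overlapping ellipses (cell body) with a
concentric elliptical nucleus.  Five presets emulate the cell types used to
build and validate the Hepatocyte Likeness Index: freshly isolated adult
hepatocytes, fetal hepatocytes, iPSC-derived hepatocytes (i-Heps), dermal
fibroblasts and nuclear-GFP-labelled HUVECs.  Preset magnitudes are generator
conventions chosen to preserve the qualitative contrasts reported for these
populations (adult cells large and symmetric with ~30% polyploid nuclei and
high albumin; fetal cells smaller, less symmetric, <5% polyploid; i-Heps
adult-like in symmetry but with larger, more variable nuclei and weak,
variable albumin; fibroblasts elongated and albumin-negative).

Polyploid nuclei are drawn from a second Gaussian mode at exactly twice the
mononucleate modal area (binucleate/tetraploid model) with the mononucleate
standard deviation.

Every sampling step is driven by a single :class:`numpy.random.Generator`, so
identical (spec, seed) pairs give bit-identical cells, images and label maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

__all__ = [
    "Stat",
    "PopulationSpec",
    "GroundTruthCell",
    "FieldImage",
    "NoiseModel",
    "PRESETS",
    "PlacementError",
    "make_population_spec",
    "sample_cells",
    "sample_feature_table",
    "render_field",
    "simulate_field",
    "suggest_field_size",
]

DEFAULT_PIXEL_SIZE = 0.65  # µm per pixel, typical 10-20x high-content optics
DEFAULT_FIELD_SHAPE = (1024, 1024)


@dataclass(frozen=True)
class Stat:
    """Mean and standard deviation of one per-cell feature."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one synthetic cell population.

    Areas are in µm², intensities in arbitrary units (AU).  ``cell_aspect``
    and ``nuclear_aspect`` are minor/major axis ratios in (0, 1].
    """

    preset_name: str
    n_cells: int = 500
    cell_area: Stat = Stat(1600.0, 300.0)
    cell_aspect: Stat = Stat(0.85, 0.08)
    nuclear_area: Stat = Stat(110.0, 20.0)
    nuclear_aspect: Stat = Stat(0.85, 0.05)
    polyploid_fraction: float = 0.0
    albumin_mfi: Stat = Stat(2000.0, 300.0)
    gfp_positive: bool = False
    gfp_mfi: Stat = Stat(1500.0, 300.0)
    mixture_components: tuple[tuple["PopulationSpec", float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.polyploid_fraction <= 1.0:
            raise ValueError(
                f"polyploid_fraction must be in [0, 1], got {self.polyploid_fraction}"
            )
        for name in ("cell_aspect", "nuclear_aspect"):
            st = getattr(self, name)
            if st.mean > 1.0:
                raise ValueError(f"{name} mean must be <= 1 (minor/major ratio)")
        if self.mixture_components is not None:
            weights = [w for _, w in self.mixture_components]
            if not weights or any(w < 0 for w in weights):
                raise ValueError("mixture weights must be non-negative and non-empty")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {sum(weights)}")


@dataclass(frozen=True)
class GroundTruthCell:
    """True geometry and intensity of one generated cell.

    Ellipses are (semi_major, semi_minor, orientation) with axes in µm and the
    orientation in radians; centroid is (x, y) in µm with x along columns.
    The nucleus is concentric and co-oriented with the cell, so containment is
    guaranteed by axis ordering.
    """

    cell_id: int
    centroid: tuple[float, float]
    cell_ellipse: tuple[float, float, float]
    nuclear_ellipse: tuple[float, float, float]
    true_class: str
    is_polyploid: bool
    true_albumin_mfi: float
    is_gfp: bool
    true_gfp_mfi: float = 0.0


@dataclass
class NoiseModel:
    """Acquisition model for rendered channels.

    ``gaussian_frac`` scales the additive read-noise sigma as a fraction of
    the mean foreground intensity of each channel; ``poisson`` toggles shot
    noise.  ``background`` is a uniform offset present in every channel.
    """

    background: float = 50.0
    gaussian_frac: float = 0.05
    poisson: bool = False
    nuclear_stain_level: float = 1000.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.gaussian_frac < 0 or self.nuclear_stain_level <= 0:
            raise ValueError("noise model parameters must be non-negative")


@dataclass
class FieldImage:
    """Multi-channel 2D fluorescence field."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


# Preset magnitudes.  These encode the printed orderings between populations
# (adult > fetal in cell area and symmetry; i-Hep nuclei larger and more
# variable than adult; fibroblast albumin at background level).  Fibroblast
# cell and nuclear sizes intentionally match the adult preset so that, among
# the morphology features, only symmetry separates the two classes; the
# biological separation otherwise rides on albumin.
PRESETS: dict[str, dict] = {
    "adult_hep": dict(
        cell_area=Stat(1600.0, 300.0),
        cell_aspect=Stat(0.85, 0.08),
        nuclear_area=Stat(110.0, 20.0),
        nuclear_aspect=Stat(0.85, 0.05),
        polyploid_fraction=0.30,
        albumin_mfi=Stat(2000.0, 300.0),
        gfp_positive=False,
    ),
    "fetal_hep": dict(
        cell_area=Stat(900.0, 250.0),
        cell_aspect=Stat(0.65, 0.12),
        nuclear_area=Stat(80.0, 15.0),
        nuclear_aspect=Stat(0.85, 0.05),
        polyploid_fraction=0.03,
        albumin_mfi=Stat(1200.0, 300.0),
        gfp_positive=False,
    ),
    "ihep": dict(
        cell_area=Stat(3000.0, 900.0),
        cell_aspect=Stat(0.85, 0.08),
        nuclear_area=Stat(150.0, 45.0),
        nuclear_aspect=Stat(0.85, 0.05),
        polyploid_fraction=0.10,
        albumin_mfi=Stat(900.0, 500.0),
        gfp_positive=False,
    ),
    "fibroblast": dict(
        cell_area=Stat(1600.0, 350.0),
        cell_aspect=Stat(0.25, 0.08),
        nuclear_area=Stat(110.0, 20.0),
        nuclear_aspect=Stat(0.80, 0.05),
        polyploid_fraction=0.0,
        albumin_mfi=Stat(120.0, 60.0),
        gfp_positive=False,
    ),
    "huvec_gfp": dict(
        cell_area=Stat(800.0, 200.0),
        cell_aspect=Stat(0.50, 0.10),
        nuclear_area=Stat(90.0, 15.0),
        nuclear_aspect=Stat(0.85, 0.05),
        polyploid_fraction=0.0,
        albumin_mfi=Stat(150.0, 70.0),
        gfp_positive=True,
        gfp_mfi=Stat(1500.0, 300.0),
    ),
}

_STAT_FIELDS = frozenset(
    {"cell_area", "cell_aspect", "nuclear_area", "nuclear_aspect", "albumin_mfi", "gfp_mfi"}
)
_SCALAR_FIELDS = frozenset(
    {"n_cells", "polyploid_fraction", "gfp_positive", "seed", "mixture_components"}
)


def make_population_spec(preset_name: str, overrides: dict | None = None) -> PopulationSpec:
    """Build a :class:`PopulationSpec` from a named preset.

    ``overrides`` may replace any spec field; Stat-valued fields accept either
    a :class:`Stat` or a ``(mean, sd)`` pair.  The returned spec is validated
    against all invariants.
    """
    overrides = dict(overrides or {})
    if preset_name == "mixture":
        components = overrides.pop("mixture_components", None)
        if not components:
            raise ValueError("preset 'mixture' requires a 'mixture_components' override")
        components = tuple((spec, float(w)) for spec, w in components)
        base = dict(preset_name="mixture", mixture_components=components)
    elif preset_name in PRESETS:
        base = dict(preset_name=preset_name, **PRESETS[preset_name])
    else:
        raise ValueError(
            f"unknown preset {preset_name!r}; valid presets: "
            f"{sorted(PRESETS) + ['mixture']}"
        )

    for key, value in overrides.items():
        if key in _STAT_FIELDS:
            base[key] = value if isinstance(value, Stat) else Stat(*value)
        elif key in _SCALAR_FIELDS:
            base[key] = value
        else:
            raise ValueError(f"unknown PopulationSpec field {key!r}")
    try:
        return PopulationSpec(**base)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid override for preset {preset_name!r}: {exc}") from exc


def _axes_from_area(area: np.ndarray, aspect: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Semi-axes (a, b) of an ellipse with given area and minor/major ratio."""
    a = np.sqrt(area / (np.pi * aspect))
    return a, a * aspect


def _draw_phenotypes(spec: PopulationSpec, n: int, rng: np.random.Generator) -> dict:
    """Draw per-cell feature arrays for ``n`` cells of one population.

    Mixture specs delegate to their components after a weighted multinomial
    assignment; ``true_class`` records the component preset name.
    """
    if spec.mixture_components is not None:
        specs = [s for s, _ in spec.mixture_components]
        weights = np.array([w for _, w in spec.mixture_components])
        assign = rng.choice(len(specs), size=n, p=weights / weights.sum())
        parts = [_draw_phenotypes(specs[k], int((assign == k).sum()), rng) for k in range(len(specs))]
        out: dict = {}
        for key in parts[0]:
            chunks = [p[key] for p in parts]
            merged = np.empty(n, dtype=chunks[0].dtype)
            for k, chunk in enumerate(chunks):
                merged[assign == k] = chunk
            out[key] = merged
        return out

    def normal(st: Stat, lo: float, hi: float | None = None) -> np.ndarray:
        x = rng.normal(st.mean, st.sd, size=n)
        return np.clip(x, lo, hi)

    is_poly = rng.random(n) < spec.polyploid_fraction
    nuc_area = normal(spec.nuclear_area, 5.0)
    # polyploid mode: 2x the mononucleate mean, mononucleate SD
    nuc_area[is_poly] = np.clip(
        rng.normal(2.0 * spec.nuclear_area.mean, spec.nuclear_area.sd, size=int(is_poly.sum())),
        5.0,
        None,
    )
    return dict(
        cell_area=normal(spec.cell_area, 25.0),
        cell_aspect=normal(spec.cell_aspect, 0.05, 1.0),
        nuclear_area=nuc_area,
        nuclear_aspect=normal(spec.nuclear_aspect, 0.05, 1.0),
        is_polyploid=is_poly,
        albumin_mfi=normal(spec.albumin_mfi, 0.0),
        gfp_mfi=(
            normal(spec.gfp_mfi, 0.0) if spec.gfp_positive else np.zeros(n)
        ),
        is_gfp=np.full(n, spec.gfp_positive),
        true_class=np.full(n, spec.preset_name, dtype=object),
    )


def suggest_field_size(spec: PopulationSpec, packing: float = 0.22) -> tuple[float, float]:
    """Square field side (µm) at which ``spec.n_cells`` pack at ``packing``."""
    mean_area = spec.cell_area.mean
    if spec.mixture_components is not None:
        mean_area = sum(s.cell_area.mean * w for s, w in spec.mixture_components)
    side = math.sqrt(max(spec.n_cells, 1) * mean_area / packing)
    side = max(side, 120.0)
    return (side, side)


def _ellipse_patch(
    cx: float, cy: float, a: float, b: float, theta: float, grid: float, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Boolean raster of an ellipse over its bounding box.

    Coordinates are in µm; ``grid`` is the raster resolution (µm per raster
    pixel) and ``shape`` the raster shape (rows, cols).  Returns row/col
    slices into the raster plus the mask.
    """
    r = max(a, b)
    r0 = max(int((cy - r) / grid) - 1, 0)
    r1 = min(int((cy + r) / grid) + 2, shape[0])
    c0 = max(int((cx - r) / grid) - 1, 0)
    c1 = min(int((cx + r) / grid) + 2, shape[1])
    rows = (np.arange(r0, r1) + 0.5) * grid - cy
    cols = (np.arange(c0, c1) + 0.5) * grid - cx
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx * ct + yy * st) / a
    v = (-xx * st + yy * ct) / b
    return slice(r0, r1), slice(c0, c1), (u * u + v * v) <= 1.0


def sample_cells(
    spec: PopulationSpec,
    field_size_um: tuple[float, float] | None = None,
    margin_um: float = 2.0,
    max_retries: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[GroundTruthCell]:
    """Sample ``spec.n_cells`` ground-truth cells placed without overlap.

    Placement is dart-throwing against an occupancy raster (1 µm grid) with
    each ellipse dilated by ``margin_um``, so rendered cells stay disjoint at
    any practical pixel size.  Raises :class:`PlacementError` when a cell
    cannot be placed within ``max_retries`` attempts.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_cells
    if n == 0:
        return []
    if field_size_um is None:
        field_size_um = suggest_field_size(spec)
    width, height = float(field_size_um[0]), float(field_size_um[1])

    pheno = _draw_phenotypes(spec, n, rng)
    cell_a, cell_b = _axes_from_area(pheno["cell_area"], pheno["cell_aspect"])
    nuc_a, nuc_b = _axes_from_area(pheno["nuclear_area"], pheno["nuclear_aspect"])
    # concentric, co-oriented nucleus: clamping axes below the cell's
    # guarantees geometric containment
    nuc_a = np.minimum(nuc_a, 0.95 * cell_a)
    nuc_b = np.minimum(nuc_b, 0.95 * cell_b)
    theta = rng.uniform(0.0, np.pi, size=n)

    grid = 1.0
    occ_shape = (int(math.ceil(height / grid)), int(math.ceil(width / grid)))
    occupied = np.zeros(occ_shape, dtype=bool)
    cells: list[GroundTruthCell] = []
    for i in range(n):
        a_eff = cell_a[i] + margin_um
        b_eff = cell_b[i] + margin_um
        r = a_eff
        if 2 * r >= min(width, height):
            raise PlacementError(
                f"cell {i + 1} (semi-major {cell_a[i]:.1f} µm) cannot fit in a "
                f"{width:.0f}x{height:.0f} µm field; enlarge the field"
            )
        placed = False
        for _ in range(max_retries):
            cx = rng.uniform(r, width - r)
            cy = rng.uniform(r, height - r)
            rs, cs, mask = _ellipse_patch(cx, cy, a_eff, b_eff, theta[i], grid, occ_shape)
            if not (occupied[rs, cs] & mask).any():
                occupied[rs, cs] |= mask
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} after {max_retries} tries; "
                "use a larger field or fewer cells"
            )
        cells.append(
            GroundTruthCell(
                cell_id=i + 1,
                centroid=(cx, cy),
                cell_ellipse=(float(cell_a[i]), float(cell_b[i]), float(theta[i])),
                nuclear_ellipse=(float(nuc_a[i]), float(nuc_b[i]), float(theta[i])),
                true_class=str(pheno["true_class"][i]),
                is_polyploid=bool(pheno["is_polyploid"][i]),
                true_albumin_mfi=float(pheno["albumin_mfi"][i]),
                is_gfp=bool(pheno["is_gfp"][i]),
                true_gfp_mfi=float(pheno["gfp_mfi"][i]),
            )
        )
    return cells


def sample_feature_table(
    spec: PopulationSpec,
    provenance: dict | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw a per-cell feature table directly from the population model.

    This is the idealized measurement: the features the imaging pipeline
    recovers on a noise-free rendering of the same cells.  It is the fast
    path for plate-scale screen simulations where per-pixel rendering adds
    nothing.  Returns a :class:`hlikit.morphometry.CellTable`.
    """
    from .morphometry import CellTable  # deferred: morphometry is downstream

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pheno = _draw_phenotypes(spec, spec.n_cells, rng)
    cell_a, cell_b = _axes_from_area(pheno["cell_area"], pheno["cell_aspect"])
    nuc_a, nuc_b = _axes_from_area(pheno["nuclear_area"], pheno["nuclear_aspect"])

    import pandas as pd

    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, spec.n_cells + 1),
            "nuclear_area": pheno["nuclear_area"],
            "nuclear_width": 2.0 * nuc_b,
            "cell_area": pheno["cell_area"],
            "cell_width": 2.0 * cell_b,
            "symmetry": pheno["cell_aspect"],
            "mfi_albumin": pheno["albumin_mfi"],
            "mfi_gfp": pheno["gfp_mfi"],
            "true_class": pheno["true_class"],
            "is_polyploid_true": pheno["is_polyploid"],
        }
    )
    prov = dict(provenance or {})
    prov.setdefault("source", "sample_feature_table")
    prov.setdefault("preset", spec.preset_name)
    return CellTable(df=df, provenance=prov, pixel_size=DEFAULT_PIXEL_SIZE)


def render_field(
    cells: Sequence[GroundTruthCell],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] | None = None,
    noise: NoiseModel | None = None,
    include_gfp: bool | None = None,
    rng: np.random.Generator | None = None,
    provenance: dict | None = None,
):
    """Rasterize ground-truth cells into a multi-channel field + label maps.

    Returns ``(FieldImage, nuclei_labels, cell_labels)`` where the label maps
    are the exact rasterized ground truth (values = cell_id).  The albumin
    channel paints each whole-cell ellipse at its true MFI, the nuclear
    channel paints nuclei at the stain level, and the optional GFP channel
    paints the nuclei of GFP-positive cells.  Background and noise follow
    ``noise``; pixels outside all cells carry background + noise only.
    """
    from .segmentation import LabelMap

    noise = noise if noise is not None else NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    if shape is None:
        if not cells:
            shape = DEFAULT_FIELD_SHAPE
        else:
            extent = max(c.centroid[0] + c.cell_ellipse[0] for c in cells)
            extent_y = max(c.centroid[1] + c.cell_ellipse[0] for c in cells)
            shape = (
                int(math.ceil((extent_y + 2.0) / pixel_size)),
                int(math.ceil((extent + 2.0) / pixel_size)),
            )
    h, w = shape
    for c in cells:
        cx, cy = c.centroid
        r = c.cell_ellipse[0]
        if cx - r < -1e-6 or cy - r < -1e-6 or cx + r > w * pixel_size + 1e-6 or cy + r > h * pixel_size + 1e-6:
            raise ValueError(
                f"cell {c.cell_id} (extent {r:.1f} µm at {c.centroid}) does not fit "
                f"inside a {h}x{w} px field at {pixel_size} µm/px"
            )

    if include_gfp is None:
        include_gfp = any(c.is_gfp for c in cells)

    nuclear = np.full(shape, noise.background, dtype=np.float64)
    albumin = np.full(shape, noise.background, dtype=np.float64)
    gfp = np.full(shape, noise.background, dtype=np.float64) if include_gfp else None
    nuclei_lab = np.zeros(shape, dtype=np.int32)
    cells_lab = np.zeros(shape, dtype=np.int32)

    for c in cells:
        cx, cy = c.centroid
        a, b, th = c.cell_ellipse
        rs, cs, mask = _ellipse_patch(cx, cy, a, b, th, pixel_size, shape)
        cells_lab[rs, cs][mask] = c.cell_id
        albumin[rs, cs][mask] = noise.background + c.true_albumin_mfi
        na, nb, nth = c.nuclear_ellipse
        rs, cs, mask = _ellipse_patch(cx, cy, na, nb, nth, pixel_size, shape)
        nuclei_lab[rs, cs][mask] = c.cell_id
        nuclear[rs, cs][mask] = noise.background + noise.nuclear_stain_level
        if gfp is not None and c.is_gfp:
            gfp[rs, cs][mask] = noise.background + c.true_gfp_mfi

    channels = {"nuclear_stain": nuclear, "albumin": albumin}
    if gfp is not None:
        channels["gfp"] = gfp

    fg = cells_lab > 0
    for name, img in channels.items():
        out = img
        if noise.poisson:
            out = rng.poisson(np.maximum(out, 0.0)).astype(np.float64)
        if noise.gaussian_frac > 0:
            sigma = noise.gaussian_frac * (img[fg].mean() if fg.any() else noise.background)
            out = out + rng.normal(0.0, sigma, size=img.shape)
        channels[name] = np.maximum(out, 0.0).astype(np.float32)

    prov = dict(provenance or {})
    prov.setdefault("n_cells", len(cells))
    field = FieldImage(channels=channels, pixel_size=pixel_size, provenance=prov)
    nuclei_map = LabelMap(labels=nuclei_lab, kind="nuclei", pixel_size=pixel_size)
    cells_map = LabelMap(labels=cells_lab, kind="cells", pixel_size=pixel_size)
    return field, nuclei_map, cells_map


def simulate_field(
    spec: PopulationSpec,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Sample one population and render it; convenience for pipelines.

    The field size is chosen automatically from the spec so the requested
    cell count packs comfortably.  Returns
    ``(cells, FieldImage, nuclei_labels, cell_labels)``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    size = suggest_field_size(spec)
    cells = sample_cells(spec, field_size_um=size, rng=rng)
    shape = (
        int(math.ceil(size[1] / pixel_size)),
        int(math.ceil(size[0] / pixel_size)),
    )
    field, nuclei, cellmap = render_field(
        cells,
        pixel_size=pixel_size,
        shape=shape,
        noise=noise,
        rng=rng,
        provenance={"preset": spec.preset_name, "seed": spec.seed},
    )
    return cells, field, nuclei, cellmap
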