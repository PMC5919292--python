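"""End-to-end orchestration: synth → segment → features → calibrate → score.

All randomness derives from the single run seed through
:class:`numpy.random.SeedSequence`, so a rerun with an identical config
reproduces identical tables and scores.  Every output carries provenance
(config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import ReferenceProfile, apply_gates, compute_hli, exclude_gfp, fit_reference_profile
from .morphometry import CellTable, concat_tables, extract_features
from .segmentation import filter_nuclei_to_cells, relabel_pair, segment_cells, segment_nuclei
from .synthgen import (
    DEFAULT_PIXEL_SIZE,
    NoiseModel,
    PopulationSpec,
    make_population_spec,
    simulate_field,
)

log = logging.getLogger("hlikit")

STAGES = ["synth", "segment", "features", "calibrate", "score"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def process_field(
    field,
    min_nuclear_area_um2: float = 20.0,
    max_nuclear_area_um2: float = 600.0,
    background_per_channel: dict[str, float] | None = None,
    nuclear_only: bool = False,
) -> CellTable:
    """Segment one field and measure its per-cell features.

    Runs nuclear segmentation on the ``nuclear_stain`` channel, grows cells
    from the nuclei over the ``albumin`` channel (which doubles as the
    cytoplasm stain in hepatocyte cultures), reconciles the two label maps
    and extracts the feature table.
    """
    nuclei = segment_nuclei(
        field.channel("nuclear_stain"),
        field.pixel_size,
        min_nuclear_area_um2=min_nuclear_area_um2,
        max_nuclear_area_um2=max_nuclear_area_um2,
    )
    if nuclear_only:
        return extract_features(field, nuclei, None)
    cells = segment_cells(field.channel("albumin"), nuclei)
    nuclei = filter_nuclei_to_cells(nuclei, cells)
    nuclei, cells = relabel_pair(nuclei, cells)
    return extract_features(field, nuclei, cells, background_per_channel)


def imaged_population_table(
    spec: PopulationSpec,
    rng: np.random.Generator,
    cells_per_field: int = 250,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: NoiseModel | None = None,
    nuclear_only: bool = False,
    provenance: dict | None = None,
) -> CellTable:
    """Render a population across as many fields as needed and measure it.

    The requested ``spec.n_cells`` are split into fields of at most
    ``cells_per_field`` cells so each field keeps a realistic packing
    density; the measured tables are concatenated.
    """
    import dataclasses

    n = spec.n_cells
    tables = []
    field_idx = 0
    while n > 0:
        k = min(n, cells_per_field)
        sub = dataclasses.replace(spec, n_cells=k)
        _, field, nuclei, cellmap = simulate_field(sub, pixel_size=pixel_size, noise=noise, rng=rng)
        table = process_field(field, nuclear_only=nuclear_only)
        table.provenance["field"] = field_idx
        tables.append(table)
        n -= k
        field_idx += 1
    out = concat_tables(tables)
    out.provenance.update(provenance or {})
    out.provenance["preset"] = spec.preset_name
    return out


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`."""

    seed: int = 0
    pixel_size: float = DEFAULT_PIXEL_SIZE
    out_dir: str = "hli_out"
    stages: list[str] = dc_field(default_factory=lambda: list(STAGES))
    noise: dict = dc_field(default_factory=dict)
    reference: dict = dc_field(default_factory=lambda: {"preset": "adult_hep", "n_cells": 500})
    negative: dict = dc_field(default_factory=lambda: {"preset": "fibroblast", "n_cells": 500})
    tests: list[dict] = dc_field(default_factory=list)
    cells_per_field: int = 250
    save_images: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid stages: {STAGES}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def digest(self) -> str:
        """Hash of the scientific configuration (paths and log level excluded)."""
        import dataclasses

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _spec_from_entry(entry: dict, seed: int) -> PopulationSpec:
    overrides = dict(entry.get("overrides", {}))
    overrides["n_cells"] = entry.get("n_cells", 500)
    overrides["seed"] = seed
    return make_population_spec(entry["preset"], overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages end to end on synthetic populations.

    Generates the reference, negative and test populations, images and
    measures them, calibrates the reference profile and scores every test
    population.  Writes cell tables, the profile and an ``hli.json`` summary
    into ``config.out_dir``; returns the summary dict.
    """
    from . import io as hio

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "hlikit_version": __version__,
    }
    summary: dict = {"provenance": provenance, "populations": {}}
    noise = NoiseModel(**config.noise) if config.noise else NoiseModel()
    seeds = np.random.SeedSequence(config.seed).spawn(3 + len(config.tests))

    import contextlib

    @contextlib.contextmanager
    def stage(name: str):
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    try:
        want = set(config.stages)
        do_measure = bool(want & {"segment", "features", "calibrate", "score"})

        populations: dict[str, CellTable] = {}
        entries = [("reference", config.reference), ("negative", config.negative)]
        entries += [(t.get("name", t["preset"]), t) for t in config.tests]
        for (name, entry), seed_seq in zip(entries, seeds):
            rng = np.random.default_rng(seed_seq)
            spec = _spec_from_entry(entry, int(seed_seq.generate_state(1)[0] % 2**31))
            log.info("population %s: preset=%s n=%d", name, spec.preset_name, spec.n_cells)
            if not do_measure and "synth" in want:
                with stage("synth"):
                    from .synthgen import sample_cells, render_field, suggest_field_size
                    import math

                    size = suggest_field_size(spec)
                    cells = sample_cells(spec, field_size_um=size, rng=rng)
                    shape = (
                        int(math.ceil(size[1] / config.pixel_size)),
                        int(math.ceil(size[0] / config.pixel_size)),
                    )
                    field, nuclei, cellmap = render_field(
                        cells, pixel_size=config.pixel_size, shape=shape, noise=noise, rng=rng
                    )
                    hio.write_field(out_dir / f"{name}_field.tif", field)
                    hio.write_ground_truth(out_dir / f"{name}_truth.csv", cells)
                    hio.write_spec_sidecar(out_dir / f"{name}_spec.json", spec)
                continue
            with stage("features"):
                table = imaged_population_table(
                    spec,
                    rng,
                    cells_per_field=config.cells_per_field,
                    pixel_size=config.pixel_size,
                    noise=noise,
                    provenance={**provenance, "well": name},
                )
            populations[name] = table
            summary["populations"][name] = {"preset": spec.preset_name, "n_cells": len(table)}

        profile: ReferenceProfile | None = None
        if "calibrate" in want and populations:
            with stage("calibrate"):
                profile = fit_reference_profile(populations["reference"], populations["negative"])
                profile.to_json(out_dir / "profile.json")
                summary["albumin_cutoff"] = profile.albumin_cutoff
                summary["albumin_auc"] = profile.calibration_meta["albumin_auc"]
                if "warning" in profile.calibration_meta:
                    log.warning(profile.calibration_meta["warning"])

        if "score" in want:
            if profile is None:
                raise PipelineError("score", "stage 'score' requires stage 'calibrate'")
            summary["hli"] = {}
            for name, entry in entries:
                with stage("score"):
                    table = populations[name]
                    if entry.get("exclude_gfp"):
                        table = exclude_gfp(table, float(entry["exclude_gfp"]))
                    gated = apply_gates(table, profile)
                    hio.write_cell_table(out_dir / f"{name}_cells.csv", gated)
                    res = compute_hli(gated)
                summary["hli"][name] = {
                    "hli": res.hli,
                    "n_total": res.n_total,
                    "n_positive": res.n_positive,
                    "attrition": res.per_gate_attrition,
                }
                log.info("HLI[%s] = %.4f (n=%d)", name, res.hli, res.n_total)
        elif "features" in want or "segment" in want:
            for name, table in populations.items():
                hio.write_cell_table(out_dir / f"{name}_cells.csv", table)
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(out_dir / "hli.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
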