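"""Plate-level niche-factor screen analysis.

Each well of a coated plate is scored by its HLI; replicate wells are
aggregated per condition (mean ± SD); a condition is a hit when its mean HLI
exceeds both the absolute threshold (0.2 by default) and the mean of the
collagen-1 control condition.  First-round hits are confirmed only if they
satisfy the same rule on every second-round plate (additional iPSC lines).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .classifier import compute_hli
from .morphometry import CellTable

__all__ = ["PlateMap", "ScreenResult", "score_plate", "call_hits", "confirm_hits"]

DEFAULT_HLI_THRESHOLD = 0.2
DEFAULT_CONTROL = "collagen-1"
LOW_COUNT_CELLS = 20


@dataclass(frozen=True)
class PlateMap:
    """Assignment of plate wells to coating conditions."""

    plate_id: str
    wells: dict[str, str]  # well_id (e.g. "B03") -> condition name
    control_condition: str = DEFAULT_CONTROL

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("plate map has no wells")
        if self.control_condition not in self.wells.values():
            raise ValueError(
                f"control condition {self.control_condition!r} is not present in any well"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.wells.values()))

    @classmethod
    def from_json(cls, path) -> "PlateMap":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            plate_id=payload.get("plate_id", "plate"),
            wells=dict(payload["wells"]),
            control_condition=payload.get("control_condition", DEFAULT_CONTROL),
        )

    @classmethod
    def from_csv(cls, path, plate_id: str = "plate",
                 control_condition: str = DEFAULT_CONTROL) -> "PlateMap":
        wells: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                wells[row["well"]] = row["condition"]
        return cls(plate_id=plate_id, wells=wells, control_condition=control_condition)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "plate_id": self.plate_id,
                    "control_condition": self.control_condition,
                    "wells": self.wells,
                },
                fh,
                indent=2,
            )


@dataclass
class ScreenResult:
    """Scored plate: per-well and per-condition HLI plus hit calls."""

    plate_id: str
    per_well: pd.DataFrame  # well_id, condition, n_total, n_positive, hli, low_count
    per_condition: pd.DataFrame  # condition, mean_hli, sd_hli, n_wells
    control_condition: str
    hits: list[str] = dc_field(default_factory=list)
    round: int = 1
    hli_threshold: float = DEFAULT_HLI_THRESHOLD
    require_above_control: bool = True

    @property
    def control_summary(self) -> dict:
        row = self.per_condition.loc[
            self.per_condition["condition"] == self.control_condition
        ]
        if row.empty:
            raise ValueError(
                f"control condition {self.control_condition!r} has no scored wells"
            )
        rec = row.iloc[0]
        return {
            "condition": self.control_condition,
            "mean_hli": float(rec["mean_hli"]),
            "sd_hli": float(rec["sd_hli"]),
            "n_wells": int(rec["n_wells"]),
        }

    def condition_mean(self, condition: str) -> float:
        row = self.per_condition.loc[self.per_condition["condition"] == condition]
        if row.empty:
            raise KeyError(f"condition {condition!r} not present on plate {self.plate_id!r}")
        return float(row.iloc[0]["mean_hli"])


def score_plate(
    tables: dict[str, CellTable],
    plate_map: PlateMap,
    min_cells: int = LOW_COUNT_CELLS,
) -> ScreenResult:
    """Score every well of a plate from gated cell tables.

    Wells with fewer than ``min_cells`` cells are flagged low-count and
    excluded from the per-condition means.  Every mapped well must have a
    table and vice versa.
    """
    if not tables:
        raise ValueError("no well tables provided")
    unknown = sorted(set(tables) - set(plate_map.wells))
    if unknown:
        raise ValueError(f"wells not present in plate map: {unknown}")
    missing = sorted(set(plate_map.wells) - set(tables))
    if missing:
        raise ValueError(f"mapped wells without a cell table: {missing}")

    rows = []
    for well_id in sorted(plate_map.wells):
        table = tables[well_id]
        condition = plate_map.wells[well_id]
        if len(table) == 0:
            rows.append((well_id, condition, 0, 0, np.nan, True))
            continue
        res = compute_hli(table)
        rows.append(
            (well_id, condition, res.n_total, res.n_positive, res.hli, res.n_total < min_cells)
        )
    per_well = pd.DataFrame(
        rows, columns=["well_id", "condition", "n_total", "n_positive", "hli", "low_count"]
    )

    usable = per_well.loc[~per_well["low_count"]]
    per_condition = (
        usable.groupby("condition", sort=True)["hli"]
        .agg(mean_hli="mean", sd_hli=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
             n_wells="count")
        .reset_index()
    )
    return ScreenResult(
        plate_id=plate_map.plate_id,
        per_well=per_well,
        per_condition=per_condition,
        control_condition=plate_map.control_condition,
    )


def _is_hit(
    result: ScreenResult,
    condition: str,
    hli_threshold: float,
    require_above_control: bool,
) -> bool:
    if condition == result.control_condition:
        return False
    mean = result.condition_mean(condition)
    if not mean > hli_threshold:  # strict: exactly 0.2 is not a hit
        return False
    if require_above_control and not mean > result.control_summary["mean_hli"]:
        return False
    return True


def call_hits(
    result: ScreenResult,
    hli_threshold: float = DEFAULT_HLI_THRESHOLD,
    require_above_control: bool = True,
) -> ScreenResult:
    """Flag hit conditions on a scored plate.

    A condition is a hit iff its per-condition mean HLI is strictly above
    ``hli_threshold`` AND (by default) strictly above the control mean; the
    control condition itself is never a hit.  Set
    ``require_above_control=False`` for the pure absolute-threshold rule.
    """
    if not 0.0 < hli_threshold < 1.0:
        raise ValueError("hli_threshold must be in (0, 1)")
    result.control_summary  # raises if control wells are missing
    hits = [
        c
        for c in result.per_condition["condition"]
        if _is_hit(result, c, hli_threshold, require_above_control)
    ]
    return replace(
        result,
        hits=sorted(hits),
        hli_threshold=hli_threshold,
        require_above_control=require_above_control,
    )


def confirm_hits(round1: ScreenResult, round2_results: list[ScreenResult]) -> list[str]:
    """Second-round confirmation of first-round hits.

    A round-1 hit is confirmed iff it satisfies the (round-1) hit rule on
    every round-2 plate.  Every round-1 hit must be present on every round-2
    plate; a missing condition is an error naming it.
    """
    if not round2_results:
        raise ValueError("no round-2 results provided")
    confirmed = []
    for condition in round1.hits:
        for r2 in round2_results:
            if condition not in set(r2.per_condition["condition"]):
                raise ValueError(
                    f"round-1 hit {condition!r} is missing from round-2 plate "
                    f"{r2.plate_id!r}"
                )
        if all(
            _is_hit(r2, condition, round1.hli_threshold, round1.require_above_control)
            for r2 in round2_results
        ):
            confirmed.append(condition)
    return confirmed
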