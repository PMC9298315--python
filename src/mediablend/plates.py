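"""Plate layout, worklist generation and deck aggregation.

Produces the three artefacts a liquid-handler run needs: a design sheet
(which medium goes in which well), a transfer worklist (ordered pipetting
instructions, grouped by source stock to minimise source changes, water
last), and a deck plan (how much of each stock to provide, including dead
volume and a safety margin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blending import MediumSpec, TransferPlan, WATER
from .errors import CapacityExceeded, MissingPlan
from .registry import StockRegistry, _fmt_number

PLATE_FORMATS = {24: ("ABCD", 6), 96: ("ABCDEFGH", 12)}


@dataclass(frozen=True)
class WellAssignment:
    plate_id: int
    well: str
    medium_name: str
    replicate_index: int


@dataclass(frozen=True)
class TransferRecord:
    step: int
    source: str
    dest_plate: int
    dest_well: str
    volume_ul: float


@dataclass
class DeckPlan:
    """Per-stock volume requirements: (stock, slot, required volume in ul)."""

    entries: list[tuple[str, str, float]]
    water_volume_ul: float


def well_sequence(plate_format: int) -> list[str]:
    """Row-major well labels for a plate format (A1, A2, ..., D6 for 24)."""
    try:
        rows, ncols = PLATE_FORMATS[plate_format]
    except KeyError:
        raise ValueError(f"unsupported plate format {plate_format}; use {sorted(PLATE_FORMATS)}")
    return [f"{r}{c}" for r in rows for c in range(1, ncols + 1)]


def plan_plates(
    media: list[tuple[MediumSpec, int]],
    plate_format: int = 24,
    randomize: bool = False,
    seed: int = 0,
    plate_budget: int | None = None,
) -> list[WellAssignment]:
    """Assign media (with replicate counts) to wells across plates.

    Default fill order is row-major within plates numbered from 1; with
    ``randomize`` the well order is a seeded permutation of the slots, so
    the same seed reproduces the same layout exactly.
    """
    wells = well_sequence(plate_format)
    capacity = len(wells)
    n_total = sum(n for _, n in media)
    n_plates = max(1, math.ceil(n_total / capacity))
    if plate_budget is not None and n_plates > plate_budget:
        raise CapacityExceeded(
            f"{n_total} wells need {n_plates} plates of {capacity}, budget is {plate_budget}"
        )
    slots = [(p, w) for p in range(1, n_plates + 1) for w in wells]
    if randomize:
        order = np.random.default_rng(seed).permutation(len(slots))
        slots = [slots[i] for i in order]
    assignments = []
    i = 0
    for medium, n_reps in media:
        for rep in range(1, n_reps + 1):
            plate, well = slots[i]
            assignments.append(WellAssignment(plate, well, medium.name, rep))
            i += 1
    return assignments


def build_worklist(
    assignments: list[WellAssignment],
    plans: dict[str, TransferPlan],
) -> list[TransferRecord]:
    """Order all transfers grouped by source stock, water last.

    Grouping by source lets the handler serve every destination well from
    one stock before moving to the next, minimising source changes; within
    a source, wells are visited in assignment order.
    """
    for a in assignments:
        if a.medium_name not in plans:
            raise MissingPlan(f"no transfer plan for medium {a.medium_name!r}")
    # source order: first appearance across plans in assignment order, water last
    sources: list[str] = []
    for a in assignments:
        for src, _ in plans[a.medium_name].steps:
            if src != WATER and src not in sources:
                sources.append(src)
    sources.append(WATER)

    records = []
    step = 1
    for src in sources:
        for a in assignments:
            for s, vol in plans[a.medium_name].steps:
                if s == src:
                    records.append(TransferRecord(step, src, a.plate_id, a.well, vol))
                    step += 1
    return records


def compute_deck(
    worklist: list[TransferRecord],
    registry: StockRegistry,
    safety_margin: float = 0.10,
) -> DeckPlan:
    """Aggregate per-stock demand: (1 + margin) * total + dead volume.

    Slots are assigned in demand-descending order (ties by name) so the
    most used stocks sit in the most accessible positions.
    """
    demand: dict[str, float] = {}
    for rec in worklist:
        demand[rec.source] = demand.get(rec.source, 0.0) + rec.volume_ul
    water = demand.pop(WATER, 0.0)
    entries = []
    for name, total in demand.items():
        dead = registry.get_stock(name).dead_volume_ul if registry.has_stock(name) else 0.0
        entries.append((name, (1 + safety_margin) * total + dead))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return DeckPlan(
        entries=[(name, f"S{i + 1}", req) for i, (name, req) in enumerate(entries)],
        water_volume_ul=(1 + safety_margin) * water,
    )


# --- CSV I/O ------------------------------------------------------------


def write_design_csv(
    assignments: list[WellAssignment],
    media: dict[str, MediumSpec],
    path,
) -> None:
    """Design sheet: one row per well/item pair with target concentrations."""
    rows = []
    for a in assignments:
        medium = media[a.medium_name]
        for item, (conc, unit) in medium.targets.items():
            rows.append(
                {
                    "plate_id": a.plate_id,
                    "well": a.well,
                    "medium_name": a.medium_name,
                    "replicate": a.replicate_index,
                    "item": item,
                    "target_concentration": _fmt_number(conc),
                    "unit": unit,
                }
            )
    pd.DataFrame(
        rows,
        columns=["plate_id", "well", "medium_name", "replicate", "item",
                 "target_concentration", "unit"],
    ).to_csv(path, index=False)


def write_worklist_csv(worklist: list[TransferRecord], path) -> None:
    """Worklist with volumes printed to one decimal (bit-exact re-read)."""
    df = pd.DataFrame(
        [
            {
                "step": r.step,
                "source": r.source,
                "dest_plate": r.dest_plate,
                "dest_well": r.dest_well,
                "volume_ul": f"{r.volume_ul:.1f}",
            }
            for r in worklist
        ],
        columns=["step", "source", "dest_plate", "dest_well", "volume_ul"],
    )
    df.to_csv(path, index=False)


def read_worklist_csv(path) -> list[TransferRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        TransferRecord(
            step=int(r["step"]),
            source=r["source"],
            dest_plate=int(r["dest_plate"]),
            dest_well=r["dest_well"],
            volume_ul=float(r["volume_ul"]),
        )
        for _, r in df.iterrows()
    ]


def write_deck_csv(deck: DeckPlan, path) -> None:
    rows = [
        {"stock_name": name, "slot": slot, "required_volume_ul": f"{req:.1f}"}
        for name, slot, req in deck.entries
    ]
    rows.append(
        {"stock_name": WATER, "slot": "", "required_volume_ul": f"{deck.water_volume_ul:.1f}"}
    )
    pd.DataFrame(rows, columns=["stock_name", "slot", "required_volume_ul"]).to_csv(
        path, index=False
    )
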