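"""Blend solver: turn a target medium composition into per-well volumes.

The core dilution identity is C1*V1 = C2*V2: the volume of stock needed to
reach a target concentration in a well is

    V_stock = (C_target / C_stock) * V_fill

with pure water topping the well up to the fill volume.  The solver
enforces the two feasibility rules of automated blending: the summed stock
volumes must not exceed the fill volume, and no single transfer may fall
below the pipettable minimum (sub-microliter transfers are unreliable on
small liquid handlers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    AmbiguousItem,
    OverfullWell,
    SubMinimumTransfer,
    UnitMismatch,
    UnresolvedItem,
    WaterOnlyMedium,
)
from .registry import StockRegistry, StockSolution, _check_unit, _fmt_number

WATER = "WATER"

MEDIA_CSV_COLUMNS = [
    "medium_name",
    "item",
    "target_concentration",
    "unit",
    "fill_volume_ul",
]


@dataclass
class MediumSpec:
    """A target formulation: item -> (concentration, unit family).

    An item is either a stock name or a component name; it is resolved
    against the registry at solve time (exact stock-name match first, then
    unique-component match).
    """

    name: str
    targets: dict[str, tuple[float, str]]
    fill_volume_ul: float = 2000.0

    def __post_init__(self):
        if not self.fill_volume_ul > 0:
            raise ValueError(f"medium {self.name!r}: fill volume must be > 0")
        for item, (conc, unit) in self.targets.items():
            _check_unit(unit)
            if not conc > 0:
                raise ValueError(
                    f"medium {self.name!r}: target concentration of {item!r} must be > 0"
                )

    def with_target(self, item: str, concentration: float, unit: str, name: str | None = None
                    ) -> "MediumSpec":
        """Copy of this medium with one target set (or removed at conc 0)."""
        targets = dict(self.targets)
        if concentration == 0:
            targets.pop(item, None)
        else:
            targets[item] = (concentration, unit)
        return MediumSpec(
            name=name if name is not None else self.name,
            targets=targets,
            fill_volume_ul=self.fill_volume_ul,
        )


@dataclass
class Constraints:
    """Pipetting constraints of the liquid handler.

    min_transfer_ul: smallest reliable transfer (default 1 ul, i.e. no
    sub-microliter dispenses); resolution_ul: volume rounding step;
    max_single_dispense_ul: largest single dispense, larger transfers are
    split into equal sub-steps.
    """

    min_transfer_ul: float = 1.0
    resolution_ul: float = 0.1
    max_single_dispense_ul: float = 300.0


@dataclass
class TransferPlan:
    """Per-well pipetting steps realising one medium.

    ``steps`` is an ordered list of (source stock name or WATER, volume in
    ul); the water top-up is always the final step.  ``achieved`` reports
    the concentration realised by each rounded volume so rounding error is
    visible next to the target.
    """

    medium_name: str
    fill_volume_ul: float
    steps: list[tuple[str, float]]
    achieved: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    well_label: str = ""

    @property
    def water_volume_ul(self) -> float:
        return sum(v for s, v in self.steps if s == WATER)

    @property
    def stock_volume_ul(self) -> float:
        return sum(v for s, v in self.steps if s != WATER)


def _resolve_item(item: str, registry: StockRegistry) -> tuple[StockSolution, str]:
    """Resolve a target item to (stock, component).

    Precedence: exact stock-name match (stock must be single-component,
    else the target is ambiguous), then unique registered stock containing
    the item as a component.
    """
    if registry.has_stock(item):
        stock = registry.get_stock(item)
        if len(stock.contents) != 1:
            raise AmbiguousItem(
                f"target {item!r} names a multi-component stock; specify a component"
            )
        return stock, next(iter(stock.contents))
    candidates = registry.stocks_containing(item)
    if not candidates:
        raise UnresolvedItem(f"target {item!r} matches no registered stock or component")
    if len(candidates) > 1:
        raise AmbiguousItem(
            f"component {item!r} is supplied by multiple stocks: "
            f"{[s.name for s in candidates]}"
        )
    stock = candidates[0]
    comp = next(c for c in stock.contents if c.lower() == item.lower())
    return stock, comp


def _round_to(volume: float, resolution: float) -> float:
    # round half away from zero, in resolution steps
    return math.floor(volume / resolution + 0.5) * resolution


def ideal_volumes(medium: MediumSpec, registry: StockRegistry) -> dict[str, tuple[str, float]]:
    """Exact (unrounded) volumes: item -> (stock name, C_t/C_s * V_fill).

    This is the closed-form dilution computation prior to any rounding or
    splitting; exposed separately so it can serve as an oracle check.
    """
    out: dict[str, tuple[str, float]] = {}
    for item, (conc, unit) in medium.targets.items():
        stock, comp = _resolve_item(item, registry)
        comp_meta = registry.get_component(comp)
        if comp_meta.unit_family != unit:
            raise UnitMismatch(
                f"target {item!r} stated in {unit!r} but component {comp!r} "
                f"uses {comp_meta.unit_family!r}"
            )
        stock_conc = stock.contents[comp]
        out[item] = (stock.name, conc / stock_conc * medium.fill_volume_ul)
    return out


def solve_blend(
    medium: MediumSpec,
    registry: StockRegistry,
    constraints: Constraints | None = None,
) -> TransferPlan:
    """Compute a feasible per-well transfer plan for a target medium.

    Volumes are rounded to the pipette resolution; transfers larger than
    the single-dispense maximum are split into equal sub-steps; water is
    dispensed last, by difference.  Raises :class:`SubMinimumTransfer`
    (with the smallest stock dilution that would fix it),
    :class:`OverfullWell`, :class:`AmbiguousItem` or
    :class:`UnresolvedItem` on infeasible designs.
    """
    c = constraints or Constraints()
    ideals = ideal_volumes(medium, registry)

    for item, (_, vol) in ideals.items():
        if vol < c.min_transfer_ul - 1e-12:
            raise SubMinimumTransfer(item, vol, c.min_transfer_ul)

    rounded = {item: (_round_to(vol, c.resolution_ul), stock)
               for item, (stock, vol) in ideals.items()}
    total_stock = sum(v for v, _ in rounded.values())
    if total_stock > medium.fill_volume_ul + c.resolution_ul / 4:
        raise OverfullWell(
            f"medium {medium.name!r}: stock volumes sum to {total_stock:.1f} ul "
            f"> fill volume {medium.fill_volume_ul:.1f} ul"
        )

    # deterministic step order: registry registration order of the stocks
    ordered = sorted(rounded.items(), key=lambda kv: registry.stock_order(kv[1][1]))

    steps: list[tuple[str, float]] = []
    flags: list[str] = []
    for item, (vol, stock_name) in ordered:
        if vol > c.max_single_dispense_ul:
            n = math.ceil(vol / c.max_single_dispense_ul)
            part = _round_to(vol / n, c.resolution_ul)
            parts = [part] * (n - 1) + [round(vol - part * (n - 1), 10)]
            flags.append(f"{item}: {vol:g} ul split into {n} sub-steps")
            steps.extend((stock_name, p) for p in parts)
        else:
            steps.append((stock_name, vol))

    water = medium.fill_volume_ul - total_stock
    if water > c.resolution_ul / 4:
        steps.append((WATER, water))

    achieved = {}
    for item, (vol, stock_name) in rounded.items():
        stock, comp = _resolve_item(item, registry)
        achieved[item] = vol / medium.fill_volume_ul * stock.contents[comp]
        target = medium.targets[item][0]
        if target > 0 and abs(achieved[item] - target) / target > 0.01:
            flags.append(f"{item}: rounding shifts concentration by >1%")

    return TransferPlan(
        medium_name=medium.name,
        fill_volume_ul=medium.fill_volume_ul,
        steps=steps,
        achieved=achieved,
        flags=flags,
    )


def water_fraction(plan: TransferPlan) -> float:
    """Fraction of the fill volume that is pure water top-up, in [0, 1]."""
    return plan.water_volume_ul / plan.fill_volume_ul


def max_fold_concentration(plan: TransferPlan) -> tuple[float, int]:
    """How many-fold the medium could be concentrated before running dry.

    A medium whose stocks occupy a fraction (1 - f) of the well, where f is
    the water fraction, can be prepared at up to 1 / (1 - f) times its
    working strength using the same stocks.  Returns the continuous factor
    and its integer floor.  Raises :class:`WaterOnlyMedium` when the plan
    contains no stock volume at all.
    """
    f = water_fraction(plan)
    if plan.stock_volume_ul <= 0:
        raise WaterOnlyMedium("fold-concentration is unbounded for pure water")
    factor = plan.fill_volume_ul / plan.stock_volume_ul
    return factor, math.floor(factor + 1e-9)


# --- CSV I/O ------------------------------------------------------------


def read_media_csv(path) -> list[MediumSpec]:
    """Load media from ``media.csv`` (one row per medium/item pair)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MEDIA_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"media csv missing columns: {sorted(missing)}")
    media = []
    for name in df["medium_name"].drop_duplicates():
        rows = df[df["medium_name"] == name]
        targets = {
            r["item"]: (float(r["target_concentration"]), _check_unit(r["unit"]))
            for _, r in rows.iterrows()
        }
        media.append(
            MediumSpec(
                name=name,
                targets=targets,
                fill_volume_ul=float(rows.iloc[0]["fill_volume_ul"]),
            )
        )
    return media


def write_media_csv(media: list[MediumSpec], path) -> None:
    rows = []
    for m in media:
        for item, (conc, unit) in m.targets.items():
            rows.append(
                {
                    "medium_name": m.name,
                    "item": item,
                    "target_concentration": _fmt_number(conc),
                    "unit": unit,
                    "fill_volume_ul": _fmt_number(m.fill_volume_ul),
                }
            )
    pd.DataFrame(rows, columns=MEDIA_CSV_COLUMNS).to_csv(path, index=False)
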