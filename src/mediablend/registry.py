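"""Stock-solution registry.

Media are blended from simple concentrated stock solutions ("modules"):
each stock delivers one or more components at a fixed concentration, and a
working medium is built by diluting stocks into a well and topping up with
water.  This module holds the library of stocks and component metadata that
all blending computations resolve against.

Unit families are closed: a concentration is expressed in exactly one of

* ``g_per_L`` — mass per volume (g/L),
* ``v_v_percent`` — volume percent (v/v%),
* ``fold`` — multiples of a named reference mixture (e.g. "1x YNB").

No conversion between families is ever attempted; a target and the stock
that delivers it must share a family.  Fold units are anchored to the
reference mixture's name: "1x YNB" and "1x MEM amino acids" are unrelated
quantities even though both are "fold".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    DuplicateName,
    MissingSolubility,
    NonPositiveConcentration,
    UnitMismatch,
    UnknownComponent,
)

UNIT_FAMILIES = ("g_per_L", "v_v_percent", "fold")
STABILITY_CLASSES = ("stable_ambient", "stable_4C", "frozen_aliquot")

STOCKS_CSV_COLUMNS = [
    "stock_name",
    "component",
    "concentration",
    "unit",
    "dead_volume_ul",
    "note",
]


def _check_unit(unit: str) -> str:
    if unit not in UNIT_FAMILIES:
        raise UnitMismatch(f"unknown unit family {unit!r}; expected one of {UNIT_FAMILIES}")
    return unit


@dataclass
class Component:
    """A medium component and its stocking metadata.

    ``solubility_limit`` (same unit family as the component) supports the
    rule of thumb that a component is comfortably stockable when it is
    soluble at >=10x its working concentration.  ``stability_class``
    records how the stock must be stored (less stable components, such as
    vitamins, are aliquoted and frozen).
    """

    name: str
    unit_family: str
    solubility_limit: float | None = None
    stability_note: str | None = None
    stability_class: str | None = None

    def __post_init__(self):
        _check_unit(self.unit_family)
        if self.solubility_limit is not None and not self.solubility_limit > 0:
            raise NonPositiveConcentration(
                f"solubility limit of {self.name!r} must be > 0"
            )
        if self.stability_class is not None and self.stability_class not in STABILITY_CLASSES:
            raise ValueError(
                f"stability_class must be one of {STABILITY_CLASSES}, got {self.stability_class!r}"
            )


@dataclass
class StockSolution:
    """A named concentrated solution delivering one or more components.

    ``contents`` maps component name -> concentration in that component's
    unit family.  A fold-unit stock concentrates exactly one named
    reference mixture (the component name *is* the reference), so it must
    be single-component.  ``dead_volume_ul`` is the unrecoverable volume of
    the source labware, applied only when aggregating deck requirements.
    """

    name: str
    contents: dict[str, float]
    dead_volume_ul: float = 0.0
    note: str = ""

    def __post_init__(self):
        if not self.contents:
            raise ValueError(f"stock {self.name!r} has no contents")
        for comp, conc in self.contents.items():
            if not conc > 0:
                raise NonPositiveConcentration(
                    f"stock {self.name!r}: concentration of {comp!r} must be > 0, got {conc}"
                )
        if self.dead_volume_ul < 0:
            raise ValueError(f"stock {self.name!r}: dead volume must be >= 0")


@dataclass
class StockRegistry:
    """Library of components and stock solutions.

    Stocks keep registration order, which downstream code uses for
    deterministic transfer-step ordering.
    """

    components: dict[str, Component] = field(default_factory=dict)
    stocks: dict[str, StockSolution] = field(default_factory=dict)

    # -- components ------------------------------------------------------

    def add_component(self, component: Component) -> "StockRegistry":
        key = component.name.lower()
        if key in (c.lower() for c in self.components):
            raise DuplicateName(f"component {component.name!r} already registered")
        self.components[component.name] = component
        return self

    def get_component(self, name: str) -> Component:
        for cname, comp in self.components.items():
            if cname.lower() == name.lower():
                return comp
        raise UnknownComponent(f"component {name!r} is not registered")

    def has_component(self, name: str) -> bool:
        return any(c.lower() == name.lower() for c in self.components)

    # -- stocks ----------------------------------------------------------

    def register_stock(self, stock: StockSolution) -> "StockRegistry":
        if any(s.lower() == stock.name.lower() for s in self.stocks):
            raise DuplicateName(f"stock {stock.name!r} already registered")
        for comp_name in stock.contents:
            if not self.has_component(comp_name):
                raise UnknownComponent(
                    f"stock {stock.name!r} references unregistered component {comp_name!r}"
                )
        fold_comps = [
            c for c in stock.contents if self.get_component(c).unit_family == "fold"
        ]
        if fold_comps and len(stock.contents) > 1:
            raise ValueError(
                f"fold-unit stock {stock.name!r} must contain exactly the one "
                f"reference mixture it concentrates, got {sorted(stock.contents)}"
            )
        self.stocks[stock.name] = stock
        return self

    def get_stock(self, name: str) -> StockSolution:
        for sname, stock in self.stocks.items():
            if sname.lower() == name.lower():
                return stock
        raise UnresolvedName(name)

    def has_stock(self, name: str) -> bool:
        return any(s.lower() == name.lower() for s in self.stocks)

    def stocks_containing(self, component: str) -> list[StockSolution]:
        return [
            s
            for s in self.stocks.values()
            if any(c.lower() == component.lower() for c in s.contents)
        ]

    def stock_order(self, name: str) -> int:
        """Registration index of a stock, for deterministic step ordering."""
        for i, sname in enumerate(self.stocks):
            if sname.lower() == name.lower():
                return i
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.stocks)


class UnresolvedName(KeyError):
    pass


def stockability_margin(
    component: Component, working_concentration: float, unit_family: str | None = None
) -> float:
    """Ratio solubility limit / working concentration (dimensionless).

    A margin >= 10 means the component can comfortably be kept as a 10x
    concentrated stock.  Raises :class:`MissingSolubility` when the
    component has no recorded limit and :class:`UnitMismatch` when the
    working concentration is stated in a different unit family.
    """
    if unit_family is not None and unit_family != component.unit_family:
        raise UnitMismatch(
            f"working concentration unit {unit_family!r} differs from component "
            f"family {component.unit_family!r}"
        )
    if component.solubility_limit is None:
        raise MissingSolubility(f"component {component.name!r} has no solubility limit")
    if not working_concentration > 0:
        raise NonPositiveConcentration("working concentration must be > 0")
    return component.solubility_limit / working_concentration


# --- CSV I/O ------------------------------------------------------------


def read_stocks_csv(path) -> StockRegistry:
    """Load a registry from ``stocks.csv``.

    One row per (stock, component) pair; multi-component stocks span
    multiple rows.  Components are created implicitly from the ``unit``
    column; conflicting units for the same component raise
    :class:`UnitMismatch`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(STOCKS_CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"stocks csv missing columns: {sorted(missing)}")
    registry = StockRegistry()
    # first pass: components
    for _, row in df.iterrows():
        comp, unit = row["component"], _check_unit(row["unit"])
        if registry.has_component(comp):
            if registry.get_component(comp).unit_family != unit:
                raise UnitMismatch(
                    f"component {comp!r} declared with conflicting units"
                )
        else:
            registry.add_component(Component(name=comp, unit_family=unit))
    # second pass: stocks, preserving first-appearance order
    for stock_name in df["stock_name"].drop_duplicates():
        rows = df[df["stock_name"] == stock_name]
        contents = {r["component"]: float(r["concentration"]) for _, r in rows.iterrows()}
        dead = rows.iloc[0].get("dead_volume_ul", "")
        note = rows.iloc[0].get("note", "")
        registry.register_stock(
            StockSolution(
                name=stock_name,
                contents=contents,
                dead_volume_ul=float(dead) if dead not in ("", None) else 0.0,
                note=note or "",
            )
        )
    return registry


def write_stocks_csv(registry: StockRegistry, path) -> None:
    """Write a registry to ``stocks.csv`` (inverse of :func:`read_stocks_csv`)."""
    rows = []
    for stock in registry.stocks.values():
        for comp, conc in stock.contents.items():
            rows.append(
                {
                    "stock_name": stock.name,
                    "component": comp,
                    "concentration": _fmt_number(conc),
                    "unit": registry.get_component(comp).unit_family,
                    "dead_volume_ul": _fmt_number(stock.dead_volume_ul),
                    "note": stock.note,
                }
            )
    pd.DataFrame(rows, columns=STOCKS_CSV_COLUMNS).to_csv(path, index=False)


def _fmt_number(x: float) -> str:
    """Shortest exact decimal for round-trip-stable CSVs."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))
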