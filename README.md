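# mediablend

Modular media blending, design-of-experiments statistics, and greedy media
optimization for microbial bioprocess development.

## The problem

Developing a culture medium that maximises a measurable phenotype — biomass
after outgrowth, secreted product titer after induction — is slow when every
candidate formulation has to be weighed out and dissolved by hand.  A modular
alternative is to keep a library of simple **concentrated stock solutions**
(a sugar at 450 g/L, a 10x trace-element premix, a 100x lipid supplement) and
let a small liquid handler blend any working medium directly in the wells of
a 24-well plate: for each target concentration the required stock volume
follows the dilution identity

    V_stock = (C_target / C_stock) · V_fill,

and pure water tops the well up.  A design is feasible when the summed stock
volumes fit in the well and no single transfer falls below the pipettable
minimum (1 µl by default).

On top of the blending layer, `mediablend` implements an iterative greedy
optimization framework for media development: each round **screens** a
library of supplements singly against the current medium, tests the
beneficial ones **in combination** (singles plus all pairs, ranked by mean),
and then **optimizes the concentrations** of what was accepted (1-FAAT scans
or a full-factorial quadratic surface).  Rounds repeat until a target is
met, the library is exhausted, or a round yields no accepted change.

The statistics layer provides the supporting methods: full-factorial
designs, quadratic response-surface regression with sequential backward
elimination (terms with adjusted p > α are removed one at a time, worst
first, with a refit after each removal), control-based screening with
Benjamini–Hochberg adjustment inside a one-way-ANOVA frame, and one-tailed
Welch comparisons.  A synthetic phenotype simulator (multiplicative effect
curves — saturating essentials, peaked optima, inhibitory declines,
saturating boosts — with pairwise synergies and log-normal replicate noise)
makes the whole loop testable without cultivation data.

## Worked example

Blend a defined yeast biomass medium (22.5 g/L fructose, 1x YNB, 7 g/L
urea, 10 g/L potassium phosphate) in a 2 ml well from four stocks:

```python
from mediablend import *

reg = StockRegistry()
reg.add_component(Component(name="fructose", unit_family="g_per_L", solubility_limit=400))
reg.add_component(Component(name="YNB", unit_family="fold"))
reg.add_component(Component(name="urea", unit_family="g_per_L"))
reg.add_component(Component(name="potassium phosphate", unit_family="g_per_L"))
reg.register_stock(StockSolution("fructose 450", {"fructose": 450}))
reg.register_stock(StockSolution("YNB 10x", {"YNB": 10}))
reg.register_stock(StockSolution("urea 140", {"urea": 140}))
reg.register_stock(StockSolution("phosphate 200", {"potassium phosphate": 200}))

dm1 = MediumSpec(name="DM1_base", targets={
    "fructose": (22.5, "g_per_L"), "YNB": (1, "fold"),
    "urea": (7, "g_per_L"), "potassium phosphate": (10, "g_per_L")},
    fill_volume_ul=2000)

plan = solve_blend(dm1, reg)
for src, vol in plan.steps:
    print(f"{src:<16} {vol:7.1f} ul")
factor, integer = max_fold_concentration(plan)
print("water fraction:", water_fraction(plan))
print(f"fold-concentration: {factor:.2f} (integer {integer})")
```

prints

```
fructose 450       100.0 ul
YNB 10x            200.0 ul
urea 140           100.0 ul
phosphate 200      100.0 ul
WATER             1500.0 ul
water fraction: 0.75
fold-concentration: 4.00 (integer 4)
```

Each stock volume is the dilution closed form (e.g. fructose:
22.5/450 × 2000 = 100 µl), water fills by difference, and because the
stocks occupy only a quarter of the well this medium could be prepared up
to 4x concentrated from the same stocks — headroom that matters when later
rounds add supplements.  `stockability_margin(component, working_conc)`
reports how comfortably a component can be stocked (fructose here: 400/22.5
≈ 17.8x its working concentration).

The `mediablend` CLI exposes the same workflow on CSV files:
`mediablend plan --stocks stocks.csv --media media.csv --format 24 --seed 1
--out run/` writes the design sheet, the source-grouped transfer worklist,
and the deck plan (per-stock volumes with dead volume and a 10% safety
margin), plus a manifest with input hashes and the seed; `fit`, `screen`,
`simulate` and `optimize` cover the statistics and the optimization loop.

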