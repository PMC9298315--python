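import pytest

from mediablend import Component, MediumSpec, StockRegistry, StockSolution


@pytest.fixture
def dm1_registry() -> StockRegistry:
    """Stocks for a defined yeast biomass medium: fructose carbon source,
    YNB trace-element module, urea nitrogen, phosphate buffer."""
    reg = StockRegistry()
    reg.add_component(Component(name="fructose", unit_family="g_per_L",
                                solubility_limit=400.0))
    reg.add_component(Component(name="YNB", unit_family="fold"))
    reg.add_component(Component(name="urea", unit_family="g_per_L"))
    reg.add_component(Component(name="potassium phosphate", unit_family="g_per_L"))
    reg.register_stock(StockSolution("fructose 450", {"fructose": 450}))
    reg.register_stock(StockSolution("YNB 10x", {"YNB": 10}))
    reg.register_stock(StockSolution("urea 140", {"urea": 140}))
    reg.register_stock(StockSolution("phosphate 200", {"potassium phosphate": 200}))
    return reg


@pytest.fixture
def dm1_base() -> MediumSpec:
    """Basal biomass medium: 22.5 g/L fructose, 1x YNB, 7 g/L urea,
    10 g/L potassium phosphate, in a 2 ml well."""
    return MediumSpec(
        name="DM1_base",
        targets={
            "fructose": (22.5, "g_per_L"),
            "YNB": (1, "fold"),
            "urea": (7, "g_per_L"),
            "potassium phosphate": (10, "g_per_L"),
        },
        fill_volume_ul=2000,
    )
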