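import pytest

from pphecon import (
    AnalysisConfig,
    Strategy,
    StrategyPair,
    load_costs,
    load_evidence,
    load_recipe,
)


@pytest.fixture(scope="session")
def evidence_registry():
    return load_evidence()


@pytest.fixture(scope="session")
def tuncalp(evidence_registry):
    return evidence_registry["tuncalp2012"]


@pytest.fixture(scope="session")
def hundley(evidence_registry):
    return evidence_registry["hundley2013"]


@pytest.fixture(scope="session")
def costs():
    return load_costs()


@pytest.fixture(scope="session")
def recipe_and_doses():
    return load_recipe()


@pytest.fixture(scope="session")
def recipe(recipe_and_doses):
    return recipe_and_doses[0]


@pytest.fixture(scope="session")
def doses(recipe_and_doses):
    return recipe_and_doses[1]


@pytest.fixture()
def base_config(evidence_registry, costs, recipe, doses):
    """Oxytocin in hospital + misoprostol in community, vs oxytocin + nothing:
    the shipped base-case comparison (1000 births, 40/60 mix)."""
    pair = StrategyPair(
        intervention=Strategy("oxytocin", "misoprostol"),
        comparator=Strategy("oxytocin", "none"),
    )
    return AnalysisConfig(
        pair=pair, evidence=evidence_registry, costs=costs, doses=doses, recipe=recipe
    )


@pytest.fixture()
def second_config(evidence_registry, costs, recipe, doses):
    """Misoprostol everywhere vs no treatment anywhere (oxytocin unavailable)."""
    pair = StrategyPair(
        intervention=Strategy("misoprostol", "misoprostol"),
        comparator=Strategy("none", "none"),
    )
    return AnalysisConfig(
        pair=pair, evidence=evidence_registry, costs=costs, doses=doses, recipe=recipe
    )
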