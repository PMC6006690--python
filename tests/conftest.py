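import pytest

from gapfillkit import (
    Direction,
    GapFillConfig,
    MetaboliteSpec,
    MetabolicModel,
    ModelCondition,
    ReactionSpec,
)


def mk_model(reactions, nutrients, biomass, secretions=()):
    """Build a model from reaction specs; metabolites inferred."""
    mets = {}
    for r in reactions:
        for m in r.stoichiometry:
            mets.setdefault(m, MetaboliteSpec(m))
    for m, _ in nutrients:
        mets.setdefault(m, MetaboliteSpec(m))
    for m in secretions:
        mets.setdefault(m, MetaboliteSpec(m))
    for m, _ in biomass:
        mets.setdefault(m, MetaboliteSpec(m))
    return MetabolicModel(
        mets, reactions, ModelCondition(nutrients, secretions, biomass)
    )


@pytest.fixture
def toy3():
    """Three metabolites A, B, Z; one reaction A -> B; growth requires Z."""
    return mk_model(
        [ReactionSpec("R1", {"A": -1, "B": 1}, Direction.L2R)],
        nutrients=[("A", 10.0)],
        biomass=[("Z", 1.0)],
    )


@pytest.fixture
def cand_c1():
    return ReactionSpec("C1", {"B": -1, "Z": 1}, Direction.L2R, in_taxonomic_range=True)


@pytest.fixture
def cand_c2():
    return ReactionSpec("C2", {"A": -1, "Z": 1}, Direction.L2R, in_taxonomic_range=False)


@pytest.fixture
def cand_c3():
    return ReactionSpec("C3", {"Z": -1, "B": 1}, Direction.L2R, in_taxonomic_range=True)


@pytest.fixture
def toy3_db(cand_c1, cand_c2, cand_c3):
    return [cand_c1, cand_c2, cand_c3]


@pytest.fixture
def recycling():
    """A -> B + W, B -> Z, W -> B; uptake A <= 10, W secretable, biomass Z.
    Byproduct recycling doubles the attainable biomass flux (20 vs 10)."""
    return mk_model(
        [
            ReactionSpec("R1", {"A": -1, "B": 1, "W": 1}, Direction.L2R),
            ReactionSpec("R2", {"B": -1, "Z": 1}, Direction.L2R),
            ReactionSpec("R3", {"W": -1, "B": 1}, Direction.L2R),
        ],
        nutrients=[("A", 10.0)],
        biomass=[("Z", 1.0)],
        secretions=["W"],
    )


@pytest.fixture
def config():
    return GapFillConfig()
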