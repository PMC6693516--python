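import pytest

from ctxmetanet.model_core import (
    EMPTY_GPR,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
)
from ctxmetanet.synthetic_data import make_toy_model, plant_transformation_scenario


@pytest.fixture(scope="session")
def diamond():
    return make_toy_model("diamond")


@pytest.fixture(scope="session")
def scenario():
    return plant_transformation_scenario("diamond", seed=7)


def _chain_reaction(rid, met_in, met_out, gpr, genes):
    stoich = {}
    if met_in:
        stoich[met_in] = -1.0
    if met_out:
        stoich[met_out] = 1.0
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="chain",
        gpr=parse_gpr(gpr, genes) if gpr else EMPTY_GPR,
    )


@pytest.fixture(scope="session")
def chain5():
    """Linear 5-reaction chain: uptake -> R1 -> R2 -> R3 -> secretion.

    Used for evidence-conflict checks: R1 is the only route from uptake
    to secretion, R3 sits downstream of it.
    """
    genes = ["g1", "g2", "g3"]
    mets = [Metabolite(m) for m in ["m0", "m1", "m2", "m3"]]
    reactions = [
        _chain_reaction("EX_in", None, "m0", "", genes),
        _chain_reaction("R1", "m0", "m1", "g1", genes),
        _chain_reaction("R2", "m1", "m2", "g2", genes),
        _chain_reaction("R3", "m2", "m3", "g3", genes),
        _chain_reaction("EX_out", "m3", None, "", genes),
    ]
    return MetabolicModel(
        metabolites=mets, reactions=reactions, genes=genes, id="chain5"
    )
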