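import numpy as np
import pytest

from bmca.network import MetabolicModel, Metabolite, Reaction, ReferenceState
from bmca.synth import make_toy_network


@pytest.fixture
def chain3_model() -> MetabolicModel:
    """Linear chain A_ext -> A -> B -> B_ext (2 internal metabolites)."""
    mets = [
        Metabolite(id="A_ext", role="external", compartment="e"),
        Metabolite(id="B_ext", role="external", compartment="e"),
        Metabolite(id="A"),
        Metabolite(id="B"),
    ]
    rxns = [
        Reaction("r1", {"A_ext": -1, "A": 1}, protein_ids=("p1",), gpr=(("p1",),)),
        Reaction("r2", {"A": -1, "B": 1}, protein_ids=("p2",), gpr=(("p2",),)),
        Reaction("r3", {"B": -1, "B_ext": 1}),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, target_reaction_id="r3")


@pytest.fixture
def two_step():
    """Two-step chain truth with fixed elasticities (-1, 0.5)."""
    return make_toy_network("two_step")


@pytest.fixture(scope="session")
def branched_truth():
    return make_toy_network("branched_3hp", seed=1)


def finite_difference_cj(model, ref, eps, h=1e-6):
    """Independent FCC oracle: central differences of log steady-state
    flux w.r.t. log enzyme level through the steady-state solver."""
    from bmca.linlog import PerturbationState, solve_steady_state

    nr = model.n_reactions
    CJ = np.zeros((nr, nr))
    for k in range(nr):
        rows = []
        for s in (+1.0, -1.0):
            e = np.ones(nr)
            e[k] = np.exp(s * h)
            sol = solve_steady_state(
                model, ref, eps, PerturbationState(e, np.zeros(model.n_external))
            )
            rows.append(np.log(np.abs(sol.v)))
        CJ[:, k] = (rows[0] - rows[1]) / (2 * h)
    return CJ
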