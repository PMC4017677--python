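import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tinit.gem_core import Metabolite, Model, Reaction, SolverOptions
from tinit.synthetic_fixtures import figure1b_network
from tinit.tasks import Task, TaskIO


@pytest.fixture(scope="session")
def solver_options() -> SolverOptions:
    return SolverOptions()


@pytest.fixture()
def chain_model() -> Model:
    """A_in -> A -> B -> B_out: the smallest network with one internal path."""
    mets = [Metabolite("A", "A", "c"), Metabolite("B", "B", "c")]
    rxns = [
        Reaction("EX_A", {"A": +1.0}, 0.0, 1000.0),
        Reaction("R_AB", {"A": -1.0, "B": +1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0),
    ]
    model = Model("chain", mets, rxns)
    model.validate()
    return model


@pytest.fixture()
def chain_task() -> Task:
    return Task(
        id="B_from_A",
        category="biosynthesis_of_products",
        inputs=[TaskIO("A", 0.0, 1000.0)],
        outputs=[TaskIO("B", None, 1000.0)],
    )


@pytest.fixture(scope="session")
def fig1b():
    return figure1b_network()
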