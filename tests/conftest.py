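import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from gemflux import make_glutamate_core, make_linear_chain  # noqa: E402


@pytest.fixture
def chain5():
    return make_linear_chain(5, uptake=10.0)


@pytest.fixture
def core():
    return make_glutamate_core()


@pytest.fixture
def loopy_chain():
    """Chain with a planted reversible duplicate step forming a 2-cycle."""
    from gemflux.model import Reaction

    model = make_linear_chain(3, uptake=10.0)
    model.add_reaction(Reaction(
        id="CYC_F", name="duplicate A->B step (cycle partner)",
        stoichiometry={"A_c": -1.0, "B_c": 1.0},
        lower_bound=-1000.0, upper_bound=1000.0))
    return model
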