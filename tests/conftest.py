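import pytest

from qnsim import QualitativeNetwork, NodeDef, EdgeDef
from qnsim.network import INHIBITING
from qnsim import synthetic


@pytest.fixture
def mutual_activation():
    """Two Boolean nodes activating each other; 3 attractors under the
    synchronous semantics: fixed (0,0), fixed (1,1), and the 2-cycle."""
    return synthetic.make_motif("mutual_activation", max_level=1)


@pytest.fixture
def abc_node():
    """A node 'X' with activators A, B and inhibitor C, all Boolean-to-two-level."""
    nodes = [NodeDef(n, 0, 2) for n in ("A", "B", "C", "X")]
    edges = [
        EdgeDef("A", "X"),
        EdgeDef("B", "X"),
        EdgeDef("C", "X", INHIBITING),
    ]
    return QualitativeNetwork(nodes, edges)


@pytest.fixture
def cascade():
    """In -> A -> B, all ranges 0-2, default functions."""
    return synthetic.make_motif("linear_cascade", max_level=2, cascade_length=3)


@pytest.fixture
def tnf_autocrine():
    return synthetic.make_motif("tnf_autocrine", max_level=2)


@pytest.fixture(scope="session")
def demo_model():
    return synthetic.demo_model()


@pytest.fixture(scope="session")
def demo_backgrounds():
    return synthetic.demo_backgrounds()


@pytest.fixture(scope="session")
def demo_drugs():
    return synthetic.demo_drugs()
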