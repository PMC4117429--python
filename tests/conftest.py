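import pytest

from boolcarve import synth


@pytest.fixture
def toy3():
    return synth.fixture("TOY3")


@pytest.fixture
def triad():
    return synth.fixture("TRIAD")


@pytest.fixture
def ffwd5():
    return synth.fixture("FFWD5")


@pytest.fixture
def redundant4():
    return synth.fixture("REDUNDANT4")


def random_networks(count, seed0=100, n_nodes=10, n_inputs=2, plant=(2, 1),
                    degree=("poisson", 2), bias=0.5):
    """Seeded ensemble of random networks with a planted feedback loop (so a
    nontrivial primary attractor usually exists)."""
    nets = []
    for i in range(count):
        spec = synth.SynthSpec(
            n_nodes=n_nodes, n_inputs=n_inputs, degree=degree, bias=bias,
            planted_loops=[plant], seed=seed0 + i,
        )
        nets.append(synth.generate(spec))
    return nets
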