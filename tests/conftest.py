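import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from glygolgi.golgi import (GolgiSolver, load_cell_line_profiles,
                            load_default_config)
from glygolgi.network import PruneConfig, generate_network
from glygolgi.rules import load_default_ruleset


@pytest.fixture(scope="session")
def ruleset():
    return load_default_ruleset()


@pytest.fixture(scope="session")
def profiles():
    return load_cell_line_profiles()


@pytest.fixture(scope="session")
def small_net(ruleset):
    """~1,400-structure reduced CHO network for solver/fitter tests."""
    return generate_network(ruleset, prune=PruneConfig(threshold=3e-4))


@pytest.fixture(scope="session")
def coarse_net(ruleset):
    """~600-structure network for the repeated-fit (noisy recovery) tests."""
    return generate_network(ruleset, prune=PruneConfig(threshold=1e-3))


@pytest.fixture(scope="session")
def tiny_net(ruleset):
    """<=200-structure network for dense-solver equivalence checks."""
    net = generate_network(ruleset, prune=PruneConfig(threshold=5e-3))
    assert net.n_structures <= 200
    return net


@pytest.fixture(scope="session")
def corpus(ruleset):
    """>=500 generated glycans with at most 12 residues (matcher corpus)."""
    net = generate_network(ruleset, prune=PruneConfig(threshold=1e-5),
                           mass_cutoff=3300.0)
    structures = [g for g in net.structures if g.n_residues() <= 12]
    assert len(structures) >= 500
    return structures


@pytest.fixture()
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def small_solver(small_net, ruleset):
    return GolgiSolver(small_net, ruleset, load_default_config())


@pytest.fixture(scope="session")
def packaged_network(ruleset):
    """The full default CHO network (published-scale pruning)."""
    return generate_network(ruleset, prune=PruneConfig())
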