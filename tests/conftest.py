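import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xrseq import GeneAnnotation, Reference, SimulationConfig
from xrseq.synthetic_data import random_reference, simulate_experiment_pair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def plasmid() -> Reference:
    """7 kb circular synthetic plasmid used across tests."""
    return random_reference(7000, seed=20230916, name="plasmid", topology="circular")


@pytest.fixture(scope="session")
def gene_bla() -> GeneAnnotation:
    """1 kb gene on the plus (sense) strand; its TS is the minus strand."""
    return GeneAnnotation("bla", 1000, 2000, "+")


@pytest.fixture(scope="session")
def prokaryote_pair(tmp_path_factory, plasmid, gene_bla):
    """A simulated mfd+/mfd- pair (defaults, n=10,000, bla TS enriched 2.5x)."""
    outdir = tmp_path_factory.mktemp("sim_pair")
    config = SimulationConfig.prokaryote(n_molecules=10_000, seed=7)
    info = simulate_experiment_pair(
        plasmid, [gene_bla], config, e_plus={"bla": 2.5}, outdir=outdir
    )
    return {"ref": plasmid, "genes": [gene_bla], "config": config, "info": info}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
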