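import numpy as np
import pytest

from lipidcc import pipeline, synth
from lipidcc.chem import parse_species


@pytest.fixture(scope="session")
def pe341():
    return parse_species("PE 16:0_18:1")


@pytest.fixture(scope="session")
def pe394():
    return parse_species("PE 17:0_22:4(7,10,13,16)")


@pytest.fixture(scope="session")
def pc364():
    return parse_species("PC 16:0_20:4(5,8,11,14)")


@pytest.fixture(scope="session")
def fa181():
    return parse_species("FA 18:1")


@pytest.fixture(scope="session")
def noiseless_truth():
    return synth.generate_lipidome(
        12, seed=7, params=synth.SimulationParams.noiseless()
    )


@pytest.fixture(scope="session")
def noiseless_layers(noiseless_truth):
    return synth.simulate_run(noiseless_truth)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_layers):
    return pipeline.run_pipeline(
        pipeline.RunConfig(),
        noiseless_layers["profile"],
        noiseless_layers["chains"],
        noiseless_layers["pb"],
    )
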