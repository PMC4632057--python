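import dataclasses

import pytest

import venomconcord as vc


@pytest.fixture(scope="session")
def cfg() -> vc.SimConfig:
    return vc.SimConfig()


@pytest.fixture(scope="session")
def truth(cfg: vc.SimConfig) -> vc.VenomSystemTruth:
    return vc.generate_abundances(cfg, seed=11)


@pytest.fixture(scope="session")
def ideal_cfg(cfg: vc.SimConfig) -> vc.SimConfig:
    return dataclasses.replace(cfg, detection_threshold=0.0)
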