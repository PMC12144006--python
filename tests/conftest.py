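from __future__ import annotations

import pytest

from petvrt import ExperimentConfig, run_vrt_experiment


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    """The standard noiseless study: six NEMA spheres, five SBRs, 7 mm FWHM."""
    return ExperimentConfig()


@pytest.fixture(scope="session")
def vrt_study(default_config):
    """Full wall-less vs. walled VRT experiment, shared across tests."""
    return run_vrt_experiment(default_config)


@pytest.fixture(scope="session")
def sphere37_sbr10(vrt_study):
    """The wall-less 37 mm sphere simulation at the highest contrast."""
    return vrt_study.simulations[("wall-less", "D37mm", 10.0)]
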