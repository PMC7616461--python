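import numpy as np
import pytest

from bhcal.oxymodel import ArterialState, ModelConstants
from bhcal.synthdata import (
    ParadigmSpec,
    assemble_synthetic_session,
    default_ground_truth,
)


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def arterial(constants) -> ArterialState:
    """Group-typical arterial state: Hb 15 g/dL, PaO2 127 -> 104 mmHg."""
    return ArterialState.from_physiology(15.0, 127.0, 104.0, constants)


@pytest.fixture(scope="session")
def paradigm() -> ParadigmSpec:
    return ParadigmSpec()


@pytest.fixture(scope="session")
def noiseless_session():
    """Uniform noiseless phantom session plus its ground truth."""
    gt = default_ground_truth(noiseless=True, vessels=False)
    series, pd_volume, gt = assemble_synthetic_session(gt, seed=11)
    return series, pd_volume, gt


@pytest.fixture(scope="session")
def noisy_session():
    """Default phantom with realistic noise levels."""
    gt = default_ground_truth()
    series, pd_volume, gt = assemble_synthetic_session(gt, seed=11)
    return series, pd_volume, gt
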