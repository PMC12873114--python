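import numpy as np
import pytest

from ttrkin import (DoseRegimen, ExchangeState, PKParameters,
                    StabiliserRelation, TTRParameters)

# Literature reference values used throughout: serum tetramer steady state
# 6.44 μM, tetramer clearance 0.016 1/h, dissociation 0.0024 1/h,
# tetramerisation 3.6e5 1/(μM³·h).
TST = 6.44
KREM_T = 0.016
KD = 0.0024
KA = 360000.0


@pytest.fixture
def reference_params() -> TTRParameters:
    """Reference turnover parameters; krem_M = 0 (reassociation regime)."""
    return TTRParameters.reference()


@pytest.fixture
def degradation_params() -> TTRParameters:
    """Deep degradation-dominated parameterisation: rapid monomer
    clearance (100 1/h) with r back-calculated for the same Tst = 6.44."""
    return TTRParameters(r=TST * (KREM_T + KD), kd=KD, ka=KA,
                         krem_T=KREM_T, krem_M=100.0)


@pytest.fixture
def reference_relation() -> StabiliserRelation:
    return StabiliserRelation.reference()


@pytest.fixture
def reference_pk() -> PKParameters:
    return PKParameters.reference()


@pytest.fixture
def daily_61mg() -> DoseRegimen:
    return DoseRegimen.daily(61.0, n_days=7)


@pytest.fixture
def equimolar_assay() -> ExchangeState:
    return ExchangeState.equimolar(6.44)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260901)
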