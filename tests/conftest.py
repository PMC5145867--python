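import dataclasses

import numpy as np
import pytest

from fruitflux import synthetic_data as sd
from fruitflux.model_core import (
    CALIBRATION_BOUNDS,
    CALIBRATION_PARAM_ORDER,
    LOG_SCALE_PARAMS,
    GenericParams,
    GenotypeParams,
)


@pytest.fixture(scope="session")
def generic():
    g = GenericParams()
    g.validate()
    return g


@pytest.fixture(scope="session")
def env():
    return sd.default_environment()


@pytest.fixture(scope="session")
def base_inputs():
    return sd.default_base_inputs()


@pytest.fixture(scope="session")
def inputs_c(base_inputs):
    return sd.make_treatment_inputs(base_inputs, "C")


@pytest.fixture(scope="session")
def inputs_wd(base_inputs):
    return sd.make_treatment_inputs(base_inputs, "WD")


def mid_bounds_genotype() -> GenotypeParams:
    """Geometric mid-point for log-scaled parameters, arithmetic otherwise."""
    values = {}
    for name in CALIBRATION_PARAM_ORDER:
        lo, hi = CALIBRATION_BOUNDS[name]
        if name in LOG_SCALE_PARAMS:
            values[name] = float(np.sqrt(lo * hi))
        else:
            values[name] = 0.5 * (lo + hi)
    return GenotypeParams(**values)


@pytest.fixture(scope="session")
def mid_genotype():
    return mid_bounds_genotype()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genotype_and_inputs(rng, treatment="C"):
    """One random valid (genotype, inputs) draw for property tests."""
    genotype = sd.sample_genotype(CALIBRATION_BOUNDS, rng)
    base = sd.default_base_inputs()
    w0 = float(10.0 ** rng.uniform(np.log10(0.13), 0.0))
    base = dataclasses.replace(base, w0obs=w0, s0obs=w0 * float(rng.uniform(0.07, 0.12)))
    return genotype, sd.make_treatment_inputs(base, treatment)
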