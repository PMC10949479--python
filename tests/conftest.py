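import warnings

import pytest

from bifidoflux import fluxcalc
from bifidoflux.netcore import RatioConstraint, apply_medium
from bifidoflux.synthetic_data import (
    CONDITIONS,
    FixtureOptions,
    build_bifid_fixture,
    build_expression_fixture,
    default_medium,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def opts():
    return FixtureOptions()


@pytest.fixture(scope="session")
def model(opts):
    return build_bifid_fixture(opts)


@pytest.fixture(scope="session")
def media(opts):
    return {c: default_medium(c, opts) for c in CONDITIONS}


@pytest.fixture(scope="session")
def profiles(model, opts):
    return {c: build_expression_fixture(model, c, opts) for c in CONDITIONS}


@pytest.fixture(scope="session")
def bounded_models(model, media):
    """Medium-bounded models per condition, acetate:lactate 3.5:2 imposed."""
    out = {}
    for condition, medium in media.items():
        bounded = apply_medium(model, medium)
        out[condition] = fluxcalc.add_ratio_constraint(
            bounded, RatioConstraint("EX_ac_e", "EX_lac__L_e", 1.75))
    return out


@pytest.fixture(scope="session")
def glucose_unit_model(model):
    """Glucose as sole carbon source at 1 mmol/gDCW/h uptake."""
    medium = default_medium("glucose")
    medium.base_uptake_bound = (medium.molecular_weight
                                / medium.reference_molecular_weight)
    return apply_medium(model, medium)
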