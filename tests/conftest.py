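import numpy as np
import pandas as pd
import pytest

import epsurv as ep
from epsurv.simulation import DomainSpec, PulseProtocol


@pytest.fixture(scope="session")
def coefficient_db() -> pd.DataFrame:
    """The bundled cell-coefficient table including the NA entry."""
    return ep.load_cell_coefficients()


@pytest.fixture(scope="session")
def complete_db(coefficient_db) -> pd.DataFrame:
    return coefficient_db.dropna().reset_index(drop=True)


@pytest.fixture(scope="session")
def kyse150_100() -> ep.PelegFermiCoefficients:
    return ep.builtin_coefficients("KYSE-150", 100)[0]


@pytest.fixture(scope="session")
def noiseless_dataset(kyse150_100) -> ep.ViabilityDataset:
    cfg = ep.GeneratorConfig(truths=[kyse150_100], noise_sd=0.0)
    return ep.generate_dataset(cfg)


@pytest.fixture()
def small_domain() -> DomainSpec:
    """A 10 x 10 mm domain, cheap enough for per-test PDE solves."""
    return DomainSpec(
        width=0.01,
        height=0.01,
        spacing=0.25e-3,
        electrode_centers=((0.003, 0.005), (0.007, 0.005)),
        electrode_radius=0.5e-3,
    )


@pytest.fixture()
def default_protocol() -> PulseProtocol:
    return PulseProtocol()
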