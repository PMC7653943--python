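"""Shared fixtures: a desk-scale scanner and cached phantom simulations.

The simulation-backed fixtures are session-scoped because several tests
interrogate the same scheme family; the phantom's seed fixes every draw, so
sharing is safe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dualgate import motion_measurement as mm
from dualgate import phantom_sim as ps
from dualgate.motion_models import GateScheme, ScannerSpec

#: coarse isotropic grid: large enough for the phantom plus 20 mm of travel,
#: small enough to keep a 30-scheme family simulation in seconds
SMALL_SHAPE = (64, 64, 48)
SMALL_VOXEL = (3.0, 3.0, 3.0)

#: the full phantom-study scheme coverage
FAMILY_SCHEMES = tuple(
    GateScheme(r, p) for r in (1, 2, 3, 4, 5, 6) for p in (1, 4, 6, 8, 10)
)

SIM_DURATION_S = 300.0
SIM_SEED = 7


@pytest.fixture(scope="session")
def small_scanner() -> ScannerSpec:
    return ScannerSpec(volume_shape=SMALL_SHAPE, voxel_size_mm=SMALL_VOXEL)


@pytest.fixture(scope="session")
def noiseless_config() -> ps.PhantomConfig:
    return ps.PhantomConfig(noise=False, seed=SIM_SEED)


@pytest.fixture(scope="session")
def noisy_config() -> ps.PhantomConfig:
    return ps.PhantomConfig(noise=True, seed=SIM_SEED)


def _family_table(config, scanner) -> pd.DataFrame:
    rows = []
    for scheme, image_set in ps.simulate_scheme_family(
        config, scanner, FAMILY_SCHEMES, SIM_DURATION_S
    ):
        resp_mm, card_mm = mm.measure_scheme_motion(image_set)
        rows.append(
            {
                "n_resp": scheme.n_resp,
                "n_card": scheme.n_card,
                "resp_mm": resp_mm,
                "card_mm": card_mm,
                "total_mm": resp_mm + card_mm,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def noiseless_motion_table(noiseless_config, small_scanner) -> pd.DataFrame:
    """Measured motion for every scheme of a noiseless phantom family."""
    return _family_table(noiseless_config, small_scanner)


@pytest.fixture(scope="session")
def noisy_motion_table(noisy_config, small_scanner) -> pd.DataFrame:
    """As above with Poisson counts and the reconstruction noise floor."""
    return _family_table(noisy_config, small_scanner)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20201109)
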