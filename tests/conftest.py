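import numpy as np
import pytest

from monofilm.isotherm_io import extract_compression_branch
from monofilm.synthetic_data import (
    STUDY_FRACTIONS,
    ExcessParams,
    Plateau,
    PressureGrid,
    PureEOSParams,
    generate_mixture_isotherm,
    generate_pure_isotherm,
)

KT = 428.2


@pytest.fixture
def grid():
    return PressureGrid(0.0, 35.0, 0.25)


@pytest.fixture
def lipid():
    # lift-off at 40 + 428.2/5.7 = 115.12 A^2
    return PureEOSParams(id="lipid", A0=40.0, pi_c=5.7, kT_term=KT)


@pytest.fixture
def compound():
    return PureEOSParams(id="compound", A0=25.0, pi_c=8.0, kT_term=KT)


@pytest.fixture
def plateau_params():
    return PureEOSParams(
        id="plat", A0=40.0, pi_c=5.7, kT_term=KT,
        plateau=Plateau(pi_t=15.0, delta_A=20.0, width=1.0),
    )


@pytest.fixture
def non_spreading():
    return PureEOSParams(id="drug", non_spreading=True)


def build_study(p1, p2, excess, grid, noise_sigma=0.0, seed=0, fractions=STUDY_FRACTIONS):
    """In-memory study set: clean branches for both pures and all mixtures."""
    seeds = np.random.SeedSequence(seed).generate_state(len(fractions) + 2)
    iso1 = generate_pure_isotherm(p1, grid, noise_sigma, int(seeds[0]))
    iso2 = generate_pure_isotherm(p2, grid, noise_sigma, int(seeds[1]))
    iso2.meta["molar_fraction_x2"] = 1.0
    isos = [iso1, iso2]
    for i, x2 in enumerate(fractions):
        isos.append(
            generate_mixture_isotherm(
                p1, p2, x2, excess, grid, noise_sigma, int(seeds[2 + i])
            )
        )
    return [extract_compression_branch(iso) for iso in isos]


@pytest.fixture
def study_builder(grid, lipid, compound):
    def build(excess=ExcessParams(), noise_sigma=0.0, seed=0, fractions=STUDY_FRACTIONS):
        return build_study(lipid, compound, excess, grid, noise_sigma, seed, fractions)

    return build
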