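import numpy as np
import pytest

from idopspm import (
    GrowthParams,
    LengthGrid,
    MortalityParams,
    ReproductionParams,
    SexParams,
    SimulationConfig,
    SpeciesParams,
    load_predation_defaults,
    load_table3,
    npgr,
)

NPGR_CFG = SimulationConfig(t_end=400.0)


def make_species(
    name="test",
    variant="G2",
    rho=0.088,
    l_max=16.8,
    mu=6.4e-4,
    f_max=21.0,
    l_r=16.3,
    sigma_r=0.39,
    **extra,
):
    """Single-sex-symmetric species parameter set for solver tests."""
    growth = GrowthParams(variant=variant, rho=rho, l_max=l_max, **extra)
    sex = SexParams(growth=growth, mortality=MortalityParams(mu=mu))
    rep = ReproductionParams(f_max=f_max, l_r=l_r, sigma_r=sigma_r)
    return SpeciesParams(species=name, female=sex, male=sex, reproduction=rep)


@pytest.fixture(scope="session")
def grid():
    return LengthGrid()


@pytest.fixture(scope="session")
def coarse_grid():
    return LengthGrid(l_upper=31.0, n_cells=124)


@pytest.fixture(scope="session")
def pp():
    return load_predation_defaults()


@pytest.fixture(scope="session")
def ref_params():
    return load_table3("reference")


@pytest.fixture(scope="session")
def tides_params():
    return load_table3("tides")


@pytest.fixture(scope="session")
def treatment_npgr(pp):
    """No-predation NPGR fits for both treatments (shared, ~2 s)."""
    return {
        tr: npgr(load_table3(tr), pp, cfg=NPGR_CFG) for tr in ("reference", "tides")
    }


@pytest.fixture(scope="session")
def granulosa_ref_table(ref_params):
    from idopspm import SynthConfig, generate_rearing_experiment

    return generate_rearing_experiment(
        SynthConfig(truth=ref_params["granulosa"], rng_seed=7)
    )
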