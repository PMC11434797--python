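import pytest

from granutab.datasets import (DEFAULT_GEOMETRY, NoiseSpec, generate_campaign,
                               reference_parameters, table1_batches)
from granutab.fitting import CampaignDataset
from granutab.roms import CoupledROM


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def ref():
    return reference_parameters()


@pytest.fixture(scope="session")
def batches():
    return table1_batches()


@pytest.fixture(scope="session")
def noiseless_dataset(batches, geom):
    """One tablet per condition, zero noise: the ROM chain evaluated
    exactly at the 24 reference conditions."""
    camp = generate_campaign(noise=NoiseSpec(0.0, 0.0, 0.0, 0.0),
                             tablets_per_condition=1, seed=3)
    return CampaignDataset(camp.data, batches, geom)


@pytest.fixture(scope="session")
def noisy_dataset(batches, geom):
    """The reference campaign size: 24 conditions x 100 tablets at the
    default noise levels."""
    camp = generate_campaign(tablets_per_condition=100, seed=11)
    return CampaignDataset(camp.data, batches, geom)


def max_surface_error_pct(cqa, result, ref, batches, geom):
    """Worst relative error (percent) of the fitted coupled-parameter
    surfaces against the generating ones, over the six granule batches."""
    rom_true = ref.rom(cqa, geom)
    kwargs = dict(cqa=cqa, geom=geom, surface1=result.surface1,
                  surface2=result.surface2, r_x=result.r_x, r_y=result.r_y,
                  constant=result.constant)
    if cqa == "strength":
        kwargs["packing"] = ref.weight
    rom_fit = CoupledROM(**kwargs)
    errs = []
    for b in batches:
        xt1, xt2 = rom_true.xi(b)
        xf1, xf2 = rom_fit.xi(b)
        errs += [abs(xf1 - xt1) / abs(xt1), abs(xf2 - xt2) / abs(xt2)]
    return 100.0 * max(errs)
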