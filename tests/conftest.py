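import numpy as np
import pytest

import pyrofrag as pf


@pytest.fixture(scope="session")
def small_region():
    return pf.ReferenceRegion("r", 0, 6000, pf.synthetic_reference(6000, seed=3))


@pytest.fixture(scope="session")
def small_panel(small_region):
    return pf.AmpliconPanel(
        small_region,
        (pf.Amplicon("A", 0, 3500), pf.Amplicon("B", 3400, 6000)))


def single_sample_config(panel, **overrides):
    """One nebulization sample over the given panel."""
    defaults = dict(
        panel=panel,
        mids=(pf.MIDTag("S1", "CACTAATTAC"),),
        methods={"S1": pf.NEBULIZATION},
        mid_corrupt_prob=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return pf.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def single_sample_config_factory():
    return single_sample_config


@pytest.fixture(scope="session")
def default_sim_reads():
    """~10k reads from the default panel, one sample, default error model."""
    cfg = single_sample_config(pf.default_panel(), molecules_per_amplicon=300,
                               seed=17)
    return pf.simulate_run(cfg).reads


@pytest.fixture(scope="session")
def tiny_pipeline_config(small_panel):
    region = small_panel.region
    alt = "A" if region.sequence[1500] != "A" else "C"
    return pf.SimulationConfig(panel=small_panel, molecules_per_amplicon=8,
                               seed=11, het_snps=((1500, alt),))
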