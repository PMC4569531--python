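import numpy as np
import pandas as pd
import pytest

from tallstand import (
    Census,
    PlotRecord,
    SpeciesRecord,
    StemRecord,
    SyntheticConfig,
    generate_network,
    small_config,
)


def make_stem(tag, plot="P1", species="Euc A", dbh=30.0, **kw):
    return StemRecord(stem_tag=tag, plot_id=plot, species=species, dbh=dbh, **kw)


@pytest.fixture
def tiny_census():
    """Two 1-ha plots, four species, a dead stem and measured heights."""
    plots = [
        PlotRecord("P1", "R1", mat=12.0, map=1400.0, pan_evap=1000.0, census_date="2013-01-01"),
        PlotRecord("P2", "R1", mat=13.0, map=1300.0, pan_evap=1100.0, census_date="2013-01-01"),
    ]
    species = [
        SpeciesRecord("Euc A", "Euc", True),
        SpeciesRecord("Euc B", "Euc", True),
        SpeciesRecord("Scl A", "Scl", False),
        SpeciesRecord("RF A", "RF", False),
    ]
    stems = [
        make_stem("T001", "P1", "Euc A", 80.0, canopy_position="dominant",
                  growth_stage="mature", height=45.0),
        make_stem("T002", "P1", "Euc A", 65.0, canopy_position="co-dominant",
                  growth_stage="mature", height=55.0),
        make_stem("T003", "P1", "Scl A", 15.0, canopy_position="suppressed",
                  growth_stage="regenerating", height=14.0),
        make_stem("T004", "P1", "RF A", 12.0, canopy_position="suppressed",
                  growth_stage="regenerating"),
        make_stem("T005", "P1", "Scl A", 20.0, alive=False, mortality_code="SD",
                  canopy_position="none", growth_stage="none"),
        make_stem("T006", "P2", "Euc B", 70.0, canopy_position="dominant",
                  growth_stage="mature", height=50.0),
        make_stem("T007", "P2", "Scl A", 25.0, canopy_position="suppressed",
                  growth_stage="regrowth"),
    ]
    return Census.from_records(plots, stems, species)


@pytest.fixture(scope="session")
def synth_small():
    """A small deterministic synthetic network shared across tests."""
    census, manifest = generate_network(small_config(n_regions=3, plots_per_region=2, seed=1))
    return census, manifest


@pytest.fixture(scope="session")
def synth_default():
    """The full 48-plot default network (seed 1)."""
    census, manifest = generate_network(SyntheticConfig(seed=1))
    return census, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
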