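import numpy as np
import pandas as pd
import pytest

from overyield import (
    accumulate_annual,
    effects_table,
    scenario_presets,
    simulate,
    validate_harvest_frame,
)


def run_study(config, seed):
    """Full synthetic study: simulate -> validate -> accumulate -> effects."""
    harvests = simulate(config, seed)
    annual = accumulate_annual(validate_harvest_frame(harvests))
    return effects_table(annual)


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def null_study(presets):
    return run_study(presets["null"], 101)


@pytest.fixture(scope="session")
def facilitation_study(presets):
    return run_study(presets["population-facilitation"], 202)


def make_block_annual(
    *,
    clover_pure=8.0,
    grass_pure=10.0,
    chicory_pure=7.0,
    tl=(2.4, 5.2),
    site="R",
    block="B1",
    population="T1",
    year=1,
):
    """A minimal one-block annual table: three pure stands + one TL mixture."""
    rows = [
        dict(site=site, block=block, plot="p1", composition="pure_clover",
             population=population, n_level="N0", replicate_id=1, year=year,
             yield_clover=clover_pure, yield_grass=0.0, yield_chicory=0.0,
             yield_nonsown=0.0, total_sown_yield=clover_pure),
        dict(site=site, block=block, plot="p2", composition="pure_grass",
             population="", n_level="N0", replicate_id=1, year=year,
             yield_clover=0.0, yield_grass=grass_pure, yield_chicory=0.0,
             yield_nonsown=0.0, total_sown_yield=grass_pure),
        dict(site=site, block=block, plot="p3", composition="pure_chicory",
             population="", n_level="N0", replicate_id=1, year=year,
             yield_clover=0.0, yield_grass=0.0, yield_chicory=chicory_pure,
             yield_nonsown=0.0, total_sown_yield=chicory_pure),
        dict(site=site, block=block, plot="p4", composition="TL",
             population=population, n_level="N0", replicate_id=1, year=year,
             yield_clover=tl[0], yield_grass=tl[1], yield_chicory=0.0,
             yield_nonsown=0.0, total_sown_yield=sum(tl)),
    ]
    return pd.DataFrame(rows)
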