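import dataclasses

import numpy as np
import pytest

from igevar.scenarios import GeneticParams, ScenarioSpec


@pytest.fixture
def default_params() -> GeneticParams:
    return GeneticParams()


@pytest.fixture
def tiny_var_spec() -> ScenarioSpec:
    """A small competition scenario for fast variability-pipeline tests."""
    return ScenarioSpec(
        scenario_id=1,
        label="competition",
        params=GeneticParams(),
        purpose="variability",
        n_sires=20,
        n_dams_per_sire=5,
        n_offspring_per_dam=10,
    )


def make_spec(purpose="variability", n_sires=20, n_dams_per_sire=5,
              n_offspring_per_dam=10, **param_overrides) -> ScenarioSpec:
    params = dataclasses.replace(GeneticParams(), **param_overrides)
    label = {True: "competition", False: "cooperation"}.get(
        params.b_bar < 0, "neutral"
    ) if params.b_bar != 0 else "neutral"
    return ScenarioSpec(
        scenario_id=0,
        label=label,
        params=params,
        purpose=purpose,
        n_sires=n_sires,
        n_dams_per_sire=n_dams_per_sire,
        n_offspring_per_dam=n_offspring_per_dam,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220308)
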