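from __future__ import annotations

import numpy as np
import pytest

from alfwalk.classify import PipelineConfig, run_pipeline
from alfwalk.simulate import ZERO_ERRORS, derive_seeds, make_demo_scenario, simulate_run

SCENARIO_SEED, RUN_SEED = derive_seeds(7, 2)


def random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def scenario():
    """The bundled four-component study (97/1/1/1 mixture, model UGMO)."""
    return make_demo_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def zero_error_run(scenario):
    """A deterministic zero-error run of the full workflow with provenance."""
    reads, provenance = simulate_run(
        scenario.refs,
        scenario.mixture,
        scenario.primers,
        error_model=ZERO_ERRORS,
        n_reads=411,
        stop_prob=0.0,
        seed=RUN_SEED,
    )
    report = run_pipeline(reads, scenario.dbs, PipelineConfig(seed=7), scenario.primers)
    return reads, provenance, report
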