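import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stressclock import simulate as sim
from stressclock.datatypes import (
    ClockModel,
    IntervalSet,
    MethylationMatrix,
    PhenotypeTable,
    ProbeManifest,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast simulation configuration for unit tests."""
    return sim.SimulationConfig(
        n_samples=60, n_clock_probes=10, n_background_probes=200, n_dex_pairs=30, seed=0
    )


@pytest.fixture(scope="session")
def toy(small_config):
    return sim.generate_toy_clock(small_config, seed=11)


@pytest.fixture(scope="session")
def manifest(small_config):
    return sim.generate_manifest(small_config, seed=12)


@pytest.fixture(scope="session")
def cohort(toy, small_config, manifest):
    return sim.generate_cohort(toy, small_config, seed=13, manifest=manifest)


@pytest.fixture()
def tiny_matrix():
    betas = pd.DataFrame(
        [[0.1, 0.5, 0.9], [0.2, 0.4, 0.8]],
        index=["s1", "s2"],
        columns=["cg1", "cg2", "cg3"],
    )
    return MethylationMatrix(betas)


@pytest.fixture()
def hand_clock():
    """Two-probe clock used for hand-arithmetic prediction checks."""
    return ClockModel(intercept=0.5, weights=pd.Series({"cg1": 1.0, "cg2": -0.5}))


@pytest.fixture()
def simple_manifest():
    frame = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [150, 201, 251, 100],
            "on_21k": [True, True, False, False],
            "on_450k": [True, True, True, True],
            "is_sex_chrom": [False, False, False, False],
        },
        index=pd.Index(["cgA", "cgB", "cgC", "cgD"], name="probe_id"),
    )
    return ProbeManifest(frame)


@pytest.fixture()
def one_peak():
    return IntervalSet.from_records([("chr1", 100, 200)])
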