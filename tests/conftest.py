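import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crossheart as ch

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced two-species design for fast unit tests: 300 orthologs,
    four size-20 modules, two responsive only in species A."""
    modules = (
        ch.ModuleSpec("resp_1", 20, frozenset({"A"})),
        ch.ModuleSpec("resp_2", 20, frozenset({"A"})),
        ch.ModuleSpec("flat_1", 20),
        ch.ModuleSpec("flat_2", 20),
    )
    return ch.SimConfig(n_orthologs=300, modules=modules, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return ch.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One full default pipeline run (reference design, seed 1), shared by
    every test that only reads its outputs."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run1"
    ch.run_pipeline({"outdir": str(outdir), "seed": 1})
    return outdir


def read_output(outdir, name):
    return pd.read_csv(outdir / name, sep="\t", comment="#", index_col=0)


@pytest.fixture
def toy_normalized():
    """4 genes x 4 samples with metadata, for fold-change/PCA unit tests."""
    samples = pd.DataFrame(
        {
            "species": ["A", "A", "B", "B"],
            "condition": ["untouched", "cryoinjured", "untouched", "cryoinjured"],
            "time_hours": [0.0, 6.0, 0.0, 6.0],
        },
        index=pd.Index(["a0", "a6", "b0", "b6"], name="sample_id"),
    )
    normalized = pd.DataFrame(
        {
            "a0": [7.0, 10.0, 0.0, 5.0],
            "a6": [31.0, 10.0, 15.0, 5.0],
            "b0": [8.0, 20.0, 3.0, 5.0],
            "b6": [8.0, 5.0, 3.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return normalized, samples
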