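import logging

import pytest

import uvpdfy as u
from uvpdfy.pipeline import PipelineParams, analyze_experiment

logging.getLogger("uvpdfy").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def syn():
    return u.alpha_synuclein()


@pytest.fixture(scope="session")
def gg():
    return u.ProteinSequence("GG", "GG")


@pytest.fixture(scope="session")
def syn_db(syn):
    return u.build_fragment_database(syn, max_zinc=2)


@pytest.fixture(scope="session")
def intermediate_run():
    """One full simulate->analyze round of the intermediate conformer preset,
    shared across tests (seed fixed)."""
    cfg = u.make_conformer_presets(seed=0)["intermediate"]
    sim = u.simulate_experiment(cfg)
    res = analyze_experiment(
        sim.features, sim.precursor, cfg.sequence, PipelineParams(max_zinc=cfg.max_zinc)
    )
    return cfg, sim, res
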