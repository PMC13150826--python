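"""The synthetic-experiment generator: determinism, preset designs, and
exact noiseless round trips through the full analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import uvpdfy as u
from uvpdfy.pipeline import PipelineParams, analyze_experiment
from uvpdfy.simulate import PRESET_NAMES, make_conformer_presets


def test_same_seed_reproduces_identical_tables():
    cfg = make_conformer_presets(3)["low-charge"]
    s1 = u.simulate_experiment(cfg)
    s2 = u.simulate_experiment(dataclasses.replace(cfg))
    for key in s1.features:
        pd.testing.assert_frame_equal(s1.features[key], s2.features[key])
    for cond in s1.precursor:
        pd.testing.assert_frame_equal(s1.precursor[cond], s2.precursor[cond])


def test_different_seeds_differ():
    a = u.simulate_experiment(make_conformer_presets(0)["intermediate"])
    b = u.simulate_experiment(make_conformer_presets(1)["intermediate"])
    assert not a.features[("apo", 1)].equals(b.features[("apo", 1)])


def test_preset_designs():
    presets = make_conformer_presets(0)
    assert set(presets) == set(PRESET_NAMES)
    for cfg in presets.values():
        assert sum(c.weight for c in cfg.conformers) == pytest.approx(1.0)
        for c in cfg.conformers:
            assert sum(c.zinc_profile) == pytest.approx(1.0)
    inter = presets["intermediate"].conformers[1].zinc_profile
    assert int(np.argmax(inter)) == 1  # intermediate conformer binds one zinc
    high = presets["high-charge"].conformers[2].zinc_profile
    assert high[2] > 0 and int(np.argmax(high)) == 2  # two zincs dominate
    low = presets["low-charge"].conformers[0].zinc_profile
    assert int(np.argmax(low)) == 3  # low-charge conformer binds most


def test_planted_coverage_counts():
    presets = make_conformer_presets(5)
    expect = {"low-charge": 119, "intermediate": 134, "high-charge": 130}
    for name, cfg in presets.items():
        assert len(set(cfg.covered_sites)) == expect[name]
        assert u.simulate_experiment(cfg).ground_truth.coverage_pct == pytest.approx(
            round(100 * expect[name] / 140, 2)
        )


def test_low_charge_nterm_holo_confined_to_c_terminal_tail():
    cfg = make_conformer_presets(2)["low-charge"]
    sim = u.simulate_experiment(cfg)
    n_sites = sim.ground_truth.holo_sites["N"]
    assert len(n_sites) == 6
    assert all(120 <= s <= 139 for s in n_sites)
    c_sites = sim.ground_truth.holo_sites["C"]
    assert len(c_sites) == 31 and all(1 <= s <= 50 for s in c_sites)


def test_invalid_configs_are_rejected():
    cfg = make_conformer_presets(0)["intermediate"]
    bad = dataclasses.replace(cfg, detection_prob=1.5)
    with pytest.raises(ValueError, match="detection_prob"):
        u.simulate_experiment(bad)
    bad = dataclasses.replace(cfg, covered_sites=(0, 200))
    with pytest.raises(ValueError, match="covered_sites"):
        bad.validate()
    bad = dataclasses.replace(cfg, fragment_zinc_count=9)
    with pytest.raises(ValueError, match="zinc"):
        bad.validate()


def test_noiseless_round_trip_is_exact():
    cfg = make_conformer_presets(0)["intermediate"]
    quiet = dataclasses.replace(
        cfg, noise_sigma=0.0, detection_prob=1.0, precursor_noise_sigma=0.0
    )
    sim = u.simulate_experiment(quiet)
    res = analyze_experiment(
        sim.features, sim.precursor, cfg.sequence, PipelineParams(max_zinc=cfg.max_zinc)
    )
    gt = sim.ground_truth
    for cond, table in (("apo", res.fy_results.model.apo), ("holo", res.fy_results.model.holo)):
        truth = gt.apo_fy if cond == "apo" else gt.holo_fy
        for site in table.index:
            for rep in table.columns:
                assert table.loc[site, rep] == pytest.approx(truth.get(site, 0.0), abs=1e-6)
    assert res.holo_counts == gt.holo_counts
    np.testing.assert_allclose(res.cds["holo"].centers, [7, 10, 13], atol=1e-3)
    np.testing.assert_allclose(res.cds["holo"].fractions, [0.40, 0.35, 0.25], atol=1e-6)
    # at charge 10 the zinc profile is the weight-and-Gaussian blend of all
    # three conformers' stoichiometries (neighbouring components contribute
    # their tails), which the noiseless extraction reproduces exactly
    blend = np.zeros(cfg.max_zinc + 1)
    for c in cfg.conformers:
        g = c.weight * np.exp(-((10 - c.center) ** 2) / (2 * c.sigma**2))
        blend += g * np.array(c.zinc_profile)
    blend /= blend.sum()
    zp = res.conformers["holo"]["zinc_profiles"][10]
    np.testing.assert_allclose(zp, blend, atol=1e-9)


def test_holo_species_only_in_zinc_condition():
    cfg = make_conformer_presets(1)["low-charge"]
    sim = u.simulate_experiment(cfg)
    db = u.build_fragment_database(cfg.sequence, max_zinc=cfg.max_zinc, adduct=cfg.adduct)
    apo_masses = sim.features[("apo", 1)]["mass"].to_numpy()
    # every apo-condition mass matches a zinc-free species exactly
    zinc_free = np.sort([sp.mass for sp in db.species if sp.zinc_count == 0])
    idx = np.searchsorted(zinc_free, apo_masses)
    idx = np.clip(idx, 0, len(zinc_free) - 1)
    near = np.minimum(
        np.abs(zinc_free[idx] - apo_masses),
        np.abs(zinc_free[np.maximum(idx - 1, 0)] - apo_masses),
    )
    assert near.max() < 1e-6
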