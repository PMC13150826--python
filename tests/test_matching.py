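"""Tolerance matching against a brute-force all-pairs oracle, ambiguity
resolution rules, and the scan-count / envelope-correlation filters."""

import numpy as np
import pytest

import uvpdfy as u
from uvpdfy.matching import (
    DeconvolutedFeature,
    FragmentMatch,
    aggregate_evidence,
    match_scan,
    resolve_ambiguity,
)
from uvpdfy.sequence import SERIES_PRIORITY


def brute_force_assign(db, mass, tol=2e-6):
    """Independent quadratic matcher: scan every species, apply the same
    ordering contract (|rel err|, series priority, zinc, site)."""
    prio = {s: i for i, s in enumerate(SERIES_PRIORITY)}
    cands = []
    for idx in range(len(db.species)):
        theo = db.species[idx].mass
        err = (mass - theo) / theo
        if abs(err) <= tol:
            sp = db.species[idx]
            cands.append((abs(err), prio[sp.series], sp.zinc_count, sp.site, idx))
    if not cands:
        return None
    return min(cands)[4]


def _feat(mass, scan=1, inten=100.0, env=None):
    return DeconvolutedFeature(scan, mass, 1, inten, env)


def test_within_and_outside_tolerance(syn_db):
    theo = syn_db.masses[2500]
    inside = match_scan(syn_db, [_feat(theo * (1 + 1e-6))])
    outside = match_scan(syn_db, [_feat(theo * (1 + 3e-6))])
    assert len(inside) == 1 and inside[0].species is syn_db.species[2500]
    # 3 ppm off this species: either unmatched or matched to a different one
    assert all(m.species is not syn_db.species[2500] for m in outside)


def test_matches_brute_force_oracle_seeded_instances(syn_db):
    rng = np.random.default_rng(11)
    masses = syn_db.masses
    for _ in range(3):
        obs = np.concatenate([
            rng.choice(masses, 50) * (1 + rng.uniform(-3e-6, 3e-6, 50)),
            rng.uniform(200, 15000, 20),
        ])
        feats = [_feat(m) for m in obs]
        got = {id(m.feature): m.species for m in match_scan(syn_db, feats)}
        for f in feats:
            expect = brute_force_assign(syn_db, f.mass)
            if expect is None:
                assert id(f) not in got
            else:
                assert got[id(f)] is syn_db.species[expect]


def test_tightening_tolerance_never_adds_matches(syn_db):
    rng = np.random.default_rng(5)
    feats = [_feat(m) for m in rng.choice(syn_db.masses, 200) * (1 + rng.uniform(-3e-6, 3e-6, 200))]
    wide = {id(m.feature) for m in match_scan(syn_db, feats, tol=2e-6)}
    tight = {id(m.feature) for m in match_scan(syn_db, feats, tol=1e-6)}
    assert tight <= wide


def test_resolve_ambiguity_rules(syn_db):
    # equal error: higher envelope r wins
    idx, _, r, rej = resolve_ambiguity([(10, 1e-6, 0.80), (20, 1e-6, 0.95)], syn_db)
    assert idx == 20 and r == 0.95 and rej == [10]
    # single candidate returned unchanged
    idx, err, r, rej = resolve_ambiguity([(7, -5e-7, None)], syn_db)
    assert idx == 7 and rej == []
    with pytest.raises(ValueError):
        resolve_ambiguity([], syn_db)


def test_base_series_beats_satellite_on_ties(syn_db):
    by_kind = {}
    for i, sp in enumerate(syn_db.species):
        by_kind[(sp.series, sp.site, sp.zinc_count)] = i
    i_b = by_kind[("b", 50, 0)]
    i_a2 = by_kind[("a+2", 50, 0)]
    idx, *_ = resolve_ambiguity([(i_a2, 1e-6, None), (i_b, 1e-6, None)], syn_db)
    assert idx == i_b


def _matches_for_scans(syn_db, scans, r=None):
    sp_idx = 100
    theo = syn_db.masses[sp_idx]
    out = []
    for s in scans:
        m = FragmentMatch(_feat(theo, scan=s), syn_db.species[sp_idx], 0.0, r)
        out.append(m)
    return out


def test_scan_count_filter_16_of_20(syn_db):
    kept = aggregate_evidence(_matches_for_scans(syn_db, range(1, 17)))
    dropped = aggregate_evidence(_matches_for_scans(syn_db, range(1, 16)))
    assert kept["kept"].all() and kept["n_scans"].iloc[0] == 16
    assert not dropped["kept"].any() and dropped["n_scans"].iloc[0] == 15


def test_envelope_correlation_filter_at_0_7(syn_db):
    assert aggregate_evidence(_matches_for_scans(syn_db, range(1, 17), r=0.71))["kept"].all()
    assert not aggregate_evidence(_matches_for_scans(syn_db, range(1, 17), r=0.69))["kept"].any()


def test_charge_states_sum_within_scan(syn_db):
    sp = syn_db.species[100]
    theo = sp.mass
    matches = []
    for scan in range(1, 17):
        for inten in (40.0, 60.0):  # two charge states of one species
            matches.append(FragmentMatch(_feat(theo, scan=scan, inten=inten), sp, 0.0))
    ev = aggregate_evidence(matches)
    assert ev["median_intensity"].iloc[0] == pytest.approx(100.0)


def test_aggregation_idempotent_and_bounded(syn_db):
    matches = _matches_for_scans(syn_db, range(1, 21))
    ev1 = aggregate_evidence(matches)
    ev2 = aggregate_evidence(matches)
    assert ev1.equals(ev2)
    assert len(ev1) <= len({m.species for m in matches})
    with pytest.raises(ValueError):
        aggregate_evidence(matches, n_scans_total=0)


def test_feature_validation():
    with pytest.raises(ValueError):
        DeconvolutedFeature(1, -5.0, 1, 1.0)
    with pytest.raises(ValueError):
        DeconvolutedFeature(1, 100.0, 1, -1.0)
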