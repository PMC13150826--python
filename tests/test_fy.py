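"""Median normalization, per-site fragment yields, coverage, and ΔFY
statistics."""

import numpy as np
import pandas as pd
import pytest

from uvpdfy.fy import (
    FragmentYieldModel,
    delta_fy,
    median_normalize,
    region_summary,
    sequence_coverage,
    site_fy,
)
from uvpdfy.sequence import RegionScheme


def _evidence(rows):
    """rows: (series, site, zinc, intensity[, kept])"""
    recs = []
    for r in rows:
        series, site, zinc, inten = r[:4]
        kept = r[4] if len(r) > 4 else True
        terminus = "N" if series[0] in "abc" else "C"
        recs.append((series, site, zinc, terminus, 0.0, 20, inten, np.nan, kept))
    df = pd.DataFrame(
        recs,
        columns=["series", "site", "zinc_count", "terminus", "mass", "n_scans",
                 "median_intensity", "mean_r", "kept"],
    ).set_index(["series", "site", "zinc_count"])
    return df


def test_median_normalization_equalizes_shared_medians():
    table = pd.DataFrame({"r1": [8.0, 10.0, 12.0], "r2": [16.0, 20.0, 24.0]})
    out = median_normalize(table)
    m1, m2 = out["r1"].median(), out["r2"].median()
    grand = np.median([10.0, 20.0])
    assert m1 == pytest.approx(grand) and m2 == pytest.approx(grand)


def test_median_normalization_identity_cases():
    equal = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [3.0, 2.0, 1.0]})
    pd.testing.assert_frame_equal(median_normalize(equal), equal)
    single = pd.DataFrame({"r1": [5.0, 7.0, 9.0]})
    out = median_normalize(single)
    assert out["r1"].median() == pytest.approx(single["r1"].median())


def test_median_normalization_all_zero_replicate_errors():
    with pytest.raises(ValueError, match="r2"):
        median_normalize(pd.DataFrame({"r1": [1.0, 2.0], "r2": [0.0, 0.0]}))


def test_fy_zero_for_non_fy_series():
    ev = _evidence([("b", 3, 0, 10.0), ("y", 7, 0, 5.0)])
    fy = site_fy(ev, L=10)
    assert fy.eq(0).all()


def test_fy_single_a_ion_is_100():
    fy = site_fy(_evidence([("a", 5, 0, 42.0)]), L=10)
    assert fy.loc[5] == pytest.approx(100.0)
    assert fy.drop(5).eq(0).all()


def test_fy_mixed_series_arithmetic():
    ev = _evidence([("a", 3, 0, 1.0), ("x", 3, 0, 1.0), ("b", 4, 0, 2.0)])
    fy = site_fy(ev, L=10)
    assert fy.loc[3] == pytest.approx(50.0)
    assert fy.loc[4] == 0.0


def test_fy_pools_holo_and_apo_variants():
    ev = _evidence([("a", 3, 0, 1.0), ("a", 3, 1, 1.0), ("b", 5, 0, 2.0)])
    fy = site_fy(ev, L=10)
    assert fy.loc[3] == pytest.approx(50.0)


def test_fy_conservation():
    ev = _evidence([("a", 1, 0, 3.0), ("x", 2, 0, 2.0), ("b", 3, 0, 4.0), ("c", 4, 0, 1.0)])
    fy = site_fy(ev, L=10)
    excluded = 100.0 * (4.0 + 1.0) / 10.0
    assert fy.sum() + excluded == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        site_fy(_evidence([("a", 1, 0, 5.0, False)]), L=10)


def test_coverage_values():
    rows = [("b", s, 0, 1.0) for s in range(1, 135)]
    assert sequence_coverage(_evidence(rows), L=140) == 95.71
    assert sequence_coverage(_evidence([]), L=140) == 0.0
    rows = [("b", s, 0, 1.0) for s in range(1, 140)]
    assert sequence_coverage(_evidence(rows), L=140) == 99.29


def test_coverage_monotone_in_evidence():
    rows = [("b", s, 0, 1.0) for s in range(1, 50)]
    c1 = sequence_coverage(_evidence(rows), L=140)
    c2 = sequence_coverage(_evidence(rows + [("y", 60, 0, 1.0)]), L=140)
    assert c2 >= c1


def _tables(apo_rows, holo_rows):
    apo = pd.DataFrame(apo_rows).T
    holo = pd.DataFrame(holo_rows).T
    apo.index.name = holo.index.name = "site"
    return apo, holo


def test_delta_fy_identical_replicates_not_significant():
    apo, holo = _tables({5: [2.0, 2.1, 1.9]}, {5: [2.0, 2.1, 1.9]})
    d = delta_fy(apo, holo)
    assert d.loc[5, "delta_fy"] == pytest.approx(0.0)
    assert not d.loc[5, "significant"]


def test_delta_fy_planted_shift_recovered():
    rng = np.random.default_rng(3)
    apo, holo = _tables(
        {5: 4.0 + 0.05 * rng.standard_normal(3)},
        {5: 2.0 + 0.05 * rng.standard_normal(3)},
    )
    d = delta_fy(apo, holo)
    assert d.loc[5, "significant"]
    assert d.loc[5, "delta_fy"] == pytest.approx(-2.0, abs=0.2)


def test_delta_fy_site_missing_from_one_condition():
    rng = np.random.default_rng(4)
    apo, holo = _tables({5: 5.0 + 0.01 * rng.standard_normal(3)}, {7: [1.0, 1.0, 1.1]})
    d = delta_fy(apo, holo)
    assert d.loc[5, "delta_fy"] == pytest.approx(-5.0, abs=0.1)
    assert d.loc[5, "significant"]


def test_delta_fy_zero_variance_handling():
    apo, holo = _tables({1: [2.0, 2.0, 2.0]}, {1: [1.0, 1.0, 1.0]})
    d = delta_fy(apo, holo)
    assert d.loc[1, "p_value"] == 0.0 and d.loc[1, "significant"]
    apo, holo = _tables({1: [2.0, 2.0, 2.0]}, {1: [2.0, 2.0, 2.0]})
    assert delta_fy(apo, holo).loc[1, "p_value"] == 1.0


def test_delta_fy_requires_two_replicates():
    apo, holo = _tables({5: [1.0]}, {5: [1.0, 2.0]})
    with pytest.raises(ValueError):
        delta_fy(apo, holo)
    with pytest.raises(ValueError):
        delta_fy(pd.DataFrame({0: {5: 1.0}, 1: {5: 2.0}}),
                 pd.DataFrame({0: {5: 1.0}, 1: {5: 2.0}}), t_test="median")


def test_region_summary_arithmetic():
    regions = RegionScheme.synuclein_default()
    delta = pd.DataFrame(
        {"delta_fy": [-2.0, -1.0, -3.0, 9.9], "significant": [True, True, True, False]},
        index=pd.Index([10, 70, 120, 30], name="site"),
    )
    rs = region_summary(delta, regions)
    assert rs["overall"] == pytest.approx(-2.0)
    assert rs["Nterm"] == pytest.approx(-2.0)
    assert rs["NAC"] == pytest.approx(-1.0)
    assert rs["Cterm"] == pytest.approx(-3.0)
    assert rs["n_significant"] == 3


def test_region_summary_empty_regions_are_none():
    regions = RegionScheme.synuclein_default()
    delta = pd.DataFrame(
        {"delta_fy": [-1.0], "significant": [True]}, index=pd.Index([70], name="site")
    )
    rs = region_summary(delta, regions)
    assert rs["NAC"] == pytest.approx(-1.0)
    assert rs["Nterm"] is None and rs["Cterm"] is None
    none_rs = region_summary(delta[delta["delta_fy"] > 0], regions)
    assert none_rs["overall"] is None


def test_model_results_summary_and_flow():
    rng = np.random.default_rng(0)
    apo = pd.DataFrame({r: {s: 3.0 + 0.03 * rng.standard_normal() for s in range(1, 20)}
                        for r in range(3)})
    holo = apo - 1.0 + 0.03 * rng.standard_normal(apo.shape)
    model = FragmentYieldModel(apo, holo, RegionScheme(((("Nterm"), 1, 10), ("Cterm", 11, 20))))
    res = model.fit()
    assert set(res.significant_sites) == set(range(1, 20))
    assert "significant" in res.summary()
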