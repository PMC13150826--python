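"""Ion-series mass arithmetic, the fragment database, and sequence/region
containers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import uvpdfy as u
from uvpdfy.sequence import (
    ALL_SERIES,
    ION_SERIES,
    N_TERMINAL_SERIES,
    C_TERMINAL_SERIES,
    RegionScheme,
    ZN_BARE,
    ZN_MINUS_2H,
    fragment_neutral_mass,
    species_composition,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_twelve_series_partition():
    assert len(ION_SERIES) == 12
    assert set(N_TERMINAL_SERIES) == {"a", "a+1", "a+2", "b", "c"}
    assert set(C_TERMINAL_SERIES) == {"x", "x+1", "y", "y-1", "y-2", "z", "z+1"}


def test_satellite_offsets_are_hydrogen_multiples():
    for name, ser in ION_SERIES.items():
        base = ION_SERIES[name[0]]
        shift = ser.offset_mass() - base.offset_mass()
        k = round(shift / 1.007825)
        assert shift == pytest.approx(k * 1.0078250319, abs=1e-9)


def test_b_and_y_of_glycylglycine(gg):
    assert fragment_neutral_mass(gg, "b", 1) == pytest.approx(57.021464, abs=1e-5)
    assert fragment_neutral_mass(gg, "y", 1) == pytest.approx(75.032029, abs=1e-5)


def test_a_is_b_minus_co(syn):
    for site in (1, 70, 139):
        diff = fragment_neutral_mass(syn, "b", site) - fragment_neutral_mass(syn, "a", site)
        assert diff == pytest.approx(27.994915, abs=1e-6)


def test_complementarity_all_sites(syn):
    M = syn.neutral_mass()
    for i in range(1, syn.length):
        s = fragment_neutral_mass(syn, "b", i) + fragment_neutral_mass(syn, "y", i)
        assert abs(s - M) < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=2, max_size=30))
def test_complementarity_random_sequences(residues):
    seq = u.ProteinSequence("t", residues)
    M = seq.neutral_mass()
    for i in range(1, seq.length):
        assert fragment_neutral_mass(seq, "b", i) + fragment_neutral_mass(seq, "y", i) == pytest.approx(M, abs=1e-6)


def test_zinc_adduct_conventions(gg):
    m0 = fragment_neutral_mass(gg, "b", 1, 0)
    assert fragment_neutral_mass(gg, "b", 1, 1, ZN_MINUS_2H) - m0 == pytest.approx(61.913492, abs=1e-5)
    assert fragment_neutral_mass(gg, "b", 1, 1, ZN_BARE) - m0 == pytest.approx(63.929142, abs=1e-5)


def test_fragment_mass_errors(gg):
    with pytest.raises(KeyError):
        fragment_neutral_mass(gg, "w", 1)
    with pytest.raises(IndexError):
        fragment_neutral_mass(gg, "b", 2)
    with pytest.raises(ValueError):
        fragment_neutral_mass(gg, "b", 1, -1)


def test_database_counts(syn, gg):
    assert len(u.build_fragment_database(syn, max_zinc=0)) == 139 * 12
    assert len(u.build_fragment_database(syn, max_zinc=2)) == 3 * 139 * 12
    assert len(u.build_fragment_database(gg, series_set=("b", "y"), max_zinc=0)) == 2


def test_database_config_errors(syn):
    with pytest.raises(ValueError):
        u.build_fragment_database(syn, series_set=())
    with pytest.raises(KeyError):
        u.build_fragment_database(syn, series_set=("b", "nope"))


def test_database_sorted_and_species_mass_consistent(syn_db):
    assert np.all(np.diff(syn_db.masses) >= 0)
    # composition-derived mass agrees with the tabulated mass
    for idx in (0, 500, 2000, len(syn_db) - 1):
        sp = syn_db.species[idx]
        comp = species_composition(syn_db.sequence, sp, syn_db.adduct)
        assert comp.mass() == pytest.approx(sp.mass, abs=1e-6)


def test_masses_increase_with_fragment_length(syn):
    db = u.build_fragment_database(syn, series_set=("b",), max_zinc=0)
    by_site = sorted(db.species, key=lambda s: s.site)
    masses = [s.mass for s in by_site]
    assert all(m2 > m1 for m1, m2 in zip(masses, masses[1:]))
    assert all(m > 0 for m in masses)


def test_query_tolerance_window(syn_db):
    target = syn_db.masses[1000]
    hits = syn_db.query(target * (1 + 1e-6), tol=2e-6)
    assert 1000 in hits
    assert 1000 not in syn_db.query(target * (1 + 3e-6), tol=2e-6)


def test_region_scheme_labels_and_invariants():
    rs = RegionScheme.synuclein_default()
    assert rs.label(1) == "Nterm" and rs.label(60) == "Nterm"
    assert rs.label(61) == "NAC" and rs.label(95) == "NAC"
    assert rs.label(96) == "Cterm" and rs.label(140) == "Cterm"
    with pytest.raises(ValueError):
        rs.label(141)
    with pytest.raises(ValueError):
        RegionScheme((("A", 1, 10), ("B", 12, 20)))


def test_bundled_sequence(syn):
    assert syn.length == 140
    assert syn.identifier == "P37840"
    assert syn.residues.startswith("MDVFMK") and syn.residues.endswith("YEPEA")


def test_sequence_validation():
    with pytest.raises(ValueError):
        u.ProteinSequence("bad", "AX")
    with pytest.raises(ValueError):
        u.ProteinSequence("short", "A")


def test_fasta_reader(tmp_path):
    p = tmp_path / "seq.fasta"
    p.write_text(">demo test\nMKV\nGG\n")
    seq = u.ProteinSequence.from_fasta(p)
    assert seq.residues == "MKVGG"
    assert seq.identifier == "demo"
    (tmp_path / "empty.fasta").write_text("\n")
    with pytest.raises(ValueError):
        u.ProteinSequence.from_fasta(tmp_path / "empty.fasta")
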