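"""Contact detection, polar classification, contact tables, SASA, burial."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrface import contacts as con
from tcrface import synthetic as syn
from tcrface.sasa import sasa_areas
from tcrface.structure import (
    AtomRecord,
    Chain,
    ChainRole,
    ComplexAnnotation,
    Residue,
    ResidueRef,
    StructureModel,
)


def _two_chain_model(coords_a, coords_b, res_name="ALA"):
    """One residue per atom, chains X (TCR alpha stand-in) and Y (peptide)."""
    def chain(cid, coords):
        residues = []
        for i, xyz in enumerate(coords):
            ref = ResidueRef(cid, i + 1, "", "A")
            residues.append(Residue(ref, res_name, [
                AtomRecord(name="CA", element="C", xyz=tuple(xyz))]))
        return Chain(cid, residues)
    s = StructureModel("pair", [chain("X", coords_a), chain("Y", coords_b)])
    ann = ComplexAnnotation(roles={"X": ChainRole.TCR_ALPHA,
                                   "Y": ChainRole.PEPTIDE})
    return s, ann


def _brute_force_pairs(coords_a, coords_b, cutoff):
    out = set()
    for i, a in enumerate(coords_a):
        for j, b in enumerate(coords_b):
            if np.linalg.norm(np.asarray(a) - np.asarray(b)) <= cutoff:
                out.add((i + 1, j + 1))
    return out


def test_single_pair_inside_cutoff():
    s, ann = _two_chain_model([(0, 0, 0)], [(3.8, 0, 0)])
    recs = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA}, {ChainRole.PEPTIDE})
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(3.8)
    assert recs[0].kind == "vdw"


def test_pair_just_outside_cutoff():
    s, ann = _two_chain_model([(0, 0, 0)], [(4.05, 0, 0)])
    recs = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA}, {ChainRole.PEPTIDE})
    assert recs == []


def test_boundary_distance_included():
    s, ann = _two_chain_model([(0, 0, 0)], [(4.0, 0, 0)])
    recs = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA}, {ChainRole.PEPTIDE})
    assert len(recs) == 1


def test_find_contacts_matches_brute_force(rng):
    """KD-tree detection equals the all-pairs scan on random 200-atom clouds."""
    for _ in range(10):
        xa = rng.uniform(0, 15, size=(100, 3))
        xb = rng.uniform(0, 15, size=(100, 3))
        s, ann = _two_chain_model(xa, xb)
        recs = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA},
                                 {ChainRole.PEPTIDE})
        got = {(r.atom_a[0].seq_num, r.atom_b[0].seq_num) for r in recs}
        assert got == _brute_force_pairs(xa, xb, 4.0)


def test_contact_symmetry_and_monotonicity(rng):
    xa = rng.uniform(0, 12, size=(60, 3))
    xb = rng.uniform(0, 12, size=(60, 3))
    s, ann = _two_chain_model(xa, xb)
    ab = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA}, {ChainRole.PEPTIDE})
    ba = con.find_contacts(s, ann, {ChainRole.PEPTIDE}, {ChainRole.TCR_ALPHA})
    pairs_ab = {(r.atom_a[0], r.atom_b[0]) for r in ab}
    pairs_ba = {(r.atom_b[0], r.atom_a[0]) for r in ba}
    assert pairs_ab == pairs_ba
    wide = con.find_contacts(s, ann, {ChainRole.TCR_ALPHA}, {ChainRole.PEPTIDE},
                             con.ContactParams(contact_cutoff=5.5))
    assert pairs_ab <= {(r.atom_a[0], r.atom_b[0]) for r in wide}


def test_disjoint_sides_required(fixture_complex):
    s, ann = fixture_complex
    with pytest.raises(ValueError, match="disjoint"):
        con.find_contacts(s, ann, {ChainRole.TCR_ALPHA},
                          {ChainRole.TCR_ALPHA, ChainRole.PEPTIDE})


# ---------------------------------------------------------------------------
# polar classification


def _polar_pair(res_a, atoms_a, res_b, atoms_b, sep):
    """Two single-residue chains whose named atoms sit ``sep`` apart."""
    ref_a = ResidueRef("X", 1, "", "X")
    ref_b = ResidueRef("Y", 1, "", "X")
    ra = Residue(ref_a, res_a, [
        AtomRecord(name=n, element=n[0], xyz=(i * 10.0, 0, 0))
        for i, n in enumerate(atoms_a)])
    rb = Residue(ref_b, res_b, [
        AtomRecord(name=n, element=n[0], xyz=(sep + i * 10.0, 0, 0))
        for i, n in enumerate(atoms_b)])
    s = StructureModel("polar", [Chain("X", [ra]), Chain("Y", [rb])])
    ann = ComplexAnnotation(roles={"X": ChainRole.TCR_BETA,
                                   "Y": ChainRole.PEPTIDE})
    recs = con.find_contacts(s, ann, {ChainRole.TCR_BETA}, {ChainRole.PEPTIDE})
    return con.classify_polar(recs, s), s


@pytest.mark.parametrize("res_a,atom_a,res_b,atom_b,sep,expect", [
    ("LYS", "NZ", "GLU", "OE1", 3.2, "saltbridge"),
    ("ARG", "NH1", "ASP", "OD2", 3.9, "saltbridge"),
    ("SER", "OG", "ALA", "O", 3.0, "hbond"),
    ("ALA", "N", "THR", "OG1", 3.4, "hbond"),
    ("ALA", "CB", "ALA", "CB", 3.9, "vdw"),
    ("SER", "OG", "ALA", "O", 3.8, "vdw"),   # beyond the 3.5 A donor-acceptor cutoff
])
def test_polar_classification(res_a, atom_a, res_b, atom_b, sep, expect):
    recs, _ = _polar_pair(res_a, [atom_a], res_b, [atom_b], sep)
    assert len(recs) == 1
    assert recs[0].kind == expect


def test_classification_partitions(fixture_complex):
    s, ann = fixture_complex
    recs = con.find_contacts(s, ann, con.TCR_ROLES, con.PMHC_ROLES)
    classified = con.classify_polar(recs, s)
    kinds = [r.kind for r in classified]
    assert len(classified) == len(recs)
    assert sum(kinds.count(k) for k in ("vdw", "hbond", "saltbridge")) == len(recs)


# ---------------------------------------------------------------------------
# contact table and percentages (printed-table worked examples)

Q61K_PEPTIDE = [4, 0, 0, 5, 7, 3, 4, 14]
Q61K_MHC = [46, 11, 0, 33, 0, 21, 0, 17]
Q61R_PEPTIDE = [5, 0, 0, 5, 8, 3, 3, 22]
Q61R_MHC = [43, 11, 0, 38, 0, 24, 0, 14]


def _table_from_counts(peptide, mhc):
    t = con.ContactTable()
    for target, counts in (("peptide", peptide), ("mhc", mhc)):
        t.counts[target] = dict(zip(con.LOOP_ORDER, counts))
        t.counts[target]["framework"] = 0
        t.totals[target] = sum(counts)
    return t


@pytest.mark.parametrize("pep,mhc,pep_pct,mhc_pct", [
    (Q61K_PEPTIDE, Q61K_MHC,
     [11, 0, 0, 14, 19, 8, 11, 38], [36, 9, 0, 26, 0, 16, 0, 13]),
    (Q61R_PEPTIDE, Q61R_MHC,
     [11, 0, 0, 11, 17, 7, 7, 48], [33, 8, 0, 29, 0, 18, 0, 11]),
])
def test_percent_rows_reproduce_published_tables(pep, mhc, pep_pct, mhc_pct):
    t = _table_from_counts(pep, mhc)
    assert t.percents("peptide") == pep_pct
    assert t.percents("mhc") == mhc_pct


def test_chain_shares():
    t = _table_from_counts(Q61K_PEPTIDE, Q61K_MHC)
    # 28 of 37 peptide contacts via the beta chain
    assert con.chain_share(t, "beta", "peptide") == 76
    # 90 of 128 MHC contacts via alpha: arithmetic gives 70.3 -> 70
    assert con.chain_share(t, "alpha", "mhc") == 70
    t2 = _table_from_counts([0, 0, 0, 0, 5, 0, 0, 0], [0] * 8)
    assert con.chain_share(t2, "beta", "peptide") == 100
    with pytest.raises(ZeroDivisionError):
        con.chain_share(t2, "alpha", "mhc")


def test_single_loop_is_100_percent():
    t = _table_from_counts([0, 0, 0, 5, 0, 0, 0, 0], [0] * 8)
    assert t.percents("peptide") == [0, 0, 0, 100, 0, 0, 0, 0]


@given(counts=st.lists(st.integers(min_value=0, max_value=200),
                       min_size=8, max_size=8).filter(lambda c: sum(c) > 0))
@settings(max_examples=100, deadline=None)
def test_percent_rounding_properties(counts):
    """Counts sum exactly; percents sum to 100 within one per nonzero loop."""
    t = _table_from_counts(counts, [1] * 8)
    pct = t.percents("peptide")
    assert sum(t.loop_counts("peptide")) == t.totals["peptide"]
    nonzero = sum(1 for c in counts if c > 0)
    assert abs(sum(pct) - 100) <= nonzero
    for c, p in zip(counts, pct):
        exact = 100 * c / sum(counts)
        assert abs(p - exact) <= 0.5 + 1e-9


def test_cdr_table_from_fixture_counts_all_contacts(fixture_complex):
    s, ann = fixture_complex
    recs = con.find_contacts(s, ann, con.TCR_ROLES, con.PMHC_ROLES)
    t = con.cdr_contact_table(recs, ann)
    assert t.totals["peptide"] + t.totals["mhc"] == len(recs)
    for target in ("peptide", "mhc"):
        assert sum(t.loop_counts(target)) + t.counts[target]["framework"] \
            == t.totals[target]
    # fixture loops are all CDR/HV4, so no framework contacts
    assert t.counts["peptide"]["framework"] == 0
    # CDR3a engages the N-terminal peptide half, CDR3b the C-terminal half
    assert t.counts["peptide"][(ChainRole.TCR_ALPHA, con.Loop.CDR3)] > 0
    assert t.counts["peptide"][(ChainRole.TCR_BETA, con.Loop.CDR3)] > 0


# ---------------------------------------------------------------------------
# SASA and burial


def test_isolated_atom_sasa_closed_form():
    # carbon r=1.7, probe 1.4: area = 4*pi*(3.1)^2
    areas = sasa_areas(np.array([[0.0, 0.0, 0.0]]), ["C"])
    expected = 4 * np.pi * 3.1**2
    assert areas[0] == pytest.approx(expected, rel=0.01)


def test_distant_atoms_additive():
    areas = sasa_areas(np.array([[0.0, 0, 0], [50.0, 0, 0]]), ["C", "O"])
    iso_c = sasa_areas(np.array([[0.0, 0, 0]]), ["C"])[0]
    iso_o = sasa_areas(np.array([[0.0, 0, 0]]), ["O"])[0]
    assert areas.sum() == pytest.approx(iso_c + iso_o, rel=1e-9)


def test_two_sphere_overlap_matches_spherical_cap():
    """Equal spheres distance d apart: each loses a cap of height h = R - d/2."""
    d = 3.0
    r_exp = 1.7 + 1.4  # expanded carbon radius
    areas = sasa_areas(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"],
                       n_points=5000)
    cap = 2 * np.pi * r_exp * (r_exp - d / 2.0)
    expected = 4 * np.pi * r_exp**2 - cap
    assert areas[0] == pytest.approx(expected, rel=0.01)
    assert areas[1] == pytest.approx(expected, rel=0.01)


def test_unknown_element_errors():
    with pytest.raises(KeyError, match="radius"):
        sasa_areas(np.array([[0.0, 0, 0]]), ["XX"])


def test_sasa_monotone_under_added_atoms(fixture_complex):
    s, _ = fixture_complex
    pep_alone = con.sasa(s, chain_ids=["C"])
    with_mhc = con.sasa(s, chain_ids=["A", "C"])
    n_pep = len(pep_alone)
    # peptide atoms come after MHC atoms in file order? chains ordered A,B,C..
    pep_within = with_mhc[-n_pep:]
    assert (pep_within <= pep_alone + 1e-9).all()


def test_peptide_burial_compositional(fixture_complex):
    """bsa equals the difference of the two independent SASA computations."""
    s, ann = fixture_complex
    rep = con.peptide_burial(s, ann)
    assert 0 <= rep.sasa_bound <= rep.sasa_free
    assert rep.bsa == pytest.approx(rep.sasa_free - rep.sasa_bound)
    assert rep.burial_fraction == pytest.approx(100 * rep.bsa / rep.sasa_free)
    assert rep.burial_fraction > 10  # the loops really bury peptide surface


def test_burial_zero_when_tcr_far():
    s, ann = syn.make_complex(syn.FixtureParams(
        crossing_deg=0, incident_deg=0, shift_A=0,
        tcr_height_A=80.0, contact_loops=False))
    rep = con.peptide_burial(s, ann)
    assert rep.burial_fraction == pytest.approx(0.0, abs=1e-9)


def test_sasa_cross_check_against_biotite(fixture_complex):
    """Independent SASA oracle: biotite's Shrake-Rupley on the same radii."""
    biotite_struc = pytest.importorskip("biotite.structure")
    import biotite.structure as bst
    s, _ = fixture_complex
    atoms = [(r, a) for r in s.residues(["C"]) for a in r.atoms]
    arr = bst.AtomArray(len(atoms))
    for i, (r, a) in enumerate(atoms):
        arr.coord[i] = a.xyz
        arr.chain_id[i] = r.ref.chain_id
        arr.res_id[i] = r.ref.seq_num
        arr.res_name[i] = r.res_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    from tcrface.sasa import VDW_RADII
    radii = np.array([VDW_RADII[a.element.upper()] for _, a in atoms])
    ours = con.sasa(s, chain_ids=["C"])
    theirs = bst.sasa(arr, probe_radius=1.4, point_number=1000,
                      vdw_radii=radii)
    assert ours.sum() == pytest.approx(theirs.sum(), rel=0.02)
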