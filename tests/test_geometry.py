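"""Superposition, groove frame, docking descriptors, RMSD profiling."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tcrface import geometry as geo
from tcrface import synthetic as syn
from tcrface.structure import ChainRole


# ---------------------------------------------------------------------------
# superposition


def test_superpose_identity(rng):
    x = rng.normal(size=(10, 3))
    res = geo.superpose(x, x)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(res.translation, 0.0, atol=1e-9)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_recovers_known_rotation(rng):
    x = rng.normal(size=(12, 3))
    r0 = Rotation.random(random_state=7).as_matrix()
    t0 = np.array([3.0, -2.0, 5.0])
    y = x @ r0.T + t0
    res = geo.superpose(x, y)
    np.testing.assert_allclose(res.rotation, r0, atol=1e-6)
    assert res.rmsd == pytest.approx(0.0, abs=1e-8)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)


def _numeric_min_rmsd(mobile, reference):
    """Brute-force oracle: minimize RMSD over rotation vector + translation."""
    def cost(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        fitted = mobile @ rot.T + p[3:]
        return np.sqrt(((fitted - reference) ** 2).sum() / len(mobile))
    best = np.inf
    for seed in range(8):
        x0 = np.concatenate([
            Rotation.random(random_state=seed).as_rotvec(),
            reference.mean(axis=0) - mobile.mean(axis=0)])
        r = minimize(cost, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, r.fun)
    return best


def test_superpose_matches_numeric_minimizer(rng):
    """Kabsch result equals a derivative-free numeric search on small instances."""
    for n in (4, 5, 6):
        mobile = rng.normal(size=(n, 3)) * 3
        reference = rng.normal(size=(n, 3)) * 3
        analytic = geo.superpose(mobile, reference).rmsd
        numeric = _numeric_min_rmsd(mobile, reference)
        assert analytic == pytest.approx(numeric, abs=1e-5)
        assert analytic <= numeric + 1e-8


def test_superpose_displacement_rmsd(rng):
    """Half the atoms moved by d along random directions -> rmsd sqrt(d^2/2)
    after an optimal fit found by the numeric oracle."""
    x = rng.normal(size=(6, 3)) * 4
    y = x.copy()
    d = 1.4
    for i in range(3):
        v = rng.normal(size=3)
        y[i] += v / np.linalg.norm(v) * d
    analytic = geo.superpose(x, y).rmsd
    numeric = _numeric_min_rmsd(x, y)
    assert analytic == pytest.approx(numeric, abs=1e-5)


def test_superpose_errors():
    with pytest.raises(ValueError):
        geo.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        geo.superpose(line, line + 1.0)
    with pytest.raises(ValueError):
        geo.superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# groove frame


def test_groove_axis_along_x(flat_complex):
    s, ann = flat_complex
    origin, axis, normal = geo.groove_frame(s, ann)
    np.testing.assert_allclose(axis, [1.0, 0.0, 0.0], atol=1e-6)
    np.testing.assert_allclose(origin, [0.0, 0.0, 0.0], atol=1e-6)
    np.testing.assert_allclose(normal, [0.0, 0.0, 1.0], atol=1e-6)


def test_reversed_peptide_flips_axis(flat_complex):
    s, ann = flat_complex
    pep = s.chain("C")
    rev = list(reversed(pep.residues))
    import copy
    s2 = copy.deepcopy(s)
    chain = s2.chain("C")
    # renumber so residue 1 now sits at the +x end
    coords = [r.atoms for r in reversed(chain.residues)]
    for r, atoms in zip(chain.residues, coords):
        r.atoms = atoms
    _, axis, _ = geo.groove_frame(s2, ann)
    np.testing.assert_allclose(axis, [-1.0, 0.0, 0.0], atol=1e-6)


def test_normal_points_toward_tcr(fixture_complex):
    s, ann = fixture_complex
    _, _, normal = geo.groove_frame(s, ann)
    assert normal[2] > 0.99  # TCR sits at +z in the fixture frame


# ---------------------------------------------------------------------------
# docking descriptors


def test_zero_parameters_measure_zero(flat_complex):
    s, ann = flat_complex
    g = geo.docking_geometry(s, ann)
    assert g.crossing_angle == pytest.approx(0.0, abs=1e-6)
    assert g.incident_angle == pytest.approx(0.0, abs=1e-6)
    assert g.peptide_shift == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("crossing,incident,shift", [
    (28.0, 5.0, -3.0),
    (28.0, 7.0, 0.0),
    (45.0, 0.0, 4.0),
    (0.0, 12.0, -4.0),
    (135.0, 20.0, 8.0),
    (170.0, 40.0, -8.0),
])
def test_parameter_recovery(crossing, incident, shift):
    s, ann = syn.make_complex(syn.FixtureParams(
        crossing_deg=crossing, incident_deg=incident, shift_A=shift))
    g = geo.docking_geometry(s, ann)
    assert g.crossing_angle == pytest.approx(crossing, abs=0.5)
    assert g.incident_angle == pytest.approx(incident, abs=0.5)
    assert g.peptide_shift == pytest.approx(shift, abs=0.2)


def test_descriptors_invariant_under_rigid_transform(fixture_complex):
    s, ann = fixture_complex
    g0 = geo.docking_geometry(s, ann)
    rot = Rotation.from_euler("zyx", [31.0, -47.0, 112.0], degrees=True).as_matrix()
    s2 = s.transformed(rot, np.array([13.0, -7.0, 22.0]))
    g1 = geo.docking_geometry(s2, ann)
    assert g1.crossing_angle == pytest.approx(g0.crossing_angle, abs=1e-6)
    assert g1.incident_angle == pytest.approx(g0.incident_angle, abs=1e-6)
    assert g1.peptide_shift == pytest.approx(g0.peptide_shift, abs=1e-6)


def test_shift_ignores_perpendicular_displacement(flat_complex):
    s, ann = flat_complex
    s2 = s.transformed(np.eye(3), np.array([0.0, 5.0, 0.0]),
                       chain_ids=["D", "E"])
    assert geo.peptide_shift(s2, ann) == pytest.approx(0.0, abs=1e-6)
    s3 = s.transformed(np.eye(3), np.array([-4.0, 0.0, 0.0]),
                       chain_ids=["D", "E"])
    assert geo.peptide_shift(s3, ann) == pytest.approx(-4.0, abs=1e-6)


def test_mirror_fixture_crossing_supplementary():
    """Mirroring the TCR axis across the groove axis preserves the planar
    angle magnitude under the [0, 180) folding convention."""
    s1, ann = syn.make_complex(syn.FixtureParams(crossing_deg=28, incident_deg=0))
    mirror = np.diag([1.0, -1.0, 1.0])  # reflect y: axis heads to -28 deg
    s2 = s1.transformed(mirror, np.zeros(3), chain_ids=["D", "E"])
    a1 = geo.crossing_angle(s1, ann)
    a2 = geo.crossing_angle(s2, ann)
    assert a2 == pytest.approx(a1, abs=1e-6)


def test_crossing_requires_disulfides(fixture_complex):
    s, ann = fixture_complex
    from dataclasses import replace as dc_replace
    bare = dc_replace(ann, disulfide_cys={})
    with pytest.raises(ValueError, match="disulfide"):
        geo.crossing_angle(s, bare)


def test_vertical_axis_is_90_degrees_incident():
    """TCR axis along the platform normal: incident angle at the 90-deg cap."""
    s, ann = syn.make_complex(syn.FixtureParams(
        crossing_deg=0, incident_deg=0, shift_A=0, contact_loops=False))
    # rotate the TCR chains about the y axis through the midpoint by 90 deg
    rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
    mid = np.array([0.0, 0.0, 16.0])
    s2 = s.transformed(rot, mid - rot @ mid, chain_ids=["D", "E"])
    assert geo.incident_angle(s2, ann) == pytest.approx(90.0, abs=1e-6)


# ---------------------------------------------------------------------------
# RMSD profiling


def test_identical_structures_zero_profile(fixture_complex):
    s, ann = fixture_complex
    prof = geo.rmsd_profile(s, s, ann, ann, [ChainRole.MHC_HEAVY],
                            ChainRole.PEPTIDE)
    assert prof.summary_backbone == pytest.approx(0.0, abs=1e-9)
    assert prof.summary_allatom == pytest.approx(0.0, abs=1e-9)
    assert all(v["backbone_rmsd"] == pytest.approx(0, abs=1e-9)
               for v in prof.per_residue.values())


def test_single_displaced_residue(fixture_complex):
    s, ann = fixture_complex
    target = s.chain("C").residues[4].ref
    models = syn.make_ensemble(s, {target: 2.0}, n_models=1, seed=3)
    prof = geo.rmsd_profile(s, models[0], ann, ann, [ChainRole.MHC_HEAVY],
                            ChainRole.PEPTIDE)
    for ref, vals in prof.per_residue.items():
        expected = 2.0 if ref == target else 0.0
        assert vals["backbone_rmsd"] == pytest.approx(expected, abs=1e-9)
        assert vals["allatom_rmsd"] == pytest.approx(expected, abs=1e-9)


def test_ensemble_profiles_match_pairwise_recomputation(fixture_complex):
    """Per-model profiles over an ensemble equal independent two-structure runs."""
    s, ann = fixture_complex
    pep_refs = [r.ref for r in s.chain("C").residues]
    amps = {ref: 0.5 + 0.1 * i for i, ref in enumerate(pep_refs)}
    models = syn.make_ensemble(s, amps, n_models=5, seed=11)
    for m in models:
        prof = geo.rmsd_profile(s, m, ann, ann, [ChainRole.MHC_HEAVY],
                                ChainRole.PEPTIDE)
        for ref in pep_refs:
            assert prof.per_residue[ref]["backbone_rmsd"] == pytest.approx(
                amps[ref], abs=1e-9)


def test_cdr_rmsd_identical_is_zero(fixture_complex):
    s, ann = fixture_complex
    out = geo.cdr_rmsd(s, s, ann, ann)
    assert out["backbone"] == pytest.approx(0.0, abs=1e-9)
    assert out["allatom"] == pytest.approx(0.0, abs=1e-9)


def test_cdr_rmsd_uniform_displacement(fixture_complex):
    """All CDR atoms shifted 0.5 A with frameworks fixed -> (0.5, 0.5)."""
    s, ann = fixture_complex
    cdr_refs = {r.ref for cid in ("D", "E") for r in s.chain(cid).residues
                if ann.loop_of(r.ref) is not None}
    m = syn.make_ensemble(s, {ref: 0.5 for ref in cdr_refs},
                          n_models=1, seed=5)[0]
    out = geo.cdr_rmsd(s, m, ann, ann)
    assert out["backbone"] == pytest.approx(0.5, abs=1e-9)
    assert out["allatom"] == pytest.approx(0.5, abs=1e-9)


def test_cdr_rmsd_matches_profile_restriction(fixture_complex):
    """cdr_rmsd agrees with rmsd_profile summaries over the TCR chains when
    the fit selection is forced to the same framework residues."""
    s, ann = fixture_complex
    cdr_refs = {r.ref for cid in ("D", "E") for r in s.chain(cid).residues
                if ann.loop_of(r.ref) is not None}
    rng = np.random.default_rng(8)
    amps = {ref: float(rng.uniform(0.2, 1.0)) for ref in cdr_refs}
    m = syn.make_ensemble(s, amps, n_models=1, seed=9)[0]
    out = geo.cdr_rmsd(s, m, ann, ann)
    # frameworks unmoved -> fit is the identity -> pooled rmsd over CDR atoms
    import itertools
    sq, n = 0.0, 0
    for ref, amp in amps.items():
        na = len(s.residue(ref).atoms)
        sq += na * amp**2
        n += na
    assert out["allatom"] == pytest.approx(np.sqrt(sq / n), abs=1e-9)
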