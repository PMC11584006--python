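"""Docking-geometry descriptors and bound/unbound RMSD profiling.

The TCR interdomain axis runs from the Valpha intrachain-disulfide centroid
to the Vbeta one (the spheres conventionally drawn on TCR cartoons). The
pMHC frame is the peptide groove axis (first principal component of peptide
C-alpha positions, oriented N to C terminus) and the MHC platform normal
(least principal component of the platform C-alpha cloud, oriented toward
the TCR). Crossing angle is measured in the platform plane, incident angle
is the out-of-plane tilt, and the peptide shift is the TCR centroid's signed
position along the groove axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import (
    ChainRole,
    ComplexAnnotation,
    ResidueRef,
    StructureModel,
    select_atoms,
)

__all__ = [
    "DockingGeometry",
    "SuperpositionResult",
    "RmsdProfile",
    "superpose",
    "groove_frame",
    "tcr_axis",
    "crossing_angle",
    "incident_angle",
    "peptide_shift",
    "docking_geometry",
    "rmsd_profile",
    "cdr_rmsd",
]


@dataclass(frozen=True)
class DockingGeometry:
    crossing_angle: float  # degrees in [0, 180)
    incident_angle: float  # degrees in [0, 90]
    peptide_shift: float   # signed A; negative = toward peptide N terminus


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, A
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit (Kabsch): minimizes RMSD of R@mobile+t vs reference."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose needs equal-shape (n, 3) coordinate arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("superpose needs at least 3 atoms")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(x, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates; fit is ill-defined")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    fitted = x @ rot.T + mu_r
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _peptide_ca(s: StructureModel, ann: ComplexAnnotation) -> np.ndarray:
    pep = ann.chain_for_role(ChainRole.PEPTIDE)
    cas = [r.atom("CA") for r in s.chain(pep).residues]
    coords = np.array([a.xyz for a in cas if a is not None], dtype=float)
    if len(coords) < 3:
        raise ValueError("peptide needs at least 3 C-alpha atoms")
    return coords


def _platform_ca(s: StructureModel, ann: ComplexAnnotation) -> np.ndarray:
    mhc = ann.chain_for_role(ChainRole.MHC_HEAVY)
    lo, hi = ann.mhc_platform_range or (-(10**9), 10**9)
    cas = [
        r.atom("CA")
        for r in s.chain(mhc).residues
        if lo <= r.ref.seq_num <= hi
    ]
    coords = np.array([a.xyz for a in cas if a is not None], dtype=float)
    if len(coords) < 3:
        raise ValueError("MHC platform needs at least 3 C-alpha atoms")
    return coords


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(unit eigvecs sorted by descending variance, centroid)."""
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evecs[:, order].T, centroid


def _tcr_centroid(s: StructureModel, ann: ComplexAnnotation) -> np.ndarray:
    ids = ann.chains_for_roles({ChainRole.TCR_ALPHA, ChainRole.TCR_BETA})
    if not ids:
        raise ValueError("no TCR chains annotated")
    return s.coords(ids).mean(axis=0)


def groove_frame(
    pmhc: StructureModel, ann: ComplexAnnotation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(origin, groove_axis, plane_normal) of the peptide-binding platform.

    groove_axis: first principal component of peptide C-alphas, oriented
    N->C terminus. plane_normal: least principal component of the platform
    C-alphas, oriented toward the TCR when TCR chains are present (else +z
    hemisphere).
    """
    pep_ca = _peptide_ca(pmhc, ann)
    axes, origin = _principal_axes(pep_ca)
    groove_axis = axes[0]
    if np.dot(groove_axis, pep_ca[-1] - pep_ca[0]) < 0:
        groove_axis = -groove_axis

    plat = _platform_ca(pmhc, ann)
    plat_axes, plat_centroid = _principal_axes(plat)
    normal = plat_axes[2]
    try:
        toward = _tcr_centroid(pmhc, ann) - plat_centroid
    except ValueError:
        toward = np.array([0.0, 0.0, 1.0])
    if np.dot(normal, toward) < 0:
        normal = -normal
    return origin, groove_axis, normal


def _disulfide_centroid(
    s: StructureModel, ann: ComplexAnnotation, role: ChainRole
) -> np.ndarray:
    if role not in ann.disulfide_cys:
        raise ValueError(f"no disulfide annotated for {role.value}")
    pts = []
    for ref in ann.disulfide_cys[role]:
        res = s.residue(ref)
        atom = res.atom("SG") or res.atom("CB")
        if atom is None:
            raise ValueError(f"disulfide cysteine {ref} has neither SG nor CB")
        pts.append(atom.xyz)
    return np.asarray(pts, dtype=float).mean(axis=0)


def tcr_axis(s: StructureModel, ann: ComplexAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """(Valpha disulfide centroid, unit vector Valpha -> Vbeta centroid)."""
    a = _disulfide_centroid(s, ann, ChainRole.TCR_ALPHA)
    b = _disulfide_centroid(s, ann, ChainRole.TCR_BETA)
    v = b - a
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate TCR axis: disulfide centroids coincide")
    return a, v / norm


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def crossing_angle(complex: StructureModel, ann: ComplexAnnotation) -> float:
    """Planar angle (deg, [0, 180)) between TCR axis and groove axis,
    both projected into the MHC platform plane."""
    _, groove, normal = groove_frame(complex, ann)
    _, axis = tcr_axis(complex, ann)
    proj_t = axis - np.dot(axis, normal) * normal
    proj_g = groove - np.dot(groove, normal) * normal
    if np.linalg.norm(proj_t) < 1e-9:
        raise ValueError("TCR axis is perpendicular to the platform; "
                         "crossing angle undefined")
    ang = _angle_deg(proj_t, proj_g)
    return ang if ang < 180.0 else 0.0


def incident_angle(complex: StructureModel, ann: ComplexAnnotation) -> float:
    """Tilt (deg, [0, 90]) of the TCR axis out of the MHC platform plane."""
    _, _, normal = groove_frame(complex, ann)
    _, axis = tcr_axis(complex, ann)
    return abs(90.0 - _angle_deg(axis, normal))


def peptide_shift(complex: StructureModel, ann: ComplexAnnotation) -> float:
    """Signed position (A) of the TCR disulfide midpoint along the groove
    axis, relative to the peptide centroid; negative = toward N terminus."""
    origin, groove, _ = groove_frame(complex, ann)
    a = _disulfide_centroid(complex, ann, ChainRole.TCR_ALPHA)
    b = _disulfide_centroid(complex, ann, ChainRole.TCR_BETA)
    mid = (a + b) / 2.0
    return float(np.dot(mid - origin, groove))


def docking_geometry(complex: StructureModel, ann: ComplexAnnotation) -> DockingGeometry:
    return DockingGeometry(
        crossing_angle=crossing_angle(complex, ann),
        incident_angle=incident_angle(complex, ann),
        peptide_shift=peptide_shift(complex, ann),
    )


# ---------------------------------------------------------------------------
# bound/unbound RMSD profiling


@dataclass
class RmsdProfile:
    per_residue: dict[ResidueRef, dict[str, float]]  # backbone_rmsd, allatom_rmsd
    summary_backbone: float
    summary_allatom: float


def _match_residues(
    a: StructureModel, b: StructureModel, chain_a: str, chain_b: str
) -> list[tuple[ResidueRef, ResidueRef]]:
    """Residue correspondence: author numbering when numbering overlaps and
    amino acids agree, else positional pairing of identical-length chains
    with identical sequences. Anything else is an error."""
    res_a = a.chain(chain_a).residues
    res_b = b.chain(chain_b).residues
    by_num = {(r.ref.seq_num, r.ref.icode): r for r in res_b}
    matched = []
    mismatched: list[str] = []
    for r in res_a:
        other = by_num.get((r.ref.seq_num, r.ref.icode))
        if other is not None:
            if other.ref.aa != r.ref.aa:
                mismatched.append(str(r.ref))
                continue
            matched.append((r.ref, other.ref))
    if matched and not mismatched:
        return matched
    if len(res_a) == len(res_b) and all(
        x.ref.aa == y.ref.aa for x, y in zip(res_a, res_b)
    ):
        return [(x.ref, y.ref) for x, y in zip(res_a, res_b)]
    raise ValueError(
        f"cannot match chain {chain_a} to {chain_b}: numbering disagrees "
        f"(mismatches: {mismatched or 'no overlap'}) and sequences differ")


def _paired_coords(
    a: StructureModel, b: StructureModel,
    pairs: list[tuple[ResidueRef, ResidueRef]], selection: str,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for ref_a, ref_b in pairs:
        atoms_a = {name: at for (_, at) in select_atoms(a, selection, [ref_a])
                   for name in [at.name]}
        atoms_b = {name: at for (_, at) in select_atoms(b, selection, [ref_b])
                   for name in [at.name]}
        for name in atoms_a:
            if name in atoms_b:
                xs.append(atoms_a[name].xyz)
                ys.append(atoms_b[name].xyz)
    return np.array(xs, dtype=float).reshape(-1, 3), np.array(ys, dtype=float).reshape(-1, 3)


def _role_pairs(
    bound: StructureModel, unbound: StructureModel,
    ann_bound: ComplexAnnotation, ann_unbound: ComplexAnnotation,
    roles,
) -> list[tuple[ResidueRef, ResidueRef]]:
    pairs = []
    for role in roles:
        cid_b = ann_bound.chain_for_role(role)
        cid_u = ann_unbound.chain_for_role(role)
        pairs.extend(_match_residues(bound, unbound, cid_b, cid_u))
    return pairs


def rmsd_profile(
    bound: StructureModel,
    unbound: StructureModel,
    ann_bound: ComplexAnnotation,
    ann_unbound: ComplexAnnotation,
    fit_on,
    profile_over: ChainRole,
) -> RmsdProfile:
    """Superpose unbound onto bound on the fit roles' backbone, then report
    per-residue backbone and all-heavy-atom RMSD over the profiled role
    without further fitting."""
    fit_pairs = _role_pairs(bound, unbound, ann_bound, ann_unbound, fit_on)
    fit_b, fit_u = _paired_coords(bound, unbound, fit_pairs, "backbone")
    sup = superpose(fit_u, fit_b)  # move unbound onto bound

    prof_pairs = _role_pairs(bound, unbound, ann_bound, ann_unbound, [profile_over])
    if not prof_pairs:
        raise ValueError(f"no matched residues for {profile_over.value}")
    per_residue = {}
    bb_sq, bb_n, aa_sq, aa_n = 0.0, 0, 0.0, 0
    for ref_b, ref_u in prof_pairs:
        entry = {}
        for selection, key in (("backbone", "backbone_rmsd"),
                               ("all_heavy", "allatom_rmsd")):
            xb, xu = _paired_coords(bound, unbound, [(ref_b, ref_u)], selection)
            if len(xb) == 0:
                entry[key] = float("nan")
                continue
            diff = sup.apply(xu) - xb
            sq = float((diff**2).sum())
            entry[key] = float(np.sqrt(sq / len(xb)))
            if selection == "backbone":
                bb_sq += sq
                bb_n += len(xb)
            else:
                aa_sq += sq
                aa_n += len(xb)
        per_residue[ref_b] = entry
    return RmsdProfile(
        per_residue=per_residue,
        summary_backbone=float(np.sqrt(bb_sq / bb_n)) if bb_n else float("nan"),
        summary_allatom=float(np.sqrt(aa_sq / aa_n)) if aa_n else float("nan"),
    )


def cdr_rmsd(
    bound_tcr: StructureModel,
    unbound_tcr: StructureModel,
    ann_bound: ComplexAnnotation,
    ann_unbound: ComplexAnnotation,
) -> dict[str, float]:
    """Pooled CDR-loop RMSD (backbone and all-heavy-atom) after superposing
    the variable domains on their non-CDR (framework) backbone."""
    tcr_roles = (ChainRole.TCR_ALPHA, ChainRole.TCR_BETA)
    pairs = _role_pairs(bound_tcr, unbound_tcr, ann_bound, ann_unbound, tcr_roles)
    fw_pairs = [p for p in pairs if ann_bound.loop_of(p[0]) is None]
    cdr_pairs = [p for p in pairs if ann_bound.loop_of(p[0]) is not None]
    if not cdr_pairs:
        raise ValueError("no CDR residues matched between the two TCRs")
    fit_b, fit_u = _paired_coords(bound_tcr, unbound_tcr, fw_pairs, "backbone")
    sup = superpose(fit_u, fit_b)
    out = {}
    for selection, key in (("backbone", "backbone"), ("all_heavy", "allatom")):
        xb, xu = _paired_coords(bound_tcr, unbound_tcr, cdr_pairs, selection)
        diff = sup.apply(xu) - xb
        out[key] = float(np.sqrt((diff**2).sum() / len(xb)))
    return out
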