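"""Seeded generator of idealized TCR-pMHC-like fixtures.

The fixtures are geometric idealizations, not physically realistic proteins:
a 10-mer poly-alanine peptide laid along a groove axis, an MHC platform made
of two helical walls plus a sheet-like floor (so its C-alpha cloud has an
unambiguous plane), and a TCR built as two compact variable-domain clusters,
each carrying the conserved intrachain cysteine pair with S-gamma atoms.
The TCR is placed so that the measured crossing angle, incident angle and
peptide-axis shift equal the requested parameters exactly at zero noise.

Fixed chain ids: A = MHC heavy, B = beta-2 microglobulin, C = peptide,
D = TCR alpha, E = TCR beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import confidence as _confidence
from .structure import (
    AtomRecord,
    Chain,
    ChainRole,
    ComplexAnnotation,
    DEFAULT_CDR_RANGES,
    Loop,
    Residue,
    ResidueRef,
    StructureModel,
)

__all__ = [
    "FixtureParams",
    "DecoySpec",
    "ConfidenceSpec",
    "make_complex",
    "make_decoy",
    "assign_confidence",
    "make_ensemble",
    "CHAIN_MHC", "CHAIN_B2M", "CHAIN_PEPTIDE", "CHAIN_ALPHA", "CHAIN_BETA",
]

CHAIN_MHC, CHAIN_B2M, CHAIN_PEPTIDE, CHAIN_ALPHA, CHAIN_BETA = "A", "B", "C", "D", "E"

CA_SPACING = 3.5       # A between consecutive pseudo-residue C-alphas
DOMAIN_HALF_SEP = 10.0  # A from TCR midpoint to each disulfide centroid
DISULFIDE_CYS = (23, 104)

# heavy-atom offsets from CA for a poly-alanine pseudo-residue
_ALA_OFFSETS = {
    "N": (-1.20, 0.45, 0.35),
    "C": (1.20, 0.50, 0.30),
    "O": (1.60, 1.40, 1.00),
    "CB": (0.00, -0.80, 1.20),
}
# framework cluster offsets (A) around each domain centroid; non-collinear
_FRAMEWORK_OFFSETS = [
    (3.0, 0.0, 0.0), (-3.0, 0.5, 0.0), (0.0, 3.0, 0.5),
    (0.5, -3.0, 0.0), (0.0, 0.5, 3.0), (0.0, -0.5, -3.0),
    (2.0, 2.0, -1.5), (-2.0, -2.0, 1.5), (1.5, -1.8, 2.2),
]
_FRAMEWORK_NUMBERS = [1, 2, 3, 40, 41, 70, 90, 120, 121]


@dataclass(frozen=True)
class FixtureParams:
    crossing_deg: float = 28.0
    incident_deg: float = 5.0
    shift_A: float = 0.0
    peptide_len: int = 10
    seed: int = 0
    noise_A: float = 0.0
    tcr_height_A: float = 16.0
    contact_loops: bool = True  # hang CDR loops near the pMHC surface

    def __post_init__(self) -> None:
        if self.peptide_len < 4:
            raise ValueError("peptide_len must be >= 4")
        if self.noise_A < 0:
            raise ValueError("noise_A must be >= 0")
        if not 0.0 <= self.crossing_deg < 180.0:
            raise ValueError("crossing_deg must lie in [0, 180)")
        if not 0.0 <= self.incident_deg <= 60.0:
            raise ValueError("incident_deg must lie in [0, 60]; steeper tilts "
                             "drive the variable domains into the platform")
        if self.tcr_height_A < 8.0:
            raise ValueError("tcr_height_A < 8 A collides the TCR domains "
                             "with the platform")


@dataclass(frozen=True)
class DecoySpec:
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    applied_to: str = "ligand"  # ligand (TCR chains) | whole

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.rotation_axis)
        if n < 1e-9:
            raise ValueError("rotation_axis must be nonzero")


@dataclass(frozen=True)
class ConfidenceSpec:
    interface_mean: float = 90.0
    noninterface_mean: float = 70.0
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.interface_mean, self.noninterface_mean):
            if not 0.0 <= v <= 100.0:
                raise ValueError("pLDDT means must lie in [0, 100]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _residue(chain_id: str, num: int, ca: np.ndarray, res_name: str = "ALA",
             extra: dict[str, np.ndarray] | None = None) -> Residue:
    one = {"ALA": "A", "CYS": "C", "GLY": "G"}[res_name]
    ref = ResidueRef(chain_id=chain_id, seq_num=num, icode="", aa=one)
    atoms = [AtomRecord(name="CA", element="C", xyz=tuple(ca))]
    for name, off in _ALA_OFFSETS.items():
        if res_name == "GLY" and name == "CB":
            continue
        atoms.append(AtomRecord(name=name, element=name[0],
                                xyz=tuple(np.asarray(ca) + off)))
    for name, pos in (extra or {}).items():
        atoms.append(AtomRecord(name=name, element=name[0], xyz=tuple(pos)))
    return Residue(ref=ref, res_name=res_name, atoms=atoms)


def _peptide_chain(n: int) -> Chain:
    residues = []
    for i in range(n):
        x = (i - (n - 1) / 2.0) * CA_SPACING
        residues.append(_residue(CHAIN_PEPTIDE, i + 1, np.array([x, 0.0, 0.0])))
    return Chain(CHAIN_PEPTIDE, residues)


def _mhc_chain() -> Chain:
    residues = []
    num = 1
    for y in (6.0, -6.0):  # two helical walls flanking the groove
        for i in range(10):
            x = (i - 4.5) * CA_SPACING
            residues.append(_residue(CHAIN_MHC, num, np.array([x, y, 0.5])))
            num += 1
    for x in (-14.0, -7.0, 0.0, 7.0, 14.0):  # sheet-like floor
        for y in (-3.0, 0.0, 3.0):
            residues.append(_residue(CHAIN_MHC, num, np.array([x, y, -3.5])))
            num += 1
    return Chain(CHAIN_MHC, residues)


def _b2m_chain() -> Chain:
    residues = []
    for i, off in enumerate([(0, 0, 0), (3.5, 0, 0), (0, 3.5, 0),
                             (3.5, 3.5, 0), (1.75, 1.75, -3.0), (0, 0, -3.5)]):
        ca = np.array([-2.0, -2.0, -9.0]) + np.asarray(off, dtype=float)
        residues.append(_residue(CHAIN_B2M, i + 1, ca))
    return Chain(CHAIN_B2M, residues)


def _domain_residues(chain_id: str, centroid: np.ndarray,
                     sg_dir: np.ndarray) -> list[Residue]:
    """Framework cluster + the conserved Cys pair whose SG atoms average to
    ``centroid`` exactly."""
    residues = []
    for num, off in zip(_FRAMEWORK_NUMBERS, _FRAMEWORK_OFFSETS):
        residues.append(_residue(chain_id, num, centroid + off))
    for num, sign in zip(DISULFIDE_CYS, (1.0, -1.0)):
        sg = centroid + sign * sg_dir
        ca = sg + np.array([0.6, 0.6, 0.8]) * sign
        residues.append(_residue(chain_id, num, ca, res_name="CYS",
                                 extra={"SG": sg}))
    residues.sort(key=lambda r: r.ref.seq_num)
    return residues


def _loop_residues(chain_id: str, spec: list[tuple[int, np.ndarray]]) -> list[Residue]:
    out = []
    for num, ca in spec:
        r = _residue(chain_id, num, ca)
        # drop the side chain toward the surface below to guarantee contacts
        out.append(Residue(r.ref, r.res_name, [
            replace(a, xyz=(a.xyz[0], a.xyz[1], ca[2] - 1.6)) if a.name == "CB" else a
            for a in r.atoms
        ]))
    return out


def make_complex(p: FixtureParams) -> tuple[StructureModel, ComplexAnnotation]:
    """Build the idealized complex and its annotation.

    At ``noise_A`` = 0 the geometry module measures exactly
    (crossing_deg, incident_deg, shift_A) on the result.
    """
    theta = np.radians(p.crossing_deg)
    phi = np.radians(p.incident_deg)
    t_dir = np.array([
        np.cos(theta) * np.cos(phi),
        np.sin(theta) * np.cos(phi),
        np.sin(phi),
    ])
    midpoint = np.array([p.shift_A, 0.0, p.tcr_height_A])
    c_alpha = midpoint - DOMAIN_HALF_SEP * t_dir
    c_beta = midpoint + DOMAIN_HALF_SEP * t_dir
    # SG pair direction: perpendicular to the TCR axis so centroids are exact
    sg_dir = np.cross(t_dir, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(sg_dir) < 1e-6:
        sg_dir = np.array([1.0, 0.0, 0.0])
    sg_dir = sg_dir / np.linalg.norm(sg_dir)

    pep = _peptide_chain(p.peptide_len)
    n_pep = p.peptide_len
    xs = [(i - (n_pep - 1) / 2.0) * CA_SPACING for i in range(n_pep)]

    alpha_res = _domain_residues(CHAIN_ALPHA, c_alpha, sg_dir)
    beta_res = _domain_residues(CHAIN_BETA, c_beta, sg_dir)
    if p.contact_loops:
        z_loop = 4.2
        alpha_res += _loop_residues(CHAIN_ALPHA, [
            (30, np.array([-12.0, 6.0, z_loop])),   # CDR1a over the alpha2 wall
            (31, np.array([-8.5, 6.0, z_loop])),
            (32, np.array([-5.0, 6.0, z_loop])),
            (58, np.array([2.0, 6.0, z_loop])),     # CDR2a
            (59, np.array([5.5, 6.0, z_loop])),
            (108, np.array([xs[1], 0.0, z_loop])),  # CDR3a over N-terminal half
            (109, np.array([xs[2], 0.0, z_loop])),
            (110, np.array([xs[3], 0.0, z_loop])),
        ])
        beta_res += _loop_residues(CHAIN_BETA, [
            (30, np.array([-12.0, -6.0, z_loop])),  # CDR1b over the alpha1 wall
            (31, np.array([-8.5, -6.0, z_loop])),
            (58, np.array([2.0, -6.0, z_loop])),    # CDR2b
            (82, np.array([9.0, -6.0, z_loop])),    # HV4b
            (108, np.array([xs[-4], 0.0, z_loop])),  # CDR3b over C-terminal half
            (109, np.array([xs[-3], 0.0, z_loop])),
            (110, np.array([xs[-2], 0.0, z_loop])),
        ])
        alpha_res.sort(key=lambda r: r.ref.seq_num)
        beta_res.sort(key=lambda r: r.ref.seq_num)

    chains = [
        _mhc_chain(),
        _b2m_chain(),
        pep,
        Chain(CHAIN_ALPHA, alpha_res),
        Chain(CHAIN_BETA, beta_res),
    ]
    s = StructureModel(
        model_id=f"fixture_x{p.crossing_deg:g}_i{p.incident_deg:g}_s{p.shift_A:g}",
        chains=chains,
        meta={
            "generator": "tcrface.synthetic.make_complex",
            "crossing_deg": p.crossing_deg,
            "incident_deg": p.incident_deg,
            "shift_A": p.shift_A,
            "seed": p.seed,
            "noise_A": p.noise_A,
        },
    )
    if p.noise_A > 0:
        rng = np.random.default_rng(p.seed)
        for ch in s.chains:
            for res in ch.residues:
                res.atoms = [
                    replace(a, xyz=tuple(np.asarray(a.xyz)
                                         + rng.normal(0.0, p.noise_A, 3)))
                    for a in res.atoms
                ]

    ann = ComplexAnnotation(
        roles={
            CHAIN_MHC: ChainRole.MHC_HEAVY,
            CHAIN_B2M: ChainRole.B2M,
            CHAIN_PEPTIDE: ChainRole.PEPTIDE,
            CHAIN_ALPHA: ChainRole.TCR_ALPHA,
            CHAIN_BETA: ChainRole.TCR_BETA,
        },
        cdr_ranges={
            (role, loop): rng_
            for role in (ChainRole.TCR_ALPHA, ChainRole.TCR_BETA)
            for loop, rng_ in DEFAULT_CDR_RANGES.items()
        },
        disulfide_cys={
            ChainRole.TCR_ALPHA: (
                ResidueRef(CHAIN_ALPHA, DISULFIDE_CYS[0], "", "C"),
                ResidueRef(CHAIN_ALPHA, DISULFIDE_CYS[1], "", "C"),
            ),
            ChainRole.TCR_BETA: (
                ResidueRef(CHAIN_BETA, DISULFIDE_CYS[0], "", "C"),
                ResidueRef(CHAIN_BETA, DISULFIDE_CYS[1], "", "C"),
            ),
        },
    )
    ann.validate(s)
    return s, ann


def make_decoy(reference: StructureModel, ann: ComplexAnnotation,
               d: DecoySpec) -> StructureModel:
    """Rigid-body decoy with an exactly known transform.

    The rotation acts about the moved subset's centroid, then the translation
    is applied; the ground-truth transform is recorded in ``meta``.
    """
    if d.applied_to == "ligand":
        chain_ids = ann.chains_for_roles({ChainRole.TCR_ALPHA, ChainRole.TCR_BETA})
    elif d.applied_to == "whole":
        chain_ids = list(reference.chain_ids)
    else:
        raise ValueError(f"unknown decoy subset {d.applied_to!r}")
    if not chain_ids:
        raise ValueError("decoy subset resolves to no chains")
    axis = np.asarray(d.rotation_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(d.rotation_deg) * axis).as_matrix()
    centroid = reference.coords(chain_ids).mean(axis=0)
    # x -> R (x - c) + c + t
    translation = centroid - rot @ centroid + np.asarray(d.translation, dtype=float)
    out = reference.transformed(rot, translation, chain_ids)
    out.model_id = reference.model_id + "_decoy"
    out.meta.update({
        "decoy_rotation_deg": d.rotation_deg,
        "decoy_rotation_axis": tuple(axis),
        "decoy_translation": tuple(d.translation),
        "decoy_applied_to": d.applied_to,
    })
    return out


def assign_confidence(s: StructureModel, ann: ComplexAnnotation,
                      c: ConfidenceSpec) -> StructureModel:
    """Copy with per-atom pLDDT drawn around separate interface and
    non-interface means (Normal, clipped to [0, 100]); seeded."""
    iface = set(_confidence.interface_residues(s, ann))
    rng = np.random.default_rng(c.seed)
    new_chains = []
    for ch in s.chains:
        new_res = []
        for res in ch.residues:
            mean = c.interface_mean if res.ref in iface else c.noninterface_mean
            vals = (np.full(len(res.atoms), mean) if c.sd == 0
                    else np.clip(rng.normal(mean, c.sd, len(res.atoms)), 0.0, 100.0))
            new_res.append(Residue(res.ref, res.res_name, [
                replace(a, conf=float(v)) for a, v in zip(res.atoms, vals)]))
        new_chains.append(Chain(ch.chain_id, new_res))
    out = StructureModel(s.model_id, new_chains, dict(s.meta))
    out.meta.update({"confidence_seed": c.seed,
                     "interface_mean": c.interface_mean,
                     "noninterface_mean": c.noninterface_mean,
                     "confidence_sd": c.sd})
    return out


def make_ensemble(base: StructureModel, amplitudes: dict[ResidueRef, float],
                  n_models: int, seed: int = 0) -> list[StructureModel]:
    """n_models copies with per-residue rigid displacements of the stated
    magnitude in seeded random directions (so each displaced residue's RMSD
    to the base equals its amplitude exactly, before any refitting)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_models):
        new_chains = []
        for ch in base.chains:
            new_res = []
            for res in ch.residues:
                amp = amplitudes.get(res.ref, 0.0)
                if amp > 0:
                    v = rng.normal(size=3)
                    v = v / np.linalg.norm(v) * amp
                    new_res.append(Residue(res.ref, res.res_name, [
                        replace(a, xyz=tuple(np.asarray(a.xyz) + v))
                        for a in res.atoms]))
                else:
                    new_res.append(Residue(res.ref, res.res_name, list(res.atoms)))
            new_chains.append(Chain(ch.chain_id, new_res))
        m = StructureModel(f"{base.model_id}_m{k + 1}", new_chains, dict(base.meta))
        m.meta.update({"ensemble_member": k + 1, "ensemble_seed": seed})
        out.append(m)
    return out
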