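"""Model-vs-reference interface accuracy: fnat, I-RMSD, L-RMSD, DockQ, CAPRI.

Grading follows the standard docking-assessment conventions: native contacts
are residue pairs across the two partners with any heavy-atom pair within
5.0 A; interface residues for I-RMSD carry any heavy atom within 10.0 A of
the other partner; L-RMSD is the ligand backbone RMSD after fitting on the
receptor backbone. DockQ combines the three on [0, 1]:

    DockQ = (fnat + 1/(1+(irmsd/1.5)^2) + 1/(1+(lrmsd/8.5)^2)) / 3

For TCR-pMHC grading the receptor is the pMHC and the ligand the TCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import superpose
from .structure import (
    ChainRole,
    ComplexAnnotation,
    ResidueRef,
    StructureModel,
    select_atoms,
)

__all__ = [
    "AccuracyParams",
    "AccuracyReport",
    "ResidueMap",
    "residue_map",
    "fnat",
    "irmsd",
    "lrmsd",
    "dockq",
    "capri_class",
    "invert_dockq_for_fnat",
    "assess",
]


@dataclass(frozen=True)
class AccuracyParams:
    native_contact_cutoff: float = 5.0     # A, residue-level native contacts
    interface_residue_cutoff: float = 10.0  # A, I-RMSD interface definition
    dockq_d1: float = 1.5                  # A, I-RMSD scaling constant
    dockq_d2: float = 8.5                  # A, L-RMSD scaling constant

    def __post_init__(self) -> None:
        for f in ("native_contact_cutoff", "interface_residue_cutoff",
                  "dockq_d1", "dockq_d2"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class AccuracyReport:
    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    capri: str  # High | Medium | Acceptable | Incorrect


@dataclass
class ResidueMap:
    """One-to-one model->reference residue pairing per mapped chain."""

    pairs: dict[ResidueRef, ResidueRef]          # model ref -> reference ref
    unpaired_model: list[ResidueRef]
    unpaired_reference: list[ResidueRef]

    @property
    def reverse(self) -> dict[ResidueRef, ResidueRef]:
        return {v: k for k, v in self.pairs.items()}


def _pair_chain(model_ch, ref_ch) -> list[tuple[ResidueRef, ResidueRef]]:
    """Pair residues of two chains: same author numbering with matching amino
    acids if that works for all shared numbers, else the best ungapped
    positional offset over identical residues."""
    by_num = {(r.ref.seq_num, r.ref.icode): r.ref for r in ref_ch.residues}
    direct = []
    mismatched = False
    for r in model_ch.residues:
        other = by_num.get((r.ref.seq_num, r.ref.icode))
        if other is None:
            continue
        if other.aa != r.ref.aa:
            mismatched = True
            break
        direct.append((r.ref, other))
    n_min = min(len(model_ch.residues), len(ref_ch.residues))
    if not mismatched and len(direct) >= 0.5 * n_min:
        return direct
    # ungapped sliding alignment on one-letter sequences
    seq_m = model_ch.sequence
    seq_r = ref_ch.sequence
    best_offset, best_score = None, 0
    for off in range(-len(seq_m) + 1, len(seq_r)):
        score = sum(
            1
            for i in range(len(seq_m))
            if 0 <= i + off < len(seq_r) and seq_m[i] == seq_r[i + off]
        )
        if score > best_score:
            best_score, best_offset = score, off
    if best_offset is None or best_score < max(3, min(len(seq_m), len(seq_r)) // 2):
        raise ValueError(
            f"chains {model_ch.chain_id}->{ref_ch.chain_id} share no ungapped "
            "common core")
    out = []
    for i, r in enumerate(model_ch.residues):
        j = i + best_offset
        if 0 <= j < len(ref_ch.residues) and seq_m[i] == seq_r[j]:
            out.append((r.ref, ref_ch.residues[j].ref))
    return out


def residue_map(
    model: StructureModel,
    reference: StructureModel,
    chain_map: dict[str, str],
) -> ResidueMap:
    """Build the model->reference residue correspondence over mapped chains."""
    pairs: dict[ResidueRef, ResidueRef] = {}
    for m_id, r_id in chain_map.items():
        if m_id not in model.chain_ids:
            raise KeyError(f"chain map names absent model chain {m_id!r}")
        if r_id not in reference.chain_ids:
            raise KeyError(f"chain map names absent reference chain {r_id!r}")
        for m_ref, r_ref in _pair_chain(model.chain(m_id), reference.chain(r_id)):
            pairs[m_ref] = r_ref
    mapped_m = set(pairs)
    mapped_r = set(pairs.values())
    unpaired_m = [r.ref for c in model.chains if c.chain_id in chain_map
                  for r in c.residues if r.ref not in mapped_m]
    unpaired_r = [r.ref for c in reference.chains
                  if c.chain_id in set(chain_map.values())
                  for r in c.residues if r.ref not in mapped_r]
    return ResidueMap(pairs=pairs, unpaired_model=unpaired_m,
                      unpaired_reference=unpaired_r)


def _residue_contacts(
    s: StructureModel, side_a: list[str], side_b: list[str], cutoff: float
) -> set[tuple[ResidueRef, ResidueRef]]:
    atoms_a = [(r.ref, a.xyz) for r in s.residues(side_a) for a in r.atoms]
    atoms_b = [(r.ref, a.xyz) for r in s.residues(side_b) for a in r.atoms]
    if not atoms_a or not atoms_b:
        return set()
    xa = np.array([x for _, x in atoms_a])
    xb = np.array([x for _, x in atoms_b])
    tree = cKDTree(xb)
    out: set[tuple[ResidueRef, ResidueRef]] = set()
    for i, hits in enumerate(tree.query_ball_point(xa, cutoff)):
        for j in hits:
            out.add((atoms_a[i][0], atoms_b[j][0]))
    return out


def _chain_map_of(rmap: ResidueMap) -> dict[str, str]:
    """Model-chain -> reference-chain map implied by the residue pairing."""
    out: dict[str, str] = {}
    for m_ref, r_ref in rmap.pairs.items():
        out[m_ref.chain_id] = r_ref.chain_id
    return out


def _partition_chains(
    ann: ComplexAnnotation, receptor_is_pmhc: bool = True
) -> tuple[list[ChainRole], list[ChainRole]]:
    pmhc = [ChainRole.MHC_HEAVY, ChainRole.PEPTIDE]  # b2m excluded from interface
    tcr = [ChainRole.TCR_ALPHA, ChainRole.TCR_BETA]
    return (pmhc, tcr) if receptor_is_pmhc else (tcr, pmhc)


def fnat(
    model: StructureModel,
    reference: StructureModel,
    rmap: ResidueMap,
    ann_ref: ComplexAnnotation,
    p: AccuracyParams = AccuracyParams(),
    receptor_is_pmhc: bool = True,
) -> float:
    """Fraction of reference receptor-ligand residue contacts present in the model."""
    rec_roles, lig_roles = _partition_chains(ann_ref, receptor_is_pmhc)
    rec = ann_ref.chains_for_roles(rec_roles)
    lig = ann_ref.chains_for_roles(lig_roles)
    native = _residue_contacts(reference, rec, lig, p.native_contact_cutoff)
    if not native:
        raise ValueError("reference has no cross-partner contacts")
    rec_set, lig_set = set(rec), set(lig)
    chain_map = _chain_map_of(rmap)
    m_rec = [m for m, r in chain_map.items() if r in rec_set]
    m_lig = [m for m, r in chain_map.items() if r in lig_set]
    model_pairs = _residue_contacts(model, m_rec, m_lig, p.native_contact_cutoff)
    # model contacts expressed in reference numbering, restricted to mapped residues
    model_in_ref = set()
    for a, b in model_pairs:
        ra, rb = rmap.pairs.get(a), rmap.pairs.get(b)
        if ra is not None and rb is not None:
            model_in_ref.add((ra, rb))
            model_in_ref.add((rb, ra))
    reproduced = sum(1 for pair in native if pair in model_in_ref)
    return reproduced / len(native)


def _interface_residues(
    reference: StructureModel, ann_ref: ComplexAnnotation,
    p: AccuracyParams, receptor_is_pmhc: bool,
) -> list[ResidueRef]:
    rec_roles, lig_roles = _partition_chains(ann_ref, receptor_is_pmhc)
    rec = ann_ref.chains_for_roles(rec_roles)
    lig = ann_ref.chains_for_roles(lig_roles)
    pairs = _residue_contacts(reference, rec, lig, p.interface_residue_cutoff)
    refs = sorted({r for pair in pairs for r in pair})
    return refs


def _paired_backbone(
    model: StructureModel, reference: StructureModel,
    rmap: ResidueMap, ref_residues: list[ResidueRef],
) -> tuple[np.ndarray, np.ndarray]:
    rev = rmap.reverse
    xs, ys = [], []
    for r_ref in ref_residues:
        m_ref = rev.get(r_ref)
        if m_ref is None:
            continue
        ref_atoms = {a.name: a for (_, a) in select_atoms(reference, "backbone", [r_ref])}
        mod_atoms = {a.name: a for (_, a) in select_atoms(model, "backbone", [m_ref])}
        for name, a in ref_atoms.items():
            if name in mod_atoms:
                xs.append(mod_atoms[name].xyz)
                ys.append(a.xyz)
    return np.array(xs).reshape(-1, 3), np.array(ys).reshape(-1, 3)


def irmsd(
    model: StructureModel,
    reference: StructureModel,
    rmap: ResidueMap,
    ann_ref: ComplexAnnotation,
    p: AccuracyParams = AccuracyParams(),
    receptor_is_pmhc: bool = True,
) -> float:
    """Backbone RMSD over reference interface residues after interface fit."""
    interface = _interface_residues(reference, ann_ref, p, receptor_is_pmhc)
    rev = rmap.reverse
    paired = [r for r in interface if r in rev]
    if len(paired) < 3:
        raise ValueError("fewer than 3 paired interface residues")
    if len(paired) < 0.5 * len(interface):
        raise ValueError(
            f"only {len(paired)}/{len(interface)} reference interface residues "
            "pairable; check the chain map")
    mob, ref = _paired_backbone(model, reference, rmap, paired)
    return superpose(mob, ref).rmsd


def lrmsd(
    model: StructureModel,
    reference: StructureModel,
    rmap: ResidueMap,
    ann_ref: ComplexAnnotation,
    p: AccuracyParams = AccuracyParams(),
    receptor_is_pmhc: bool = True,
) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone."""
    rec_roles, lig_roles = _partition_chains(ann_ref, receptor_is_pmhc)
    rec_ids = set(ann_ref.chains_for_roles(rec_roles))
    # b2m joins the receptor fit when present in both structures
    b2m = ann_ref.chains_for_roles([ChainRole.B2M])
    rev = rmap.reverse
    if b2m and any(rev.get(r.ref) for r in reference.residues(b2m)):
        rec_ids |= set(b2m)
    lig_ids = set(ann_ref.chains_for_roles(lig_roles))
    rec_res = [r.ref for r in reference.residues(rec_ids) if r.ref in rev]
    lig_res = [r.ref for r in reference.residues(lig_ids) if r.ref in rev]
    if len(rec_res) < 3 or not lig_res:
        raise ValueError("too few paired receptor or ligand residues")
    mob_r, ref_r = _paired_backbone(model, reference, rmap, rec_res)
    sup = superpose(mob_r, ref_r)
    mob_l, ref_l = _paired_backbone(model, reference, rmap, lig_res)
    diff = sup.apply(mob_l) - ref_l
    return float(np.sqrt((diff**2).sum() / len(ref_l)))


def capri_class(fnat_v: float, irmsd_v: float, lrmsd_v: float) -> str:
    """CAPRI quality tier; boundary values are inclusive."""
    if fnat_v >= 0.5 and (irmsd_v <= 1.0 or lrmsd_v <= 1.0):
        return "High"
    if fnat_v >= 0.3 and (irmsd_v <= 2.0 or lrmsd_v <= 5.0):
        return "Medium"
    if fnat_v >= 0.1 and (irmsd_v <= 4.0 or lrmsd_v <= 10.0):
        return "Acceptable"
    return "Incorrect"


def dockq(
    fnat_v: float, irmsd_v: float, lrmsd_v: float,
    p: AccuracyParams = AccuracyParams(),
) -> tuple[float, str]:
    """DockQ score and CAPRI class from the three component metrics."""
    if not 0.0 <= fnat_v <= 1.0:
        raise ValueError(f"fnat {fnat_v} outside [0, 1]")
    if irmsd_v < 0 or lrmsd_v < 0:
        raise ValueError("RMSDs must be non-negative")
    score = (
        fnat_v
        + 1.0 / (1.0 + (irmsd_v / p.dockq_d1) ** 2)
        + 1.0 / (1.0 + (lrmsd_v / p.dockq_d2) ** 2)
    ) / 3.0
    return score, capri_class(fnat_v, irmsd_v, lrmsd_v)


def invert_dockq_for_fnat(
    dockq_score: float, irmsd_v: float, lrmsd_v: float,
    p: AccuracyParams = AccuracyParams(),
) -> float:
    """The unique fnat in [0, 1] consistent with a DockQ score and its RMSDs.

    The score is affine in fnat, so inversion is closed-form; raises if the
    implied fnat falls outside [0, 1].
    """
    f = (
        3.0 * dockq_score
        - 1.0 / (1.0 + (irmsd_v / p.dockq_d1) ** 2)
        - 1.0 / (1.0 + (lrmsd_v / p.dockq_d2) ** 2)
    )
    if not -1e-9 <= f <= 1.0 + 1e-9:
        raise ValueError(f"no fnat in [0,1] consistent with DockQ {dockq_score}")
    return float(min(max(f, 0.0), 1.0))


def assess(
    model: StructureModel,
    reference: StructureModel,
    ann_ref: ComplexAnnotation,
    chain_map: dict[str, str],
    p: AccuracyParams = AccuracyParams(),
    receptor_is_pmhc: bool = True,
) -> AccuracyReport:
    """End-to-end model grading against a reference complex."""
    rmap = residue_map(model, reference, chain_map)
    f = fnat(model, reference, rmap, ann_ref, p, receptor_is_pmhc)
    i = irmsd(model, reference, rmap, ann_ref, p, receptor_is_pmhc)
    l = lrmsd(model, reference, rmap, ann_ref, p, receptor_is_pmhc)
    score, tier = dockq(f, i, l, p)
    return AccuracyReport(fnat=f, irmsd=i, lrmsd=l, dockq=score, capri=tier)
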