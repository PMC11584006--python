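"""Atomic contact detection, polar-contact classification, CDR-decomposed
contact tables, and peptide surface burial.

Contacts follow the crystallographic convention: every heavy-atom pair across
the two binding partners at 4.0 A or less counts once. Hydrogen-bond and
salt-bridge calls use heavy-atom donor/acceptor distance criteria (no
hydrogens are present, so no angle terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import sasa as _sasa
from .structure import (
    AtomRecord,
    ChainRole,
    ComplexAnnotation,
    Loop,
    ResidueRef,
    StructureModel,
)

__all__ = [
    "ContactParams",
    "ContactRecord",
    "ContactTable",
    "BurialReport",
    "find_contacts",
    "classify_polar",
    "cdr_contact_table",
    "chain_share",
    "round_percent",
    "sasa",
    "peptide_burial",
    "PMHC_ROLES",
    "TCR_ROLES",
]

TCR_ROLES = frozenset({ChainRole.TCR_ALPHA, ChainRole.TCR_BETA})
PMHC_ROLES = frozenset({ChainRole.MHC_HEAVY, ChainRole.B2M, ChainRole.PEPTIDE})

#: the eight Table-1 loop columns, alpha chain first
LOOP_ORDER: list[tuple[ChainRole, Loop]] = [
    (ChainRole.TCR_ALPHA, Loop.CDR1),
    (ChainRole.TCR_ALPHA, Loop.CDR2),
    (ChainRole.TCR_ALPHA, Loop.HV4),
    (ChainRole.TCR_ALPHA, Loop.CDR3),
    (ChainRole.TCR_BETA, Loop.CDR1),
    (ChainRole.TCR_BETA, Loop.CDR2),
    (ChainRole.TCR_BETA, Loop.HV4),
    (ChainRole.TCR_BETA, Loop.CDR3),
]


@dataclass(frozen=True)
class ContactParams:
    contact_cutoff: float = 4.0      # A, heavy-atom van der Waals contact
    hbond_da_cutoff: float = 3.5     # A, donor-acceptor distance
    saltbridge_cutoff: float = 4.0   # A, charged N to carboxylate O
    probe_radius: float = 1.4        # A, solvent probe for SASA
    sasa_points: int = 960           # sphere-sampling count

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hbond_da_cutoff", "saltbridge_cutoff",
                     "probe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sasa_points < 1:
            raise ValueError("sasa_points must be >= 1")


@dataclass(frozen=True)
class ContactRecord:
    atom_a: tuple[ResidueRef, str]
    atom_b: tuple[ResidueRef, str]
    distance: float
    kind: str = "vdw"  # vdw | hbond | saltbridge


def round_percent(count: float, total: float) -> int:
    """Integer percent share, rounded half away from zero (95/128 -> 74)."""
    if total == 0:
        raise ZeroDivisionError("percent of zero total is undefined")
    x = 100.0 * count / total
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _side_atoms(
    s: StructureModel, ann: ComplexAnnotation, roles: Iterable[ChainRole]
) -> list[tuple[ResidueRef, AtomRecord]]:
    chain_ids = ann.chains_for_roles(roles)
    out = [(r.ref, a) for r in s.residues(chain_ids) for a in r.atoms]
    return out


def find_contacts(
    s: StructureModel,
    ann: ComplexAnnotation,
    side_a: Iterable[ChainRole],
    side_b: Iterable[ChainRole],
    p: ContactParams = ContactParams(),
) -> list[ContactRecord]:
    """All heavy-atom pairs across the two sides within the contact cutoff.

    Deterministic order: side_a file order (outer), then side_b file order.
    """
    side_a, side_b = set(side_a), set(side_b)
    if side_a & side_b:
        raise ValueError("contact sides must be disjoint role sets")
    atoms_a = _side_atoms(s, ann, side_a)
    atoms_b = _side_atoms(s, ann, side_b)
    if not atoms_a or not atoms_b:
        empty = "a" if not atoms_a else "b"
        raise ValueError(f"side_{empty} resolves to no atoms in {s.model_id!r}")
    xyz_a = np.array([a.xyz for _, a in atoms_a])
    xyz_b = np.array([a.xyz for _, a in atoms_b])
    tree_b = cKDTree(xyz_b)
    pairs = tree_b.query_ball_point(xyz_a, p.contact_cutoff)
    records = []
    for i, hits in enumerate(pairs):
        ref_a, atom_a = atoms_a[i]
        for j in sorted(hits):
            ref_b, atom_b = atoms_b[j]
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            records.append(ContactRecord(
                atom_a=(ref_a, atom_a.name),
                atom_b=(ref_b, atom_b.name),
                distance=d,
            ))
    return records


# side-chain nitrogen atoms of positively charged residues / carboxylate
# oxygens of negatively charged residues, for salt-bridge detection
_BASIC_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# heavy-atom H-bond capability: backbone N donates, backbone O accepts;
# side-chain N/O of polar residues treated as donor and/or acceptor
_SC_DONOR = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SC_ACCEPTOR = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}


def _is_donor(res_name: str, atom: str) -> bool:
    return atom == "N" or atom in _SC_DONOR.get(res_name, ())


def _is_acceptor(res_name: str, atom: str) -> bool:
    return atom in ("O", "OXT") or atom in _SC_ACCEPTOR.get(res_name, ())


def classify_polar(
    contacts: Sequence[ContactRecord],
    s: StructureModel,
    p: ContactParams = ContactParams(),
) -> list[ContactRecord]:
    """Assign each contact exactly one kind: saltbridge > hbond > vdw."""
    out = []
    for c in contacts:
        (ref_a, name_a), (ref_b, name_b) = c.atom_a, c.atom_b
        rn_a = s.residue(ref_a).res_name
        rn_b = s.residue(ref_b).res_name
        kind = "vdw"
        sb = (
            (name_a in _BASIC_N.get(rn_a, ()) and name_b in _ACIDIC_O.get(rn_b, ()))
            or (name_b in _BASIC_N.get(rn_b, ()) and name_a in _ACIDIC_O.get(rn_a, ()))
        )
        if sb and c.distance <= p.saltbridge_cutoff:
            kind = "saltbridge"
        elif c.distance <= p.hbond_da_cutoff and (
            (_is_donor(rn_a, name_a) and _is_acceptor(rn_b, name_b))
            or (_is_donor(rn_b, name_b) and _is_acceptor(rn_a, name_a))
        ):
            kind = "hbond"
        out.append(replace(c, kind=kind))
    return out


@dataclass
class ContactTable:
    """Per-loop contact counts and integer percent shares, per target.

    Mirrors the printed Table-1 layout: eight loop columns (CDR1/CDR2/HV4/CDR3
    for each TCR chain) plus a separate framework row, for targets ``peptide``
    and ``mhc``.
    """

    counts: dict[str, dict[tuple[ChainRole, Loop] | str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def percent(self, target: str, key: tuple[ChainRole, Loop] | str) -> int:
        return round_percent(self.counts[target][key], self.totals[target])

    def percents(self, target: str) -> list[int]:
        return [self.percent(target, key) for key in LOOP_ORDER]

    def loop_counts(self, target: str) -> list[int]:
        return [self.counts[target][key] for key in LOOP_ORDER]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{loop.value}{'a' if role is ChainRole.TCR_ALPHA else 'b'}"
                for role, loop in LOOP_ORDER] + ["framework", "total"]
        rows = {}
        for target in ("peptide", "mhc"):
            if target not in self.counts:
                continue
            cnts = self.loop_counts(target) + [self.counts[target]["framework"],
                                               self.totals[target]]
            rows[f"{target}_count"] = cnts
            if self.totals[target] > 0:
                pct = self.percents(target) + [
                    self.percent(target, "framework"), 100]
            else:
                pct = ["-"] * 10
            rows[f"{target}_percent"] = pct
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def cdr_contact_table(
    contacts: Sequence[ContactRecord],
    ann: ComplexAnnotation,
) -> ContactTable:
    """Attribute TCR-vs-pMHC contacts to CDR loops and targets.

    Each contact must have exactly one atom on a TCR chain; its loop is the
    annotated CDR/HV4 interval containing the TCR residue (else framework),
    and its target is ``peptide`` or ``mhc`` by the partner chain role.
    """
    table = ContactTable()
    for target in ("peptide", "mhc"):
        table.counts[target] = {key: 0 for key in LOOP_ORDER}
        table.counts[target]["framework"] = 0
        table.totals[target] = 0
    for c in contacts:
        side = {}
        for which, (ref, _) in (("a", c.atom_a), ("b", c.atom_b)):
            role = ann.roles.get(ref.chain_id)
            if role is None:
                raise ValueError(f"contact residue {ref} has no annotated role")
            side[which] = (ref, role)
        tcr = [v for v in side.values() if v[1] in TCR_ROLES]
        pmhc = [v for v in side.values() if v[1] in PMHC_ROLES]
        if len(tcr) != 1 or len(pmhc) != 1:
            raise ValueError(
                f"contact {side['a'][0]}-{side['b'][0]} is not TCR-vs-pMHC")
        tcr_ref, _ = tcr[0]
        _, pmhc_role = pmhc[0]
        target = "peptide" if pmhc_role is ChainRole.PEPTIDE else "mhc"
        hit = ann.loop_of(tcr_ref)
        key: tuple[ChainRole, Loop] | str = hit if hit is not None else "framework"
        table.counts[target][key] += 1
        table.totals[target] += 1
    return table


def chain_share(table: ContactTable, chain: str, target: str) -> int:
    """Integer percent of a target's contacts mediated by one TCR chain."""
    role = {"alpha": ChainRole.TCR_ALPHA, "beta": ChainRole.TCR_BETA}[chain]
    total = table.totals[target]
    if total == 0:
        raise ZeroDivisionError(f"no contacts to {target}")
    n = sum(table.counts[target][key] for key in LOOP_ORDER if key[0] == role)
    return round_percent(n, total)


def sasa(s: StructureModel, p: ContactParams = ContactParams(),
         chain_ids: Iterable[str] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), file order."""
    atoms = [a for r in s.residues(chain_ids) for a in r.atoms]
    coords = np.array([a.xyz for a in atoms]).reshape(-1, 3)
    elements = [a.element for a in atoms]
    return _sasa.sasa_areas(coords, elements, p.probe_radius, p.sasa_points)


@dataclass(frozen=True)
class BurialReport:
    sasa_free: float        # peptide SASA in the pMHC subcomplex, A^2
    sasa_bound: float       # peptide SASA in the full complex, A^2
    bsa: float              # buried surface area, A^2
    burial_fraction: float  # percent of free SASA buried by the TCR


def peptide_burial(
    s_complex: StructureModel,
    ann: ComplexAnnotation,
    p: ContactParams = ContactParams(),
) -> BurialReport:
    """Fraction of the peptide's pMHC-bound accessible surface buried by TCR.

    ``sasa_free`` is the peptide SASA computed in the TCR-deleted pMHC
    subcomplex; ``sasa_bound`` is the peptide SASA in the full complex.
    """
    for role in (ChainRole.PEPTIDE, ChainRole.MHC_HEAVY):
        if not ann.chains_with_role(role):
            raise ValueError(f"complex lacks a {role.value} chain")
    if not ann.chains_for_roles(TCR_ROLES):
        raise ValueError("complex lacks TCR chains")
    pep_chain = ann.chain_for_role(ChainRole.PEPTIDE)
    pmhc_ids = ann.chains_for_roles(PMHC_ROLES)

    def peptide_total(chain_subset: list[str]) -> float:
        atoms = [a for r in s_complex.residues(chain_subset) for a in r.atoms]
        areas = sasa(s_complex, p, chain_ids=chain_subset)
        mask = np.array([
            ref.chain_id == pep_chain
            for r in s_complex.residues(chain_subset) for ref in [r.ref]
            for _ in r.atoms
        ])
        assert len(mask) == len(atoms)
        return float(areas[mask].sum())

    sasa_free = peptide_total(pmhc_ids)
    sasa_bound = peptide_total(list(s_complex.chain_ids))
    bsa = sasa_free - sasa_bound
    frac = 100.0 * bsa / sasa_free if sasa_free > 0 else 0.0
    # sampling noise can leave a tiny negative bsa for a non-contacting TCR
    if abs(bsa) < 1e-9:
        bsa = 0.0
        frac = 0.0
    return BurialReport(sasa_free=sasa_free, sasa_bound=sasa_bound,
                        bsa=bsa, burial_fraction=frac)
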