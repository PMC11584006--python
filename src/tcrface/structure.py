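"""Typed hierarchical structure model for TCR-pMHC complexes.

The model keeps only heavy (non-hydrogen) atoms of standard amino acids,
with author residue numbering preserved verbatim. Per-atom ``conf`` carries
either a crystallographic B-factor or a predictor confidence (pLDDT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "Chain",
    "StructureModel",
    "ChainRole",
    "ComplexAnnotation",
    "Loop",
    "select_atoms",
    "STANDARD_AA",
    "AA_THREE_TO_ONE",
]

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA = frozenset(AA_THREE_TO_ONE)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: label, element, coordinates (A), occupancy, confidence."""

    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    conf: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if self.element.upper() in ("H", "D"):
            raise ValueError(f"hydrogen atom {self.name!r} not allowed in model")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Author-numbered residue identity: (chain, number, insertion code)."""

    chain_id: str
    seq_num: int
    icode: str = ""
    aa: str = "X"

    # identity ignores the amino-acid letter so that refs from config files
    # (which may omit it) compare equal to refs from parsed structures
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueRef):
            return NotImplemented
        return (self.chain_id, self.seq_num, self.icode) == (
            other.chain_id, other.seq_num, other.icode)

    def __hash__(self) -> int:
        return hash((self.chain_id, self.seq_num, self.icode))

    def __str__(self) -> str:
        return f"{self.chain_id}{self.seq_num}{self.icode}"


@dataclass
class Residue:
    ref: ResidueRef
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.ref.seq_num == seq_num and r.ref.icode == icode:
                return r
        return None

    @property
    def sequence(self) -> str:
        return "".join(r.ref.aa for r in self.residues)


@dataclass
class StructureModel:
    """Ordered chains -> residues -> heavy atoms."""

    model_id: str
    chains: list[Chain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureModel needs at least one chain")
        seen: set[ResidueRef] = set()
        for ch in self.chains:
            for res in ch.residues:
                if res.ref in seen:
                    raise ValueError(f"duplicate residue {res.ref}")
                seen.add(res.ref)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residues(self, chain_ids: Iterable[str] | None = None) -> list[Residue]:
        wanted = None if chain_ids is None else set(chain_ids)
        out = []
        for ch in self.chains:
            if wanted is None or ch.chain_id in wanted:
                out.extend(ch.residues)
        return out

    def residue(self, ref: ResidueRef) -> Residue:
        res = self.chain(ref.chain_id).get(ref.seq_num, ref.icode)
        if res is None:
            raise KeyError(f"no residue {ref} in model {self.model_id!r}")
        return res

    def atom_count(self) -> int:
        return sum(len(r.atoms) for ch in self.chains for r in ch.residues)

    def coords(self, chain_ids: Iterable[str] | None = None) -> np.ndarray:
        rows = [a.xyz for r in self.residues(chain_ids) for a in r.atoms]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: Iterable[str] | None = None) -> "StructureModel":
        """Copy with ``x -> R x + t`` applied to the named chains (all if None)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        wanted = None if chain_ids is None else set(chain_ids)
        new_chains = []
        for ch in self.chains:
            if wanted is not None and ch.chain_id not in wanted:
                new_chains.append(Chain(ch.chain_id, [
                    Residue(r.ref, r.res_name, list(r.atoms)) for r in ch.residues]))
                continue
            new_res = []
            for r in ch.residues:
                new_atoms = [
                    replace(a, xyz=tuple(rotation @ np.asarray(a.xyz) + translation))
                    for a in r.atoms
                ]
                new_res.append(Residue(r.ref, r.res_name, new_atoms))
            new_chains.append(Chain(ch.chain_id, new_res))
        return StructureModel(self.model_id, new_chains, dict(self.meta))


class ChainRole(str, Enum):
    TCR_ALPHA = "tcr_alpha"
    TCR_BETA = "tcr_beta"
    MHC_HEAVY = "mhc_heavy"
    B2M = "b2m"
    PEPTIDE = "peptide"


class Loop(str, Enum):
    CDR1 = "CDR1"
    CDR2 = "CDR2"
    HV4 = "HV4"
    CDR3 = "CDR3"


#: IMGT-style default loop bounds on the variable-domain numbering; HV4 spans
#: the framework-3 hypervariable stretch. Always overridable via config.
DEFAULT_CDR_RANGES: dict[Loop, tuple[int, int]] = {
    Loop.CDR1: (27, 38),
    Loop.CDR2: (56, 65),
    Loop.HV4: (81, 86),
    Loop.CDR3: (105, 117),
}


@dataclass
class ComplexAnnotation:
    """Chain roles, CDR/HV4 loop intervals, and conserved disulfide cysteines.

    ``cdr_ranges`` maps (role, loop) -> inclusive author-number interval;
    ``disulfide_cys`` maps a TCR role to its two cysteine ResidueRefs.
    """

    roles: dict[str, ChainRole]
    cdr_ranges: dict[tuple[ChainRole, Loop], tuple[int, int]] = field(default_factory=dict)
    disulfide_cys: dict[ChainRole, tuple[ResidueRef, ResidueRef]] = field(default_factory=dict)
    #: optional author-number interval restricting the MHC platform (alpha1/alpha2)
    mhc_platform_range: tuple[int, int] | None = None

    def chains_with_role(self, role: ChainRole) -> list[str]:
        return [cid for cid, r in self.roles.items() if r == role]

    def chain_for_role(self, role: ChainRole) -> str:
        ids = self.chains_with_role(role)
        if len(ids) != 1:
            raise ValueError(f"expected exactly one {role.value} chain, found {ids}")
        return ids[0]

    def chains_for_roles(self, roles: Iterable[ChainRole]) -> list[str]:
        wanted = set(roles)
        return [cid for cid, r in self.roles.items() if r in wanted]

    def loop_of(self, ref: ResidueRef) -> tuple[ChainRole, Loop] | None:
        """The (role, loop) containing an author-numbered residue, or None."""
        role = self.roles.get(ref.chain_id)
        if role is None:
            return None
        for (r, loop), (lo, hi) in self.cdr_ranges.items():
            if r == role and lo <= ref.seq_num <= hi:
                return role, loop
        return None

    def validate(self, s: StructureModel) -> None:
        for cid in self.roles:
            if cid not in s.chain_ids:
                raise ValueError(f"annotated chain {cid!r} missing from structure")
        if len(self.chains_with_role(ChainRole.PEPTIDE)) != 1:
            raise ValueError("annotation must name exactly one peptide chain")
        n_a = len(self.chains_with_role(ChainRole.TCR_ALPHA))
        n_b = len(self.chains_with_role(ChainRole.TCR_BETA))
        if (n_a or n_b) and (n_a, n_b) != (1, 1):
            raise ValueError("TCR annotation needs exactly one alpha and one beta chain")
        for (role, loop), (lo, hi) in self.cdr_ranges.items():
            cid = self.chain_for_role(role)
            nums = [r.ref.seq_num for r in s.chain(cid).residues]
            if not nums or lo > hi or hi < min(nums) or lo > max(nums):
                raise ValueError(
                    f"{loop.value} interval [{lo},{hi}] outside chain {cid} "
                    f"numbering [{min(nums, default='?')},{max(nums, default='?')}]")
        for role, (c1, c2) in self.disulfide_cys.items():
            for ref in (c1, c2):
                res = s.residue(ref)
                if res.res_name != "CYS":
                    raise ValueError(f"disulfide residue {ref} is {res.res_name}, not CYS")


def select_atoms(
    s: StructureModel,
    selection: str,
    residues: Sequence[ResidueRef] | None = None,
) -> list[tuple[ResidueRef, AtomRecord]]:
    """Atoms of a named selection in deterministic file order.

    ``backbone`` = {N, CA, C, O}; ``all_heavy`` = every non-hydrogen atom;
    ``side_chain`` = all_heavy minus backbone.
    """
    if selection not in ("backbone", "all_heavy", "side_chain"):
        raise ValueError(f"unknown selection {selection!r}")
    wanted = None if residues is None else set(residues)
    if wanted is not None:
        present = {r.ref for r in s.residues()}
        missing = wanted - present
        if missing:
            raise KeyError(f"residues not in structure: {sorted(map(str, missing))}")
    out: list[tuple[ResidueRef, AtomRecord]] = []
    for ch in s.chains:
        for res in ch.residues:
            if wanted is not None and res.ref not in wanted:
                continue
            for a in res.atoms:
                is_bb = a.name in BACKBONE_ATOMS
                if selection == "backbone" and not is_bb:
                    continue
                if selection == "side_chain" and is_bb:
                    continue
                out.append((res.ref, a))
    return out
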