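"""Reading and writing coordinate files and annotation configs.

PDB and mmCIF parsing is delegated to gemmi; this layer filters to heavy
atoms of standard amino acids, resolves altlocs (highest occupancy wins,
ties broken by file order), and builds the typed :class:`StructureModel`.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi

from .structure import (
    AA_THREE_TO_ONE,
    STANDARD_AA,
    AtomRecord,
    Chain,
    ChainRole,
    ComplexAnnotation,
    Loop,
    Residue,
    ResidueRef,
    StructureModel,
)

__all__ = [
    "read_structure",
    "read_structures",
    "write_pdb",
    "load_annotation",
    "dump_annotation",
    "ParseError",
]


class ParseError(ValueError):
    """A coordinate or config file could not be parsed."""


def _detect_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")


def _convert_model(st_name: str, model: "gemmi.Model", model_id: str) -> StructureModel:
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            if gres.name not in STANDARD_AA:
                continue  # waters, ions, glycans, ligands dropped at read time
            # altloc resolution: per atom-name group keep the highest-occupancy
            # conformer; ties resolved by file order (first wins)
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            if not best:
                continue
            icode = gres.seqid.icode.strip()
            ref = ResidueRef(
                chain_id=gch.name,
                seq_num=gres.seqid.num,
                icode=icode,
                aa=AA_THREE_TO_ONE[gres.name],
            )
            atoms = [
                AtomRecord(
                    name=name,
                    element=best[name].element.name,
                    xyz=(best[name].pos.x, best[name].pos.y, best[name].pos.z),
                    occupancy=best[name].occ,
                    conf=best[name].b_iso,
                    altloc=(best[name].altloc or "").strip(),
                )
                for name in order
            ]
            residues.append(Residue(ref=ref, res_name=gres.name, atoms=atoms))
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))
    if not chains:
        raise ParseError(f"{st_name}: no standard protein residues found")
    return StructureModel(model_id=model_id, chains=chains)


def read_structures(path: str | Path, format: str = "auto") -> list[StructureModel]:
    """Read every model in a PDB/mmCIF file (one StructureModel per MODEL)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no models")
    base = st.name or path.stem
    out = []
    for i, model in enumerate(st):
        mid = base if len(st) == 1 else f"{base}#{i + 1}"
        out.append(_convert_model(str(path), model, mid))
    return out


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a single-model coordinate file (first model of multi-model files)."""
    return read_structures(path, format)[0]


def write_pdb(s: StructureModel, path: str | Path,
              conf_scale_to_bfactor: bool = True) -> None:
    """Write a StructureModel as a PDB file via gemmi.

    The B-factor column carries ``conf``; confidence on a 0-1 scale is
    multiplied by 100 on write so pLDDT round-trips on the 0-100 scale.
    """
    max_conf = max((a.conf for r in s.residues() for a in r.atoms), default=0.0)
    scale = 100.0 if (conf_scale_to_bfactor and max_conf <= 1.0) else 1.0
    st = gemmi.Structure()
    st.name = s.model_id
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.ref.seq_num, res.ref.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                ga.b_iso = a.conf * scale
                ga.altloc = a.altloc[0] if a.altloc else "\0"
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# annotation config

def annotate_complex(s: StructureModel, cfg: dict) -> ComplexAnnotation:
    """Bind a chain-role / CDR-range config to a structure.

    Config schema (JSON-compatible dict)::

        {"roles": {"A": "mhc_heavy", "B": "b2m", "C": "peptide",
                   "D": "tcr_alpha", "E": "tcr_beta"},
         "cdr_ranges": {"tcr_alpha": {"CDR1": [27, 38], ...}, "tcr_beta": {...}},
         "disulfides": {"tcr_alpha": [[23, ""], [104, ""]], ...},
         "mhc_platform_range": [1, 180]}   # optional
    """
    try:
        roles = {cid: ChainRole(role) for cid, role in cfg["roles"].items()}
    except KeyError as exc:
        raise ParseError("annotation config missing 'roles' section") from exc
    except ValueError as exc:
        raise ParseError(f"unknown chain role in config: {exc}") from exc

    cdr_ranges: dict[tuple[ChainRole, Loop], tuple[int, int]] = {}
    for role_name, loops in cfg.get("cdr_ranges", {}).items():
        role = ChainRole(role_name)
        for loop_name, (lo, hi) in loops.items():
            cdr_ranges[(role, Loop(loop_name))] = (int(lo), int(hi))

    disulfides: dict[ChainRole, tuple[ResidueRef, ResidueRef]] = {}
    for role_name, pair in cfg.get("disulfides", {}).items():
        role = ChainRole(role_name)
        cid = next(c for c, r in roles.items() if r == role)
        refs = tuple(
            ResidueRef(chain_id=cid, seq_num=int(num), icode=str(ic), aa="C")
            for num, ic in pair
        )
        if len(refs) != 2:
            raise ParseError(f"disulfide for {role_name} must list two cysteines")
        disulfides[role] = refs  # type: ignore[assignment]

    platform = cfg.get("mhc_platform_range")
    ann = ComplexAnnotation(
        roles=roles,
        cdr_ranges=cdr_ranges,
        disulfide_cys=disulfides,
        mhc_platform_range=tuple(platform) if platform else None,
    )
    try:
        ann.validate(s)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"annotation config invalid: {exc}") from exc
    return ann


def load_annotation(s: StructureModel, path: str | Path) -> ComplexAnnotation:
    with open(path) as fh:
        return annotate_complex(s, json.load(fh))


def dump_annotation(ann: ComplexAnnotation, path: str | Path) -> None:
    cfg: dict = {"roles": {cid: role.value for cid, role in ann.roles.items()}}
    cdr: dict[str, dict[str, list[int]]] = {}
    for (role, loop), (lo, hi) in ann.cdr_ranges.items():
        cdr.setdefault(role.value, {})[loop.value] = [lo, hi]
    if cdr:
        cfg["cdr_ranges"] = cdr
    if ann.disulfide_cys:
        cfg["disulfides"] = {
            role.value: [[c.seq_num, c.icode] for c in pair]
            for role, pair in ann.disulfide_cys.items()
        }
    if ann.mhc_platform_range:
        cfg["mhc_platform_range"] = list(ann.mhc_platform_range)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
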