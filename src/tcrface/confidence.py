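"""Interface-pLDDT computation, model ranking, and dual-cutoff triage.

Predictor confidence arrives per atom (B-factor column) or per model
(sidecar table). Residue pLDDT is the unweighted mean of a residue's
heavy-atom values; I-pLDDT is the unweighted mean of residue pLDDTs over
interface residues, defined side-symmetrically as residues with any heavy
atom within 4 A of the binding partner. Triage passes a model only when
model confidence > 0.875 AND I-pLDDT > 87.5, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import ChainRole, ComplexAnnotation, ResidueRef, StructureModel

__all__ = [
    "ModelScores",
    "TriageThresholds",
    "TriageVerdict",
    "detect_plddt_scale",
    "residue_plddt",
    "interface_residues",
    "iplddt",
    "rank_models",
    "triage",
    "enrichment_summary",
    "read_sidecar_scores",
]

INTERFACE_CUTOFF = 4.0  # A, heavy-atom rule defining interface residues


@dataclass
class ModelScores:
    model_id: str
    model_confidence: float
    iplddt: float | None = None  # 0-100 scale once computed
    plddt_scale: str = "0-100"   # scale the raw per-atom values were read on

    def __post_init__(self) -> None:
        if not 0.0 <= self.model_confidence <= 1.0:
            raise ValueError("model_confidence must lie in [0, 1]")
        if self.iplddt is not None and not 0.0 <= self.iplddt <= 100.0:
            raise ValueError("iplddt must lie in [0, 100]")


@dataclass(frozen=True)
class TriageThresholds:
    confidence_min: float = 0.875
    iplddt_min: float = 87.5


@dataclass(frozen=True)
class TriageVerdict:
    passed: bool
    failed_criteria: tuple[str, ...]


def detect_plddt_scale(values: Iterable[float]) -> tuple[str, float]:
    """('0-1'|'0-100', multiplier to reach 0-100).

    If every value is <= 1.0 the set is treated as a 0-1 scale and rescaled
    by 100; otherwise it is already on 0-100.
    """
    vmax = max(values, default=0.0)
    return ("0-1", 100.0) if vmax <= 1.0 else ("0-100", 1.0)


def residue_plddt(s: StructureModel) -> dict[ResidueRef, float]:
    """Per-residue pLDDT on the 0-100 scale: mean of heavy-atom conf values."""
    all_conf = [a.conf for r in s.residues() for a in r.atoms]
    _, mult = detect_plddt_scale(all_conf)
    out = {}
    for res in s.residues():
        if not res.atoms:
            raise ValueError(f"residue {res.ref} has no confidence values")
        out[res.ref] = float(np.mean([a.conf for a in res.atoms])) * mult
    return out


def interface_residues(
    s: StructureModel,
    ann: ComplexAnnotation,
    cutoff: float = INTERFACE_CUTOFF,
    sides: str = "both",
) -> list[ResidueRef]:
    """Residues with any heavy atom within ``cutoff`` of the other partner.

    The partition is TCR chains vs pMHC chains. ``sides`` may restrict the
    returned set to "tcr" or "pmhc"; the default pools both partners.
    """
    tcr_ids = ann.chains_for_roles({ChainRole.TCR_ALPHA, ChainRole.TCR_BETA})
    pmhc_ids = ann.chains_for_roles(
        {ChainRole.MHC_HEAVY, ChainRole.B2M, ChainRole.PEPTIDE})
    if not tcr_ids or not pmhc_ids:
        raise ValueError("both a TCR side and a pMHC side are required")

    def atoms_of(ids):
        return [(r.ref, a.xyz) for r in s.residues(ids) for a in r.atoms]

    at_t = atoms_of(tcr_ids)
    at_p = atoms_of(pmhc_ids)
    tree_p = cKDTree(np.array([x for _, x in at_p]))
    hits_t: set[ResidueRef] = set()
    hits_p: set[ResidueRef] = set()
    for i, nbrs in enumerate(
        tree_p.query_ball_point(np.array([x for _, x in at_t]), cutoff)
    ):
        if nbrs:
            hits_t.add(at_t[i][0])
            for j in nbrs:
                hits_p.add(at_p[j][0])
    if sides == "tcr":
        chosen = hits_t
    elif sides == "pmhc":
        chosen = hits_p
    else:
        chosen = hits_t | hits_p
    order = {r.ref: i for i, r in enumerate(s.residues())}
    return sorted(chosen, key=lambda ref: order[ref])


def iplddt(
    s: StructureModel,
    ann: ComplexAnnotation,
    cutoff: float = INTERFACE_CUTOFF,
    sides: str = "both",
) -> float:
    """Mean residue pLDDT over interface residues (0-100 scale)."""
    iface = interface_residues(s, ann, cutoff, sides)
    if not iface:
        raise ValueError("empty interface: no residues within cutoff")
    per_res = residue_plddt(s)
    return float(np.mean([per_res[ref] for ref in iface]))


def rank_models(scores: Sequence[ModelScores]) -> list[ModelScores]:
    """Descending by model confidence; ties broken by model_id."""
    if not scores:
        raise ValueError("no models to rank")
    return sorted(scores, key=lambda m: (-m.model_confidence, m.model_id))


def triage(m: ModelScores, t: TriageThresholds = TriageThresholds()) -> TriageVerdict:
    """Strict dual-cutoff verdict; boundary-exact scores fail."""
    if m.iplddt is None:
        raise ValueError(f"model {m.model_id}: iplddt not computed")
    failed = []
    if not m.model_confidence > t.confidence_min:
        failed.append("model_confidence")
    if not m.iplddt > t.iplddt_min:
        failed.append("iplddt")
    return TriageVerdict(passed=not failed, failed_criteria=tuple(failed))


def enrichment_summary(
    models: Sequence[tuple[ModelScores, str]],
    t: TriageThresholds = TriageThresholds(),
) -> pd.DataFrame:
    """CAPRI-class counts and fractions, for all models and the triage-passing
    subset. Rows: class; columns: (all|passing) x (count|fraction)."""
    if not models:
        raise ValueError("no models given")
    classes = ["High", "Medium", "Acceptable", "Incorrect"]
    rows = {}
    passing = [(m, c) for m, c in models if triage(m, t).passed]
    for label, subset in (("all", list(models)), ("passing", passing)):
        counts = {c: 0 for c in classes}
        for _, cls in subset:
            if cls not in counts:
                raise ValueError(f"unknown CAPRI class {cls!r}")
            counts[cls] += 1
        n = len(subset)
        rows[(label, "count")] = [counts[c] for c in classes]
        rows[(label, "fraction")] = [
            counts[c] / n if n else float("nan") for c in classes]
    return pd.DataFrame(rows, index=classes)


def read_sidecar_scores(path) -> list[ModelScores]:
    """Read a TSV sidecar with header columns model_id, model_confidence
    and optionally iplddt."""
    df = pd.read_csv(path, sep="\t")
    required = {"model_id", "model_confidence"}
    if not required <= set(df.columns):
        raise ValueError(f"sidecar must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(ModelScores(
            model_id=str(row["model_id"]),
            model_confidence=float(row["model_confidence"]),
            iplddt=float(row["iplddt"]) if "iplddt" in df.columns
            and not pd.isna(row.get("iplddt")) else None,
        ))
    return out
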