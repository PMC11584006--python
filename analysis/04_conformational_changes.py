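#!/usr/bin/env python
"""Bound/unbound conformational-change profiling on a synthetic ensemble.

Emulates the comparison of a TCR-bound peptide against an NMR-style ensemble
of unbound conformers: 10 perturbed copies of the fixture with larger
mobility at the peptide termini, profiled per position after superposing on
the MHC platform, plus the pooled CDR-loop RMSD of a perturbed unbound TCR.
Writes results/peptide_rmsd_profile.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tcrface import geometry as geo
from tcrface import synthetic as syn
from tcrface.structure import ChainRole

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    base, ann = syn.make_complex(syn.FixtureParams(
        crossing_deg=28.0, incident_deg=5.0, shift_A=-3.0, seed=1))

    pep_refs = [r.ref for r in base.chain("C").residues]
    # termini more mobile than the center, as for a groove-bound peptide
    n = len(pep_refs)
    amps = {ref: float(0.4 + 1.2 * abs(i - (n - 1) / 2) / ((n - 1) / 2))
            for i, ref in enumerate(pep_refs)}
    ensemble = syn.make_ensemble(base, amps, n_models=10, seed=2)

    rows = []
    for k, member in enumerate(ensemble, start=1):
        prof = geo.rmsd_profile(base, member, ann, ann,
                                [ChainRole.MHC_HEAVY], ChainRole.PEPTIDE)
        for ref, vals in prof.per_residue.items():
            rows.append({"model": k, "position": f"P{ref.seq_num}",
                         "backbone_rmsd": round(vals["backbone_rmsd"], 3),
                         "allatom_rmsd": round(vals["allatom_rmsd"], 3)})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "peptide_rmsd_profile.tsv", sep="\t", index=False)
    mean_by_pos = df.groupby("position", sort=False).backbone_rmsd.mean()
    print("mean backbone RMSD per peptide position over 10 unbound models:")
    for pos, v in mean_by_pos.items():
        print(f"  {pos}\t{v:.2f} A (set amplitude "
              f"{amps[pep_refs[int(pos[1:]) - 1]]:.2f} A)")

    # rigid-body TCR: small uniform CDR perturbation, frameworks fixed
    cdr_refs = {r.ref for cid in ("D", "E") for r in base.chain(cid).residues
                if ann.loop_of(r.ref) is not None}
    unbound_tcr = syn.make_ensemble(base, {ref: 0.55 for ref in cdr_refs},
                                    n_models=1, seed=3)[0]
    out = geo.cdr_rmsd(base, unbound_tcr, ann, ann)
    print(f"CDR loops, bound vs unbound TCR: backbone {out['backbone']:.2f} A, "
          f"all-atom {out['allatom']:.2f} A")


if __name__ == "__main__":
    main()
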