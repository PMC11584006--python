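#!/usr/bin/env python
"""Docking-geometry descriptors and generator parameter recovery.

Measures crossing angle, incident angle and peptide-axis shift on the saved
fixture, then sweeps a parameter grid (including the crystallographically
observed 28/5 and 28/7 degree combinations) and reports the worst recovery
error. Writes results/geometry_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from tcrface import geometry as geo
from tcrface import synthetic as syn
from tcrface.io import load_annotation, read_structure

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    s = read_structure(RESULTS / "fixtures" / "complex.pdb")
    ann = load_annotation(s, RESULTS / "fixtures" / "complex_annotation.json")
    g = geo.docking_geometry(s, ann)
    print(f"fixture: crossing {g.crossing_angle:.1f} deg, "
          f"incident {g.incident_angle:.1f} deg, shift {g.peptide_shift:.1f} A "
          "(targets 28.0 / 5.0 / -3.0)")

    rows = []
    for theta in (0.0, 10.0, 28.0, 45.0, 90.0, 135.0, 170.0):
        for phi in (0.0, 5.0, 7.0, 15.0, 30.0, 40.0):
            for shift in (-8.0, -3.0, 0.0, 4.0, 8.0):
                sg, anng = syn.make_complex(syn.FixtureParams(
                    crossing_deg=theta, incident_deg=phi, shift_A=shift))
                m = geo.docking_geometry(sg, anng)
                rows.append({
                    "crossing_set": theta, "incident_set": phi,
                    "shift_set": shift,
                    "crossing_meas": round(m.crossing_angle, 3),
                    "incident_meas": round(m.incident_angle, 3),
                    "shift_meas": round(m.peptide_shift, 3),
                })
    df = pd.DataFrame(rows)
    df["crossing_err"] = (df.crossing_meas - df.crossing_set).abs()
    df["incident_err"] = (df.incident_meas - df.incident_set).abs()
    df["shift_err"] = (df.shift_meas - df.shift_set).abs()
    df.to_csv(RESULTS / "geometry_recovery.tsv", sep="\t", index=False)
    print(f"grid: {len(df)} parameter triples; worst errors "
          f"crossing {df.crossing_err.max():.4f} deg, "
          f"incident {df.incident_err.max():.4f} deg, "
          f"shift {df.shift_err.max():.4f} A "
          "(tolerances 0.5 deg / 0.5 deg / 0.2 A)")


if __name__ == "__main__":
    main()
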