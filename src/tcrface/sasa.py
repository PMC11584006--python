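"""Numerical solvent-accessible surface area (Shrake-Rupley sampling).

Each heavy atom is expanded by the probe radius and sampled with a
deterministic Fibonacci sphere; the accessible fraction of sample points
times the expanded-sphere area gives the per-atom SASA.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["VDW_RADII", "sasa_points", "sasa_areas"]

#: Heavy-atom van der Waals radii (A), Bondi-style set used by common
#: SASA tools; NACCESS uses closely similar values.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


def sasa_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points (deterministic Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)          # polar angle
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i    # golden-angle azimuth
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_areas(
    coords: np.ndarray,
    elements: list[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible area (A^2) for heavy atoms.

    Raises ``KeyError`` naming the first atom whose element has no radius.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if len(elements) != len(coords):
        raise ValueError("one element per atom required")
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = el.upper()
        if key not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r} (atom {i})")
        radii[i] = VDW_RADII[key]

    expanded = radii + probe_radius
    sphere = sasa_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbors:
            nb = coords[neighbors]
            nb_r = expanded[neighbors]
            d2 = ((pts[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas
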