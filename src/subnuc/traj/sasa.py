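"""Shrake-Rupley solvent-accessible surface area.

Sphere-sampling estimate: each atom's accessible area is the fraction of
quasi-uniform test points on its probe-expanded sphere not buried inside
any neighbour's expanded sphere, times the expanded-sphere area.  Default
probe radius 1.4 Å (water).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..errors import InputError

#: van der Waals radii (Å) by element for standard inputs; coarse
#: pseudo-atoms should carry explicit per-atom radii instead.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
}


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def radii_from_elements(elements) -> np.ndarray:
    out = []
    for e in elements:
        key = str(e).strip().upper()[:1]
        if key not in VDW_RADII:
            raise InputError(f"no van der Waals radius for element {e!r}; "
                             "supply explicit radii")
        out.append(VDW_RADII[key])
    return np.array(out)


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (Å²) for one frame.

    ``selection`` restricts which atoms are reported; all atoms still act
    as occluders.  Total area is the sum of the returned values.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be (atoms, 3)")
    if radii.shape[0] != coords.shape[0]:
        raise InputError("one radius per atom required")
    sel = np.arange(coords.shape[0]) if selection is None else np.asarray(selection, int)

    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    areas = np.zeros(sel.size)
    for out_i, i in enumerate(sel):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.mean()
        areas[out_i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas
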