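"""Coarse toy subnucleosome particle with tunable unwrapping and tail dynamics.

The particle is deliberately minimal - just enough geometry and statistics
to exercise every trajectory metric with closed-form expectations:

* DNA: ``n_bp`` pseudo base pairs on an ideal left-handed superhelix
  (radius 41.9 Å, pitch 25.9 Å, 1.84 turns over 147 bp by default), with
  three heavy pseudo-atoms per bp (two backbone beads on strands I/J, one
  base bead).  ``unwrap_left`` / ``unwrap_right`` base pairs are released
  onto straight tangent lines, emulating the DNA opening that follows
  H2A/H2B dimer loss.
* Two H3 copies (chains A and E): a rigid 18-bead core segment (residues
  38-55) jittering about fixed positions, and a 37-bead disordered tail
  (residues 1-37) whose beads follow independent per-coordinate AR(1)
  processes about anchor points: x_f = a + rho*(x_{f-1} - a) +
  sqrt(1-rho^2)*N(0, sigma), so the stationary per-axis sd is exactly sigma
  and the fluctuation autocorrelation time is set by rho.

Chain A sits at the low-bp DNA entry (the side that unwraps in the hexasome
convention used here; the retained dimer sits on the high-bp side), chain E
at the high-bp entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import SpecificationError
from ..traj.core import Trajectory, TAIL_RANGE, CORE_INITIAL_RANGE

STRAND_OFFSET = 3.0          # Å, backbone beads off the helix midline
TAIL_SPACING = 2.0           # Å, anchor spacing along the tail exit line


def _as_sigma(value, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if (arr < 0).any():
        raise SpecificationError("tail fluctuation sd must be >= 0")
    return arr


@dataclass
class ToyParticleSpec:
    n_bp: int = 147
    dyad_bp: int = 74                  # 1-based
    radius: float = 41.9               # Å
    pitch: float = 25.9                # Å per superhelical turn
    turns: float = 1.84                # total turns over n_bp
    atoms_per_bp: int = 3
    unwrap_left: int = 0               # bp released on the low-bp side
    unwrap_right: int = 0
    tail_beads: int = 37
    tail_sigma: tuple = (2.0, 2.0)     # per chain (A, E); scalar or per-bead
    rho: float = 0.9                   # AR(1) frame-to-frame correlation
    core_jitter_sd: float = 0.1        # Å
    n_frames: int = 500
    frame_spacing_ps: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.unwrap_left < 0 or self.unwrap_right < 0:
            raise SpecificationError("unwrap counts must be >= 0")
        if self.unwrap_left + self.unwrap_right >= self.n_bp:
            raise SpecificationError("unwrap counts must leave wrapped DNA")
        if not 0 <= self.rho < 1:
            raise SpecificationError("need 0 <= rho < 1")
        if self.atoms_per_bp < 1:
            raise SpecificationError("need >= 1 pseudo-atom per bp")
        if self.n_frames < 1:
            raise SpecificationError("need >= 1 frame")
        if not 1 <= self.dyad_bp <= self.n_bp:
            raise SpecificationError("dyad_bp out of range")
        if self.core_jitter_sd < 0:
            raise SpecificationError("core jitter sd must be >= 0")


def _dna_centers(spec: ToyParticleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Base-pair center positions and local radial normals.

    Wrapped bp lie on the superhelix; unwrapped bp continue along the
    boundary tangent with the per-bp arc length preserved (normals frozen).
    """
    n = spec.n_bp
    dphi = 2.0 * np.pi * spec.turns / (n - 1)
    c = spec.pitch / (2.0 * np.pi)
    arc = dphi * np.sqrt(spec.radius ** 2 + c ** 2)

    def helix(i):  # 1-based bp index -> point on left-handed superhelix
        phi = (i - spec.dyad_bp) * dphi
        return np.array([spec.radius * np.cos(phi),
                         -spec.radius * np.sin(phi),
                         c * phi])

    def tangent(i):  # unit tangent in direction of increasing bp
        phi = (i - spec.dyad_bp) * dphi
        t = np.array([-spec.radius * np.sin(phi),
                      -spec.radius * np.cos(phi), c])
        return t / np.linalg.norm(t)

    def normal(i):
        phi = (i - spec.dyad_bp) * dphi
        return np.array([np.cos(phi), -np.sin(phi), 0.0])

    lo = spec.unwrap_left + 1            # first wrapped bp
    hi = n - spec.unwrap_right           # last wrapped bp
    centers = np.zeros((n, 3))
    normals = np.zeros((n, 3))
    for idx in range(1, n + 1):
        if idx < lo:
            centers[idx - 1] = helix(lo) - tangent(lo) * arc * (lo - idx)
            normals[idx - 1] = normal(lo)
        elif idx > hi:
            centers[idx - 1] = helix(hi) + tangent(hi) * arc * (idx - hi)
            normals[idx - 1] = normal(hi)
        else:
            centers[idx - 1] = helix(idx)
            normals[idx - 1] = normal(idx)
    return centers, normals


def _topology(spec: ToyParticleSpec) -> tuple[pd.DataFrame, dict]:
    """Atom table plus index bookkeeping for the coordinate builder."""
    rows = []
    # DNA: strand I backbone, strand J backbone, base bead (chain I)
    for bp in range(1, spec.n_bp + 1):
        rows.append(("I", bp, "DN", "P", True, "DNA"))
        rows.append(("J", bp, "DN", "P", True, "DNA"))
        if spec.atoms_per_bp >= 3:
            rows.append(("I", bp, "DN", "C1'", True, "DNA"))
    tail_lo, tail_hi = 1, spec.tail_beads
    core_lo, core_hi = CORE_INITIAL_RANGE
    for chain in ("A", "E"):
        for res in range(tail_lo, tail_hi + 1):
            rows.append((chain, res, "GLY", "CA", True, "tail"))
        for res in range(core_lo, core_hi + 1):
            rows.append((chain, res, "GLY", "CA", True, "core"))
    topo = pd.DataFrame(rows, columns=["chain", "resid", "resname", "atom",
                                       "heavy", "role"])
    idx = {
        "tail_A": topo.index[(topo["chain"] == "A") & (topo["role"] == "tail")].to_numpy(),
        "tail_E": topo.index[(topo["chain"] == "E") & (topo["role"] == "tail")].to_numpy(),
        "core": topo.index[topo["role"] == "core"].to_numpy(),
        "dna": topo.index[topo["role"] == "DNA"].to_numpy(),
    }
    return topo, idx


def simulate_particle_trajectory(spec: ToyParticleSpec) -> tuple[Trajectory, pd.DataFrame]:
    """Generate (trajectory, topology) for the toy particle.

    Deterministic for a given (spec, seed); frame count equals
    ``spec.n_frames``.
    """
    rng = np.random.default_rng(spec.seed)
    centers, normals = _dna_centers(spec)
    topo, _ = _topology(spec)
    n_atoms = len(topo)

    # static template coordinates
    template = np.zeros((n_atoms, 3))
    i_atom = 0
    for bp in range(spec.n_bp):
        template[i_atom] = centers[bp] + STRAND_OFFSET * normals[bp]; i_atom += 1
        template[i_atom] = centers[bp] - STRAND_OFFSET * normals[bp]; i_atom += 1
        if spec.atoms_per_bp >= 3:
            template[i_atom] = centers[bp]; i_atom += 1

    core_lo, core_hi = CORE_INITIAL_RANGE
    n_core = core_hi - core_lo + 1
    theta = np.linspace(0, np.pi, n_core)
    core_template = {
        "A": np.stack([10.0 * np.cos(theta), 10.0 * np.sin(theta),
                       -5.0 * np.ones(n_core)], axis=1),
        "E": np.stack([10.0 * np.cos(theta), -10.0 * np.sin(theta),
                       5.0 * np.ones(n_core)], axis=1),
    }

    # tail anchors: straight exit line from the DNA entry region outward
    def tail_anchors(entry_bp: int) -> np.ndarray:
        p = centers[entry_bp - 1]
        d = p / np.linalg.norm(p)
        anchors = np.zeros((spec.tail_beads, 3))
        for res in range(1, spec.tail_beads + 1):
            anchors[res - 1] = p + d * TAIL_SPACING * (spec.tail_beads - res)
        return anchors

    anchors = {"A": tail_anchors(min(7, spec.n_bp)),
               "E": tail_anchors(max(spec.n_bp - 6, 1))}
    sigma = {"A": _as_sigma(spec.tail_sigma[0], spec.tail_beads),
             "E": _as_sigma(spec.tail_sigma[1], spec.tail_beads)}

    chain_arr = topo["chain"].to_numpy()
    role_arr = topo["role"].to_numpy()
    tail_idx = {c: np.flatnonzero((chain_arr == c) & (role_arr == "tail"))
                for c in ("A", "E")}
    core_idx = {c: np.flatnonzero((chain_arr == c) & (role_arr == "core"))
                for c in ("A", "E")}
    for c in ("A", "E"):
        template[core_idx[c]] = core_template[c]
        template[tail_idx[c]] = anchors[c]

    coords = np.tile(template, (spec.n_frames, 1, 1))

    # core jitter
    if spec.core_jitter_sd > 0:
        all_core = np.concatenate([core_idx["A"], core_idx["E"]])
        coords[:, all_core, :] += rng.normal(
            0.0, spec.core_jitter_sd, size=(spec.n_frames, all_core.size, 3))

    # AR(1) tails, initialized at the stationary distribution
    rho = spec.rho
    innov = np.sqrt(1.0 - rho ** 2)
    for c in ("A", "E"):
        sd = sigma[c][:, None]                       # (beads, 1)
        a = anchors[c]
        x = a + rng.normal(0.0, 1.0, size=a.shape) * sd
        coords[0, tail_idx[c]] = x
        for f in range(1, spec.n_frames):
            x = a + rho * (x - a) + innov * rng.normal(0.0, 1.0, size=a.shape) * sd
            coords[f, tail_idx[c]] = x

    traj = Trajectory(coords=coords, frame_spacing_ps=spec.frame_spacing_ps)
    return traj, topo


# presets matching the three particle compositions ---------------------------

def nucleosome_spec(seed: int = 0, **kw) -> ToyParticleSpec:
    """Fully wrapped particle, symmetric moderate tail fluctuations."""
    return ToyParticleSpec(seed=seed, **kw)


def hexasome_spec(seed: int = 0, **kw) -> ToyParticleSpec:
    """One dimer lost: ~35 bp unwrapped on the low-bp side, with larger
    fluctuations for the adjacent (chain A) tail."""
    kw.setdefault("unwrap_left", 35)
    kw.setdefault("tail_sigma", (3.2, 2.0))
    return ToyParticleSpec(seed=seed, **kw)


def tetrasome_spec(seed: int = 0, **kw) -> ToyParticleSpec:
    """Both dimers lost: ~66 bp remain wrapped, both tails more dynamic."""
    kw.setdefault("unwrap_left", 40)
    kw.setdefault("unwrap_right", 41)
    kw.setdefault("tail_sigma", (3.2, 3.2))
    return ToyParticleSpec(seed=seed, **kw)
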