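"""Trajectory container, superposition and fluctuation/convergence metrics.

The trajectory is a plain (frames, atoms, 3) coordinate array in Å with a
topology table alongside (chain, residue, atom name, heavy flag, role tag).
H3 residues 1-37 are the disordered tail; 38-55 the initial core region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InputError, SpecificationError

TAIL_RANGE = (1, 37)
CORE_INITIAL_RANGE = (38, 55)

TOPOLOGY_COLUMNS = ["chain", "resid", "resname", "atom", "heavy", "role"]


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Å)."""

    coords: np.ndarray
    frame_spacing_ps: float = 10.0
    trimmed_fraction: float = 0.0       # bookkeeping only

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (frames, atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise InputError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def select(topo: pd.DataFrame, role: str | None = None, chain: str | None = None,
           heavy: bool | None = None, atom: str | None = None,
           resid_range: tuple[int, int] | None = None) -> np.ndarray:
    """Atom indices matching the given topology filters."""
    mask = np.ones(len(topo), dtype=bool)
    if role is not None:
        mask &= (topo["role"] == role).to_numpy()
    if chain is not None:
        mask &= (topo["chain"] == chain).to_numpy()
    if heavy is not None:
        mask &= (topo["heavy"].astype(bool) == heavy).to_numpy()
    if atom is not None:
        mask &= (topo["atom"] == atom).to_numpy()
    if resid_range is not None:
        lo, hi = resid_range
        mask &= ((topo["resid"] >= lo) & (topo["resid"] <= hi)).to_numpy()
    return np.flatnonzero(mask)


def trim_equilibration(traj: Trajectory, fraction: float = 0.4) -> Trajectory:
    """Drop the first floor(fraction * n_frames) frames as equilibration.

    Default 0.4 mirrors discarding the first 100 ns of 250 ns runs.
    """
    if not 0 <= fraction < 1:
        raise SpecificationError("trim fraction must be in [0, 1)")
    n_drop = int(np.floor(fraction * traj.n_frames))
    return Trajectory(coords=traj.coords[n_drop:],
                      frame_spacing_ps=traj.frame_spacing_ps,
                      trimmed_fraction=fraction)


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto
    reference in the least-squares sense: x -> (x - cm) @ R + cr."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    return rot, cr - cm @ rot


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(traj: Trajectory, selection: np.ndarray) -> tuple[Trajectory, np.ndarray]:
    """Least-squares fit every frame onto an iterated mean structure.

    The reference is obtained by aligning all frames to the first frame,
    averaging, then refining once: frames are re-aligned to that average and
    the average recomputed.  Improper rotations are never produced (mirror
    images keep a nonzero residual RMSD).  Returns the aligned trajectory
    and the per-frame RMSD over the selection.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise InputError("selection needs at least 3 atoms")
    first = traj.coords[0, sel]
    if np.linalg.matrix_rank(first - first.mean(axis=0)) < 2:
        raise InputError("selection is degenerate (collinear or coincident atoms)")

    def align_to(ref_sel: np.ndarray, coords: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            rot, t = kabsch(coords[f, sel], ref_sel)
            out[f] = coords[f] @ rot + t
        return out

    aligned = align_to(first, traj.coords)
    ref = aligned[:, sel].mean(axis=0)
    aligned = align_to(ref, aligned)        # one refinement pass
    ref = aligned[:, sel].mean(axis=0)

    rmsd = np.array([_rmsd(aligned[f, sel], ref) for f in range(aligned.shape[0])])
    return Trajectory(coords=aligned, frame_spacing_ps=traj.frame_spacing_ps,
                      trimmed_fraction=traj.trimmed_fraction), rmsd


# ---------------------------------------------------------------------------
# fluctuations


def rmsf_single(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Per-atom RMSF about the time-average position, sqrt(<|x - <x>|^2>)."""
    if traj.n_frames < 2:
        raise InputError("RMSF undefined for a single frame")
    sel = np.asarray(selection, dtype=int)
    x = traj.coords[:, sel]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))


def rmsf(replicates: list[Trajectory], selection: np.ndarray,
         resids: np.ndarray | None = None) -> pd.DataFrame:
    """Across-replicate mean and SEM of per-atom RMSF.

    ``resids`` optionally labels each selected atom with a residue number
    (one bead/Cα per residue in the coarse model).
    """
    sel = np.asarray(selection, dtype=int)
    profiles = np.stack([rmsf_single(t, sel) for t in replicates])  # (R, A)
    mean = profiles.mean(axis=0)
    n_rep = profiles.shape[0]
    sem = profiles.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.zeros_like(mean)
    out = pd.DataFrame({"rmsf": mean, "sem": sem})
    out.insert(0, "residue", resids if resids is not None else sel)
    return out


def rac(traj: Trajectory, taus: np.ndarray | None = None,
        selection: np.ndarray | None = None) -> pd.DataFrame:
    """RMS average correlation: convergence diagnostic on an aligned trajectory.

    For window length tau, running averages of the coordinates over
    [t, t+tau) are compared (plain RMSD, no refit) against the
    whole-trajectory average structure, and averaged over all N - tau + 1
    window starts.  RAC(1) is the mean per-frame RMSD to the average
    structure; RAC(N) is 0 by construction.
    """
    n = traj.n_frames
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if taus is None:
        taus = np.unique(np.linspace(1, n, min(n, 50)).astype(int))
    taus = np.asarray(taus, dtype=int)
    if (taus < 1).any() or (taus > n).any():
        raise SpecificationError("taus must be in [1, n_frames]")

    x = traj.coords[:, sel]
    avg = x.mean(axis=0)
    csum = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    values = []
    for tau in taus:
        win = (csum[tau:] - csum[:-tau]) / tau       # (N - tau + 1, A, 3)
        d = np.sqrt(np.mean(np.sum((win - avg) ** 2, axis=2), axis=1))
        values.append(float(d.mean()))
    return pd.DataFrame({"tau": taus, "rac": values})


def radius_of_gyration(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Mass-uniform radius of gyration per frame over the selection."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise InputError("empty selection")
    x = traj.coords[:, sel]
    centroid = x.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum((x - centroid) ** 2, axis=2), axis=1))
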