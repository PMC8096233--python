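"""Tail-DNA heavy-atom contacts and superhelical-location profiles.

A contact is a (tail heavy atom, DNA heavy atom) pair within the cutoff
(default 4.5 Å, inclusive).  Contacts are counted per frame, grouped by
(tail residue, DNA base pair), and reported as per-frame means; the "total
number of contacts" of a tail is the sum of those means over all
(residue, bp) cells, rounded to an integer for reporting.

Superhelical locations (SHL) index positions along nucleosomal DNA in
helical turns from the dyad (SHL 0): SHL(bp) = (bp - dyad) / 10 rounded to
the nearest half turn (half-up) and clamped to [-7, 7].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..errors import InputError
from .core import Trajectory, select

DEFAULT_CUTOFF = 4.5
DEFAULT_DYAD = 74


@dataclass
class ContactMatrix:
    """Time-averaged contact counts per tail: residue x base pair."""

    counts: dict[str, np.ndarray]      # chain -> (n_tail_res, n_bp)
    tail_resids: np.ndarray
    bp_index: np.ndarray               # 1-based
    cutoff: float
    n_frames: int

    def total(self, chain: str) -> int:
        """Summed per-frame mean contacts of one tail (integer report)."""
        return int(round(float(self.counts[chain].sum())))


def contacts(traj: Trajectory, topo: pd.DataFrame,
             cutoff: float = DEFAULT_CUTOFF) -> ContactMatrix:
    """Count tail-DNA heavy-atom contacts, averaged over frames."""
    if not topo["heavy"].astype(bool).any():
        raise InputError("no heavy atoms flagged in topology")
    dna_idx = select(topo, role="DNA", heavy=True)
    tail_chains = sorted(topo.loc[topo["role"] == "tail", "chain"].unique())
    if dna_idx.size == 0 or not tail_chains:
        raise InputError("need non-empty tail and DNA heavy-atom selections")

    bp_of_dna = topo.loc[dna_idx, "resid"].to_numpy()
    bp_index = np.unique(bp_of_dna)
    bp_pos = {bp: i for i, bp in enumerate(bp_index)}

    result = {}
    tail_resids = None
    for chain in tail_chains:
        t_idx = select(topo, role="tail", chain=chain, heavy=True)
        resids = topo.loc[t_idx, "resid"].to_numpy()
        if tail_resids is None:
            tail_resids = np.unique(resids)
        res_pos = {r: i for i, r in enumerate(tail_resids)}
        acc = np.zeros((tail_resids.size, bp_index.size))
        for f in range(traj.n_frames):
            tree = cKDTree(traj.coords[f, dna_idx])
            hits = tree.query_ball_point(traj.coords[f, t_idx], cutoff)
            for a, neigh in enumerate(hits):
                ri = res_pos[resids[a]]
                for j in neigh:
                    acc[ri, bp_pos[bp_of_dna[j]]] += 1.0
        result[chain] = acc / traj.n_frames
    return ContactMatrix(counts=result, tail_resids=tail_resids,
                         bp_index=bp_index, cutoff=cutoff,
                         n_frames=traj.n_frames)


def contacts_bruteforce(traj: Trajectory, topo: pd.DataFrame,
                        cutoff: float = DEFAULT_CUTOFF) -> ContactMatrix:
    """All-pairs O(n^2) reference implementation (testing oracle)."""
    dna_idx = select(topo, role="DNA", heavy=True)
    tail_chains = sorted(topo.loc[topo["role"] == "tail", "chain"].unique())
    bp_of_dna = topo.loc[dna_idx, "resid"].to_numpy()
    bp_index = np.unique(bp_of_dna)
    bp_pos = np.searchsorted(bp_index, bp_of_dna)

    result = {}
    tail_resids = None
    for chain in tail_chains:
        t_idx = select(topo, role="tail", chain=chain, heavy=True)
        resids = topo.loc[t_idx, "resid"].to_numpy()
        if tail_resids is None:
            tail_resids = np.unique(resids)
        res_pos = np.searchsorted(tail_resids, resids)
        acc = np.zeros((tail_resids.size, bp_index.size))
        for f in range(traj.n_frames):
            d = np.linalg.norm(
                traj.coords[f, t_idx][:, None, :] - traj.coords[f, dna_idx][None, :, :],
                axis=2)
            within = d <= cutoff
            for a, j in zip(*np.nonzero(within)):
                acc[res_pos[a], bp_pos[j]] += 1.0
        result[chain] = acc / traj.n_frames
    return ContactMatrix(counts=result, tail_resids=tail_resids,
                         bp_index=bp_index, cutoff=cutoff,
                         n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# superhelical locations


def shl_assign(bp_index: int, dyad: int = DEFAULT_DYAD,
               n_bp: int | None = None) -> float:
    """SHL of a 1-based bp index: (bp - dyad)/10 to nearest 0.5, clamped."""
    if bp_index < 1 or (n_bp is not None and bp_index > n_bp):
        raise InputError(f"bp index {bp_index} out of range")
    raw = (bp_index - dyad) / 10.0
    shl = np.floor(raw * 2.0 + 0.5) / 2.0          # half-up to nearest 0.5
    return float(np.clip(shl, -7.0, 7.0))


def shl_map(n_bp: int, dyad: int = DEFAULT_DYAD) -> pd.DataFrame:
    """Base-pair -> SHL table for a particle of n_bp base pairs."""
    bps = np.arange(1, n_bp + 1)
    return pd.DataFrame({"bp": bps,
                         "shl": [shl_assign(b, dyad, n_bp) for b in bps]})


def contacts_by_shl(cm: ContactMatrix, dyad: int = DEFAULT_DYAD) -> pd.DataFrame:
    """Sum the contact matrix columns into SHL bins, one row per SHL.

    Output columns: shl plus one column per tail chain.
    """
    shls = np.array([shl_assign(int(b), dyad) for b in cm.bp_index])
    grid = np.arange(-7.0, 7.5, 0.5)
    out = {"shl": grid}
    for chain, mat in cm.counts.items():
        per_bp = mat.sum(axis=0)
        out[chain] = [float(per_bp[shls == s].sum()) for s in grid]
    return pd.DataFrame(out)
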