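"""Trajectory and topology I/O.

Trajectories travel as multi-model PDB (MODEL/ENDMDL records; chains I/J
are the DNA strands, A/E the two H3 copies); the topology as TSV with
columns chain, resid, resname, atom, heavy, role.  PDB reading/writing is
delegated to biotite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ..errors import InputError
from .core import TOPOLOGY_COLUMNS, Trajectory

_ELEMENT_BY_ATOM = {"P": "P", "CA": "C", "C1'": "C"}


def write_topology_tsv(topo: pd.DataFrame, path) -> None:
    topo[TOPOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_topology_tsv(path) -> pd.DataFrame:
    topo = pd.read_csv(path, sep="\t")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in topo.columns]
    if missing:
        raise InputError(f"topology TSV missing columns: {missing}")
    topo["heavy"] = topo["heavy"].astype(bool)
    return topo


def write_trajectory_pdb(traj: Trajectory, topo: pd.DataFrame, path) -> None:
    """Write frames as a multi-model PDB."""
    n_atoms = traj.n_atoms
    if len(topo) != n_atoms:
        raise InputError("topology and trajectory atom counts differ")
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = topo["chain"].to_numpy(dtype="U4")
    stack.res_id = topo["resid"].astype(int).to_numpy()
    stack.res_name = topo["resname"].to_numpy(dtype="U5")
    stack.atom_name = topo["atom"].to_numpy(dtype="U6")
    stack.element = np.array(
        [_ELEMENT_BY_ATOM.get(a, a[:1]) for a in topo["atom"].astype(str)],
        dtype="U2",
    )
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path, topo: pd.DataFrame | None = None,
                        frame_spacing_ps: float = 10.0) -> tuple[Trajectory, pd.DataFrame]:
    """Read a multi-model PDB back into (trajectory, topology).

    If a topology table is not supplied, one is reconstructed from the PDB
    fields, with all atoms flagged heavy and roles inferred from the chain
    convention (I/J = DNA, A/E residues 1-37 = tail, others = core).
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):            # single model
        coords = stack.coord[None, :, :].astype(float)
        first = stack
    else:
        coords = stack.coord.astype(float)
        first = stack[0]
    if topo is None:
        chains = np.asarray(first.chain_id, dtype=str)
        resids = np.asarray(first.res_id, dtype=int)
        roles = np.where(
            np.isin(chains, ["I", "J"]), "DNA",
            np.where(resids <= 37, "tail", "core"),
        )
        topo = pd.DataFrame({
            "chain": chains,
            "resid": resids,
            "resname": np.asarray(first.res_name, dtype=str),
            "atom": np.asarray(first.atom_name, dtype=str),
            "heavy": np.ones(len(chains), dtype=bool),
            "role": roles,
        })
    if len(topo) != coords.shape[1]:
        raise InputError("topology and PDB atom counts differ")
    return Trajectory(coords=coords, frame_spacing_ps=frame_spacing_ps), topo
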