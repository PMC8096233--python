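"""Read-only access to BMRB NMR-STAR chemical-shift loops.

Deposited chemical shifts for the three particle species live in BMRB
entries 50805 (tetrasome), 50806 (nucleosome) and 50807 (hexasome).  This
module extracts the assigned-chemical-shift loop (``_Atom_chem_shift``)
from a downloaded NMR-STAR file and converts backbone amide H/N shifts into
a :class:`~subnuc.nmr.PeakList` for the shift-difference analysis.  Parsing
uses gemmi's STAR reader (NMR-STAR is a STAR dialect).
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError
from .nmr import PeakList


def read_nmr_star_shifts(path) -> pd.DataFrame:
    """Atom chemical shifts (residue, res_name, atom, shift_ppm) from an
    NMR-STAR file's Atom_chem_shift loop."""
    try:
        from gemmi import cif
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading NMR-STAR files requires gemmi") from exc

    doc = cif.read(str(path))
    rows = []
    tags = ["Seq_ID", "Comp_ID", "Atom_ID", "Val"]
    for block in doc:
        # NMR-STAR nests the shift loop inside a save frame; plain STAR
        # exports may carry it at block level - accept both
        containers = [block]
        containers.extend(item.frame for item in block if item.frame is not None)
        for container in containers:
            for row in container.find("_Atom_chem_shift.", tags):
                rows.append({
                    "residue": int(row[0]),
                    "res_name": str(row[1]),
                    "atom": str(row[2]),
                    "shift_ppm": float(row[3]),
                })
    if not rows:
        raise InputError(f"no _Atom_chem_shift loop found in {path}")
    return pd.DataFrame(rows)


def amide_peak_list(shifts: pd.DataFrame, species: str,
                    height: float = 1.0) -> PeakList:
    """Build an amide (H, N) peak list from a chemical-shift table.

    Residues missing either the H or the N shift are dropped; peak heights
    are not deposited, so a constant placeholder height is used.
    """
    h = shifts[shifts["atom"] == "H"][["residue", "shift_ppm"]]
    n = shifts[shifts["atom"] == "N"][["residue", "shift_ppm"]]
    m = h.merge(n, on="residue", suffixes=("_h", "_n"))
    if m.empty:
        raise InputError("no residues with both H and N shifts")
    data = pd.DataFrame({
        "residue": m["residue"].astype(int),
        "dH_ppm": m["shift_ppm_h"],
        "dN_ppm": m["shift_ppm_n"],
        "height": height,
    })
    return PeakList(species=species, data=data)
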