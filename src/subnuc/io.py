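"""Tabular I/O: gel tables, Sparky-style peak lists, relaxation series.

All tables are plain TSV.  The Sparky-style peak list uses an assignment
string of the form ``G33N-H`` (residue one-letter code + number) alongside
explicit ppm columns, which is what peak-picking software exports.
"""

from __future__ import annotations

import re

import pandas as pd

from .errors import InputError
from .nmr import PeakList
from .proteolysis import GEL_COLUMNS

_ASSIGNMENT_RE = re.compile(r"^[A-Za-z]?(\d+)")


def write_gel_tsv(gel: pd.DataFrame, path) -> None:
    cols = GEL_COLUMNS + [c for c in ("lane",) if c in gel.columns]
    gel[cols].to_csv(path, sep="\t", index=False)


def read_gel_tsv(path) -> pd.DataFrame:
    gel = pd.read_csv(path, sep="\t")
    missing = [c for c in GEL_COLUMNS if c not in gel.columns]
    if missing:
        raise InputError(f"gel TSV missing columns: {missing}")
    return gel


def write_peak_list_tsv(peaks: PeakList, path) -> None:
    d = peaks.data.copy()
    d.insert(1, "assignment", [f"X{int(r)}N-H" for r in d["residue"]])
    d.to_csv(path, sep="\t", index=False)


def read_peak_list_tsv(path, species: str) -> PeakList:
    d = pd.read_csv(path, sep="\t")
    if "residue" not in d.columns:
        if "assignment" not in d.columns:
            raise InputError("peak TSV needs a residue or assignment column")
        res = []
        for a in d["assignment"]:
            m = _ASSIGNMENT_RE.match(str(a))
            if not m:
                raise InputError(f"cannot parse assignment {a!r}")
            res.append(int(m.group(1)))
        d["residue"] = res
    d = d.drop(columns=[c for c in ("assignment",) if c in d.columns])
    return PeakList(species=species, data=d)


def write_relaxation_tsv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, sep="\t", index=False)


def read_relaxation_tsv(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t")
    for col in ("residue", "delay_ms", "height"):
        if col not in d.columns:
            raise InputError(f"relaxation TSV missing column {col!r}")
    return d
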