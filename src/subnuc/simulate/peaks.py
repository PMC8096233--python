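"""Synthetic amide peak lists for nucleosome / hexasome / tetrasome species.

Emulates the structure of the HSQC comparison: a shared set of H3 tail
residues, a nucleosome reference position per residue, a per-species shift
offset profile (tetrasome offset from nucleosome; hexasome carrying both a
nucleosome-like hex-N and a tetrasome-like hex-T peak per residue), and a
planted hex-T/hex-N peak-height fold asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import SpecificationError
from ..nmr import PeakList, csd


def default_reference_positions(residues, seed: int = 0) -> pd.DataFrame:
    """Plausible random-coil-like amide positions for the given residues.

    1H shifts drawn uniformly in 7.8-8.7 ppm and 15N in 108-126 ppm
    (typical disordered-tail amide region); deterministic for a given seed.
    """
    residues = np.asarray(list(residues), dtype=int)
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "residue": residues,
        "dH_ppm": rng.uniform(7.8, 8.7, size=residues.size),
        "dN_ppm": rng.uniform(108.0, 126.0, size=residues.size),
    })


@dataclass
class PeakSimSpec:
    """Planted truth for one set of species peak lists.

    ``offset_scale_h`` / ``offset_scale_n`` set the per-residue tetrasome
    offset magnitudes (Gaussian, ppm); defaults give a mean combined shift
    difference near the 0.09 ppm scale seen between the reference species.
    ``shift_noise_ppm`` is positional noise applied to the hexasome peaks
    around their parent reference positions (1H ppm; the 15N noise is scaled
    by 1/0.154 so both contribute equally to the combined difference).
    """

    residues: tuple = tuple(range(1, 37))
    reference: pd.DataFrame | None = None      # nucleosome positions
    offset_scale_h: float = 0.06               # ppm, 1H tetrasome offset sd
    offset_scale_n: float = 0.40               # ppm, 15N tetrasome offset sd
    min_separation_ppm: float = 0.02           # floor on nuc-tet combined offset
    fold_asymmetry: float = 2.4                # hex-T / hex-N height ratio
    base_height: float = 1.0e6
    height_noise_sd: float = 0.05              # multiplicative, fractional
    shift_noise_ppm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.residues) == 0:
            raise SpecificationError("empty residue range")
        if len(set(self.residues)) != len(self.residues):
            raise SpecificationError("residues must be unique")
        if self.fold_asymmetry <= 0:
            raise SpecificationError("fold-asymmetry must be > 0")
        if self.height_noise_sd < 0 or self.shift_noise_ppm < 0:
            raise SpecificationError("noise levels must be >= 0")


def simulate_peak_lists(spec: PeakSimSpec) -> dict[str, PeakList]:
    """Peak lists for nucleosome, tetrasome and hexasome.

    The hexasome list has two labelled entries per residue: hex-N at the
    nucleosome position and hex-T at the tetrasome position (plus optional
    positional noise), with hex-T heights ``fold_asymmetry`` times the hex-N
    heights before multiplicative height noise.
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.asarray(list(spec.residues), dtype=int)
    n = residues.size

    ref = spec.reference
    if ref is None:
        ref = default_reference_positions(residues, seed=spec.seed)
    ref = ref.set_index("residue").loc[residues].reset_index()

    # tetrasome offset profile, floored so every residue separates clearly
    off_h = rng.normal(0.0, spec.offset_scale_h, size=n)
    off_n = rng.normal(0.0, spec.offset_scale_n, size=n)
    sep = csd(off_h, off_n)
    low = sep < spec.min_separation_ppm
    if low.any():
        bump = np.where(sep[low] > 0, spec.min_separation_ppm / np.maximum(sep[low], 1e-12), 1.0)
        off_h[low] = np.where(sep[low] > 0, off_h[low] * bump, spec.min_separation_ppm)
        off_n[low] = off_n[low] * np.where(sep[low] > 0, bump, 0.0)

    def heights(size):
        base = spec.base_height * np.ones(size)
        if spec.height_noise_sd > 0:
            base = base * (1.0 + rng.normal(0.0, spec.height_noise_sd, size=size))
        return np.clip(base, 1.0, None)

    nuc = pd.DataFrame({
        "residue": residues,
        "dH_ppm": ref["dH_ppm"].to_numpy(),
        "dN_ppm": ref["dN_ppm"].to_numpy(),
        "height": heights(n),
    })
    tet = pd.DataFrame({
        "residue": residues,
        "dH_ppm": ref["dH_ppm"].to_numpy() + off_h,
        "dN_ppm": ref["dN_ppm"].to_numpy() + off_n,
        "height": heights(n),
    })

    def jitter(size):
        if spec.shift_noise_ppm == 0:
            return np.zeros(size), np.zeros(size)
        return (rng.normal(0.0, spec.shift_noise_ppm, size=size),
                rng.normal(0.0, spec.shift_noise_ppm / 0.154, size=size))

    jh_n, jn_n = jitter(n)
    jh_t, jn_t = jitter(n)
    hex_n_height = spec.base_height * np.ones(n)
    hex_t_height = spec.fold_asymmetry * hex_n_height
    if spec.height_noise_sd > 0:
        hex_n_height = hex_n_height * (1.0 + rng.normal(0.0, spec.height_noise_sd, n))
        hex_t_height = hex_t_height * (1.0 + rng.normal(0.0, spec.height_noise_sd, n))
    hexa = pd.DataFrame({
        "residue": np.concatenate([residues, residues]),
        "dH_ppm": np.concatenate([nuc["dH_ppm"] + jh_n, tet["dH_ppm"] + jh_t]),
        "dN_ppm": np.concatenate([nuc["dN_ppm"] + jn_n, tet["dN_ppm"] + jn_t]),
        "height": np.clip(np.concatenate([hex_n_height, hex_t_height]), 1.0, None),
        "subset": ["hex-N"] * n + ["hex-T"] * n,
    })

    return {
        "nucleosome": PeakList("nucleosome", nuc),
        "tetrasome": PeakList("tetrasome", tet),
        "hexasome": PeakList("hexasome", hexa),
    }
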