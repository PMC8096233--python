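"""Synthetic 15N relaxation decay series.

Peak heights follow a single-exponential decay without offset,
H(d) = H0 * exp(-d / T), plus additive Gaussian noise - the model the
relaxation fitting assumes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import SpecificationError


def simulate_relaxation(
    true_T: Mapping[int, float],
    delays: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    h0: float = 100.0,
) -> pd.DataFrame:
    """Relaxation series (residue, delay_ms, height) for planted T values.

    ``true_T`` maps residue number -> relaxation time (ms); ``delays`` may
    contain duplicates (independent repeat measurements).  ``noise_sd`` is
    additive on heights, in units of ``h0``-scaled intensity.
    """
    delays = np.asarray(list(delays), dtype=float)
    if (delays < 0).any():
        raise SpecificationError("delays must be non-negative")
    for res, t in true_T.items():
        if t <= 0:
            raise SpecificationError(f"residue {res}: true_T must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for res, t in true_T.items():
        clean = h0 * np.exp(-delays / float(t))
        noisy = clean + rng.normal(0.0, noise_sd, size=delays.size) if noise_sd else clean
        for d, h in zip(delays, noisy):
            rows.append({"residue": int(res), "delay_ms": float(d),
                         "height": float(h), "H0": h0})
    return pd.DataFrame(rows)
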