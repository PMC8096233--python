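"""Synthetic gel-densitometry tables for trypsin proteolysis time courses.

The generative model is the fitted model of the kinetic analysis: the
fraction of full-length H3 at time t is a weighted sum of single-exponential
decays, sum_j w_j * A0_j * exp(-k_j * t), plus Gaussian densitometry noise
(clamped at zero - band densities cannot be negative).  A hexasome built
from one nucleosome-like and one tetrasome-like tail is the half/half
two-state case.

Each replicate additionally carries a pre-digest reference lane
(lane="reference", the sample taken before enzyme addition) at the full
band volume; the kinetic analysis normalizes digest lanes to it.  A planted
intercept A0 < 1 therefore shows up as an apparent sub-unity fraction from
the first digest lane onward, emulating particles lost to dissociation
during mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import SpecificationError

#: paper-style digestion sampling grid (minutes)
DEFAULT_TIMEPOINTS = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0)

#: arbitrary densitometry scale for band volumes
VOLUME_SCALE = 10_000.0


@dataclass
class ProteolysisSimSpec:
    """Ground truth for one species' digestion time course.

    ``mixture_weights`` overrides (k_true, a0_true) with a multi-state model
    given as (k, A0, weight) triples; weights must sum to 1.
    """

    species: str
    k_true: float = 0.0                       # min^-1
    a0_true: float = 1.0                      # fraction in (0, 1]
    timepoints: tuple = DEFAULT_TIMEPOINTS    # min, strictly increasing, first 0
    replicates: int = 3
    noise_sd: float = 0.02                    # fraction units
    mixture_weights: list[tuple[float, float, float]] | None = None
    seed: int = 0
    scale: float = VOLUME_SCALE

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or t[0] != 0 or (np.diff(t) <= 0).any() or (t < 0).any():
            raise SpecificationError(
                "timepoints must be non-negative, strictly increasing, first = 0"
            )
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SpecificationError("need at least one replicate")
        if self.mixture_weights is not None:
            w = sum(w for _, _, w in self.mixture_weights)
            if abs(w - 1.0) > 1e-9:
                raise SpecificationError(f"mixture weights must sum to 1, got {w}")
            for k, a0, _ in self.mixture_weights:
                if k < 0 or not 0 < a0 <= 1:
                    raise SpecificationError("each state needs k >= 0 and 0 < A0 <= 1")
        else:
            if self.k_true < 0 or not 0 < self.a0_true <= 1:
                raise SpecificationError("need k_true >= 0 and 0 < a0_true <= 1")

    @property
    def states(self) -> list[tuple[float, float, float]]:
        if self.mixture_weights is not None:
            return list(self.mixture_weights)
        return [(self.k_true, self.a0_true, 1.0)]

    def decay_fraction(self, t) -> np.ndarray:
        """Noise-free model fraction at time(s) t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for k, a0, w in self.states:
            out = out + w * a0 * np.exp(-k * t)
        return out


def simulate_proteolysis(spec: ProteolysisSimSpec) -> pd.DataFrame:
    """Gel table (species, time_min, replicate, band, volume, lane).

    Digest-lane volumes are scale * (model(t) + N(0, noise_sd)) clamped at 0;
    the per-replicate reference lane is exactly scale * 1.0.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    model = spec.decay_fraction(t)
    rows = []
    for rep in range(1, spec.replicates + 1):
        rows.append({
            "species": spec.species, "time_min": 0.0, "replicate": rep,
            "band": "H3", "volume": spec.scale, "lane": "reference",
        })
        noisy = model + rng.normal(0.0, spec.noise_sd, size=t.size)
        noisy = np.clip(noisy, 0.0, None)
        for ti, fi in zip(t, noisy):
            rows.append({
                "species": spec.species, "time_min": float(ti), "replicate": rep,
                "band": "H3", "volume": float(spec.scale * fi), "lane": "digest",
            })
    return pd.DataFrame(rows)


# ready-made specs at the reference kinetic parameters ----------------------

def nucleosome_proteolysis_spec(seed: int = 0, **kw) -> ProteolysisSimSpec:
    """Nucleosome-state truth: k = 0.012 min^-1, A0 = 0.87."""
    return ProteolysisSimSpec(species="nucleosome", k_true=0.012, a0_true=0.87,
                              seed=seed, **kw)


def tetrasome_proteolysis_spec(seed: int = 0, **kw) -> ProteolysisSimSpec:
    """Tetrasome-state truth: k = 0.19 min^-1, A0 = 1.0."""
    return ProteolysisSimSpec(species="tetrasome", k_true=0.19, a0_true=1.0,
                              seed=seed, **kw)


def hexasome_proteolysis_spec(seed: int = 0, **kw) -> ProteolysisSimSpec:
    """Hexasome as the half-weighted sum of the two component decays."""
    return ProteolysisSimSpec(
        species="hexasome",
        mixture_weights=[(0.012, 0.87, 0.5), (0.19, 1.0, 0.5)],
        seed=seed, **kw,
    )
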