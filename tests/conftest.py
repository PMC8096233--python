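import numpy as np
import pandas as pd
import pytest

from subnuc.proteolysis import TimeCourse

#: digestion sampling grid used throughout (minutes)
TIMEPOINTS = np.array([0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0])


def make_timecourse(species, t, mean, sd=None, n_rep=3):
    """Assemble a TimeCourse directly from per-timepoint means."""
    t = np.asarray(t, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.zeros_like(mean) if sd is None else np.asarray(sd, dtype=float)
    rows = []
    for ti, mi in zip(t, mean):
        for rep in range(1, n_rep + 1):
            rows.append({"time_min": ti, "replicate": rep, "fraction": mi})
    return TimeCourse(species=species, timepoints=t, mean=mean, sd=sd,
                      fractions=pd.DataFrame(rows))


@pytest.fixture
def timepoints():
    return TIMEPOINTS.copy()


@pytest.fixture(scope="session")
def proteolysis_fit_ensemble():
    """Fitted kinetics over 50 seed pairs at the reference conditions.

    Shared across the acceptance tests: triplicate nucleosome-state
    (k=0.012, A0=0.87) and tetrasome-state (k=0.19, A0=1.0) courses at
    t = 0..50 min with 2% densitometry noise, refit with the constrained
    weighted exponential.
    """
    from subnuc.proteolysis import fit_exposure_kinetics, fraction_full_length
    from subnuc.simulate import (
        nucleosome_proteolysis_spec,
        simulate_proteolysis,
        tetrasome_proteolysis_spec,
    )

    fits = {"nucleosome": [], "tetrasome": []}
    for s in range(50):
        for name, factory, off in (
            ("nucleosome", nucleosome_proteolysis_spec, 0),
            ("tetrasome", tetrasome_proteolysis_spec, 1),
        ):
            gel = simulate_proteolysis(factory(seed=2 * s + off))
            fits[name].append(fit_exposure_kinetics(fraction_full_length(gel)))
    return fits
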