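import warnings

import numpy as np
import pytest

from bexfes.fes import BinningSpec, assign_microstates, reconstruct_fes
from bexfes.synthetic import (
    MetadSchedule,
    ToyLandscape,
    make_landscape,
    make_toy_peptide,
    sample_biased_replicas,
)

TWO_WELL_SPEC = ToyLandscape(
    cv_names=["cv1", "cv2"],
    wells=[([0.8, 0.8], 12.0, [0.25, 0.25]),
           ([2.2, 2.2], 7.0, [0.25, 0.25])],
    domain=[(0.0, 3.0), (0.0, 3.0)],
    temperature=350.0,
)


@pytest.fixture(scope="session")
def two_well_landscape():
    return make_landscape(TWO_WELL_SPEC, seed=1)


@pytest.fixture(scope="session")
def sampled_two_well(two_well_landscape):
    """A converged bias-exchange run on the two-well landscape.

    150k steps per replica with a 30k-step equilibration (deposition stops
    at t_eq) give free energies accurate to a couple of kJ/mol; built once
    per session because it takes ~10 s.
    """
    sched = MetadSchedule(gaussian_height=0.30, gaussian_width_per_cv=[0.2, 0.2],
                          deposition_stride=5, exchange_stride=20, t_eq=30000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        runs = sample_biased_replicas(two_well_landscape, sched, n_replicas=2,
                                      n_steps=150000, seed=1)
    spec = BinningSpec(["cv1", "cv2"], {"cv1": 0.2, "cv2": 0.2},
                       {"cv1": (0.0, 3.0), "cv2": (0.0, 3.0)}, t_eq=30000)
    occ = assign_microstates(runs, spec)
    fes = reconstruct_fes(occ, runs, spec, kT=TWO_WELL_SPEC.kT)
    return {"landscape": two_well_landscape, "schedule": sched, "runs": runs,
            "spec": spec, "occupancy": occ, "fes": fes}


@pytest.fixture(scope="session")
def helix40():
    return make_toy_peptide(40, "H" * 40, seed=0)


@pytest.fixture(scope="session")
def strand40():
    return make_toy_peptide(40, "E" * 40, seed=0)


@pytest.fixture(scope="session")
def coil10():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_peptide(10, "C" * 10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
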