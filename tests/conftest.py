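import numpy as np
import pytest

from serinepk.datatypes import DoseEvent, StructuralParams, grams_to_umol, make_subject
from serinepk.model import simulate_concentration


@pytest.fixture
def pop_params() -> StructuralParams:
    """Typical population ratio parameters of the analysis."""
    return StructuralParams(k_abs=2.88, f_over_v=0.00429, cl_over_v=0.288, kgen_over_v=29.6)


@pytest.fixture
def dose_20g() -> float:
    return grams_to_umol(20.0)


@pytest.fixture
def trial_doses(dose_20g):
    """Two 20 g boluses: t = 0 and 25.8 h (middle of the second-dose window)."""
    return [DoseEvent(0.0, dose_20g), DoseEvent(25.8, dose_20g)]


@pytest.fixture
def noiseless_subject(pop_params, trial_doses):
    """One subject sampled on the trial grid, exactly on the model curve."""
    times = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 25.8]
    conc = simulate_concentration(pop_params, trial_doses, times)
    return make_subject(
        "S01",
        [d.time for d in trial_doses],
        [d.amount for d in trial_doses],
        times,
        conc,
        weight=80.0,
        height=178.0,
    )


def random_one_compartment_params(rng: np.random.Generator) -> StructuralParams:
    """A random plausible parameter set (log-uniform around the trial scale)."""
    return StructuralParams(
        k_abs=float(np.exp(rng.uniform(np.log(0.3), np.log(10.0)))),
        f_over_v=float(np.exp(rng.uniform(np.log(5e-4), np.log(5e-2)))),
        cl_over_v=float(np.exp(rng.uniform(np.log(0.05), np.log(2.0)))),
        kgen_over_v=float(np.exp(rng.uniform(np.log(3.0), np.log(100.0)))),
    )
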