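import numpy as np
import pytest

import fullsib as fs
from fullsib.model import FullSibModel


@pytest.fixture
def balanced_records():
    """One moderate balanced dataset with h2 = 0.5 and independent errors."""
    config = fs.SimulationConfig(
        design=fs.NestedDesign.balanced(10, 5, 4),
        vc=fs.VarianceComponents.from_h2(0.5),
        mu=10.0,
        seed=123,
    )
    return fs.simulate_full_sib(config)


@pytest.fixture
def unbalanced_records():
    """A ragged design exercising the general estimator paths."""
    design = fs.NestedDesign(((3, 4, 2), (5, 1, 4), (2, 2), (6, 3, 2, 4), (4, 4, 3)))
    config = fs.SimulationConfig(
        design=design,
        vc=fs.VarianceComponents(0.3, 0.2, 0.6),
        mu=5.0,
        seed=11,
    )
    return fs.simulate_full_sib(config)


def fit_many(design, vc, method, n_reps, seed0, ar=None, ar_scope="dam"):
    """Component estimates over replicate simulations (rows: s2_s, s2_d, s2_e)."""
    if ar is None:
        ar = fs.ARErrorSpec.independent()
    out = np.empty((n_reps, 3))
    for rep in range(n_reps):
        rec = fs.simulate_full_sib(
            fs.SimulationConfig(
                design=design, vc=vc, ar=ar, ar_scope=ar_scope, seed=seed0 + rep
            )
        )
        res = FullSibModel.from_records(rec, validate=False).fit(method)
        out[rep] = (res.params.sigma_s2, res.params.sigma_d2, res.params.sigma_e2)
    return out
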