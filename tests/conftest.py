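import numpy as np
import pytest

from dmlmm import BasisSpec, DMFAArchitecture, LongitudinalDataset
from dmlmm.vi import VIEngine


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dataset(rng):
    """30 subjects from two sine groups with 6 irregular points each."""
    ids, ts, ys = [], [], []
    for i in range(30):
        t = np.sort(rng.uniform(0, 1, 6))
        g = rng.choice([-1.0, 1.0])
        ids.append(i)
        ts.append(t)
        ys.append(g * np.sin(2 * np.pi * t) + rng.normal(0, 0.3, 6))
    return LongitudinalDataset(ids, ts, ys)


@pytest.fixture
def small_engine(toy_dataset):
    """A briefly trained small engine for tests needing a sensible state."""
    spec = BasisSpec("legendre", 4, 0.0, 1.0)
    arch = DMFAArchitecture((4, 1), (2,))
    eng = VIEngine(toy_dataset, spec, arch, seed=7).init_state()
    for _ in range(15):
        eng.update_locals()
        eng.global_step(rho=1.0)
    return eng


@pytest.fixture
def fitted_small_model(toy_dataset):
    """A fitted estimator on the toy two-group data (fast settings)."""
    from dmlmm import DMLMM

    est = DMLMM(d=4, layer_dims=(1,), layer_components=(2,),
                domain=(0.0, 1.0), n_iter=120, batch_size=None,
                init_groups=2, random_state=5)
    return est.fit(toy_dataset)
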