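import numpy as np
import pytest

from octcyst.synthetic import PhantomSpec, SequenceSimSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_phantom_spec():
    return PhantomSpec(height=64, width=64, n_layers=3, n_cysts=1,
                       cyst_axes_range=(3, 6), speckle_sigma=0.0, seed=7)


def make_sim_spec(seed=0, T=31, n_patients=50, K=10, obs_total=300,
                  a11=0.8, a22=0.8, sign_flip_frac=0.0):
    """Simulation spec with distinct emission rows, seeded."""
    r = np.random.default_rng(seed + 777)
    B = r.dirichlet(np.ones(K), size=2)
    A = np.array([[a11, 1 - a11], [1 - a22, a22]])
    return SequenceSimSpec(A_true=A, pi_true=np.array([0.5, 0.5]), B_true=B,
                           T=T, n_patients=n_patients, obs_total=obs_total,
                           sign_flip_frac=sign_flip_frac, seed=seed)
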