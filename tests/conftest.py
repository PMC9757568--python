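import numpy as np
import pytest

import eeglevels as el

MONTAGE_16 = list(el.MONTAGE_62[:16])


def tiny_windows():
    """Three 15-second windows around ingestion (desk-scale unit tests)."""
    return [
        el.WindowSpec(1, -0.25, 0.0, 0),
        el.WindowSpec(2, 0.0, 0.25, 1),
        el.WindowSpec(3, 0.25, 0.5, 1),
    ]


def tiny_cohort_spec(seed=0, effect=None, n_subjects=4):
    return el.CohortSpec(
        n_subjects=n_subjects,
        montage=tuple(MONTAGE_16),
        n_latent_sources=4,
        session_start=-0.25,
        session_end=0.5,
        windows=tiny_windows(),
        effect=effect or el.null_effect(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four 16-channel subjects with 15-second windows, no planted effect."""
    spec = tiny_cohort_spec()
    return spec, el.generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort):
    spec, recordings = tiny_cohort
    return [s for r in recordings for s in el.split_windows(r, spec.windows)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(rng, n, p_edge=0.7):
    """Random symmetric nonnegative weight matrix with ~p_edge edge density."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < p_edge
    W[iu] = rng.uniform(0.1, 1.0, len(iu[0])) * mask
    return W + W.T
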