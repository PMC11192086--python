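import numpy as np
import pytest

from progspace.enumeration import enumerate_all_up_to, enumerate_unique
from progspace.programs import Program, validate
from progspace.task import TaskParams


@pytest.fixture(scope="session")
def params():
    return TaskParams()


@pytest.fixture(scope="session")
def m2_ensemble(params):
    ens = enumerate_unique(2, params)
    ens.evaluate()
    ens.sort()
    return ens


@pytest.fixture(scope="session")
def m3_ensemble(params):
    ens = enumerate_all_up_to(3, params)
    ens.evaluate()
    ens.sort()
    return ens


@pytest.fixture(scope="session")
def m4_ensemble(params):
    """Full M<=4 ensemble, evaluated; shared by the acceptance checks."""
    ens = enumerate_all_up_to(4, params)
    ens.evaluate()
    ens.sort()
    return ens


def random_valid_programs(size, n, seed, params=TaskParams()):
    """Seeded sample of distinct valid canonical programs of one size."""
    from progspace.programs import canonicalize

    rng = np.random.default_rng(seed)
    out = {}
    tries = 0
    while len(out) < n and tries < 100_000:
        tries += 1
        labels = tuple(rng.choice([-1, 1], size=size).tolist())
        t_lose = tuple(rng.integers(0, size, size=size).tolist())
        t_win = tuple(rng.integers(0, size, size=size).tolist())
        p = Program(labels, t_lose, t_win)
        if validate(p, params):
            c = canonicalize(p)
            out[c.canonical_id] = c
    return list(out.values())
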