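import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucoff as nc
from nucoff.markov import Generator

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fitted() -> nc.DimericParams:
    """LexA-like parameters fitted to the measured naked-DNA off-rate."""
    return nc.fit_naked_dimeric()


def random_generator(rng: np.random.Generator, n: int, scale: float = 1.0) -> Generator:
    """A random valid generator with one absorbing state (the last)."""
    R = rng.uniform(0.0, scale, size=(n, n))
    R[:, -1] = 0.0  # absorbing
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    labels = tuple(f"s{i}" for i in range(n))
    return Generator(labels, R, absorbing=frozenset({labels[-1]}))


@pytest.fixture
def make_random_generator():
    return random_generator


def enumerate_joint_lattice(spec, landscape, k0):
    """Independent brute-force joint-lattice builder (dict-of-dicts).

    Written deliberately as plain nested loops over explicit (p, n) tuples,
    sharing no code with the package's vectorized builder, so it can serve
    as an oracle for small instances.  Returns (labels, dense rate matrix).
    """
    n_max = landscape.n_max
    flank = spec.L - n_max
    f = spec.footprint

    def allowed(p, n):
        return 1 <= p <= spec.L - f + 1 and p + f - 1 + spec.d <= flank + n

    states = []
    for n in range(n_max + 1):
        for p in range(1, spec.L - f + 2):
            if allowed(p, n):
                states.append(("bound", p, n))
        states.append(("free", None, n))
    index = {s: i for i, s in enumerate(states)}
    R = np.zeros((len(states), len(states)))

    def add(src, dst, rate):
        i, j = index[dst], index[src]
        R[i, j] += rate
        R[j, j] -= rate

    kon = spec.ks_off / spec.kd_specific * spec.conc
    for kind, p, n in states:
        if kind == "bound":
            slide = spec.k1 / spec.K if p == spec.site_start else spec.k1
            for q in (p - 1, p + 1):
                if allowed(q, n):
                    add(("bound", p, n), ("bound", q, n), slide)
            off = spec.ks_off if p == spec.site_start else spec.K * spec.ks_off
            add(("bound", p, n), ("free", None, n), off)
            if n < n_max:
                ku = k0 * np.exp(-(landscape.dG[n + 1] - landscape.dG[n]))
                add(("bound", p, n), ("bound", p, n + 1), ku)
            if n > 0 and allowed(p, n - 1):
                add(("bound", p, n), ("bound", p, n - 1), k0)
        else:
            if n == 0:
                continue  # absorbing off state: no outgoing rates
            if n < n_max:
                ku = k0 * np.exp(-(landscape.dG[n + 1] - landscape.dG[n]))
                add(("free", None, n), ("free", None, n + 1), ku)
            add(("free", None, n), ("free", None, n - 1), k0)
            if kon > 0:
                for q in range(1, spec.L - f + 2):
                    if allowed(q, n):
                        add(("free", None, n), ("bound", q, n), kon)
    labels = tuple(
        f"{k}:{p}:{n}" if k == "bound" else f"{k}:{n}" for k, p, n in states
    )
    return labels, R


@pytest.fixture
def joint_lattice_oracle():
    return enumerate_joint_lattice
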