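import numpy as np
import pytest

from gammalethal.wright_fisher import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A very small population for fast reference-engine runs."""
    return SimConfig(N=20, U=0.5, R=10.0, s_mean=50.0, beta=0.4,
                     ne_assumed=20.0, burnin_generations=50, seed=7,
                     record_every=25, purge_every=10)


class ScriptedRNG:
    """Deterministic stand-in for a Generator: plays back scripted draws."""

    def __init__(self, poisson=(), uniform=(), integers=(), normal=()):
        self._poisson = list(poisson)
        self._uniform = list(uniform)
        self._integers = list(integers)
        self._normal = list(normal)

    def poisson(self, lam, size=None):
        return self._poisson.pop(0)

    def uniform(self, lo=0.0, hi=1.0, size=None):
        out = self._uniform.pop(0)
        return np.asarray(out) if size is not None else out

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self._normal.pop(0)


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG
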