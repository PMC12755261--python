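import numpy as np
import pytest

from cascade_chronos import BurstModel, CascadeSpec, GeneSpec


@pytest.fixture
def geom4():
    """Geometric burst law (support {0,1,...}) with mean 4: <b^2> = 36."""
    return BurstModel("geometric", 4.0)


@pytest.fixture
def make_gene(geom4):
    """Gene factory defaulting to the reference parameterization
    (gamma = 0.05/min, steady state 1000, geometric bursts of mean 4)."""

    def _make(
        steady_state=1000.0,
        alpha=0.5,
        gamma=0.05,
        burst=None,
        threshold=None,
    ):
        return GeneSpec.from_steady_state(
            steady_state=steady_state,
            burst=burst or geom4,
            gamma=gamma,
            threshold=threshold,
            relative_threshold=None if threshold is not None else alpha,
        )

    return _make


@pytest.fixture
def make_cascade(make_gene):
    def _make(n=1, alpha=0.5, gamma=0.05, steady_state=1000.0, burst=None):
        genes = tuple(
            make_gene(steady_state=steady_state, alpha=alpha, gamma=gamma, burst=burst)
            for _ in range(n)
        )
        return CascadeSpec(genes=genes, dilution_rate=gamma)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
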