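import numpy as np
import pytest

from bbgp.types import SnpSeries


def make_series(y, n, t, rep=None, snp_id="snp", **kw):
    """Shorthand SnpSeries constructor for tests."""
    y = np.asarray(y)
    if rep is None:
        rep = np.ones(y.shape, dtype=int)
    return SnpSeries(
        snp_id=snp_id, t=np.asarray(t, dtype=float), rep=np.asarray(rep),
        y=y, n=np.asarray(n), **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_series_factory(rng):
    """Random but valid SNP series over a replicated design."""

    def factory(n_reps=3, gens=(0, 14, 28, 44, 60), depth=45, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        t, rep = [], []
        for r in range(n_reps):
            for g in gens:
                t.append(g)
                rep.append(r + 1)
        t = np.asarray(t, dtype=float)
        n = local.poisson(depth, size=t.size)
        p = local.uniform(0.1, 0.9)
        y = local.binomial(n, p)
        return make_series(y, n, t, rep)

    return factory
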