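import numpy as np
import pytest

from tpwm.model_core import SiteAlignment, build_tpwm
from tpwm.scanner import BackgroundModel


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform()


def random_alignment(rng, n=240, width=4, correlated=True):
    """Random site alignment; optionally with a latent two-class pair so the
    builder has genuine structure to split on."""
    codes = np.empty((n, width), dtype=np.int8)
    for j in range(width):
        p = rng.dirichlet(np.ones(4) * rng.uniform(0.5, 4.0))
        codes[:, j] = rng.choice(4, size=n, p=p)
    if correlated and width >= 2:
        i, j = rng.choice(width, size=2, replace=False)
        z = rng.random(n) < 0.5
        codes[:, i] = np.where(z, 0, 2)
        noise = rng.random(n) < 0.1
        codes[:, j] = np.where(z ^ noise, 1, 3)
    return SiteAlignment(codes)


def random_tree(rng, width=None, n=240):
    """A random TPWM fixture built from a random alignment; low threshold and
    small min_leaf so most fixtures contain splits and missing branches."""
    width = width or int(rng.integers(3, 7))
    aln = random_alignment(rng, n=n, width=width, correlated=bool(rng.integers(2)))
    return build_tpwm(aln, min_leaf=40, threshold=0.05, pseudocount=0.5), aln


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
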