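import pytest
from hypothesis import settings

from wunifrac.fixtures import FixtureSpec, figure_fixtures, gen_labeled_tree

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def figs():
    return figure_fixtures()


def random_lt(seed, **kw):
    """Random labeled tree with mildly varied shape parameters per seed."""
    defaults = dict(
        n_leaves=4 + seed % 7,
        n_samples=2 + seed % 2,
        max_count=1 + seed % 5,
        seed=seed,
    )
    defaults.update(kw)
    return gen_labeled_tree(FixtureSpec(**defaults))
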