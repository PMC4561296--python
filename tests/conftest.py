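import numpy as np
import pytest

from generep.geneset import GeneSet, Universe, _clear_alias_warning_cache


@pytest.fixture(autouse=True)
def _fresh_alias_warnings():
    _clear_alias_warning_cache()
    yield
    _clear_alias_warning_cache()


@pytest.fixture
def small_universe() -> Universe:
    return Universe(genes=frozenset(f"G{i:04d}" for i in range(1, 2001)), name="small")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_set(name: str, genes, signs=None, **kw) -> GeneSet:
    direction = None
    if signs is not None:
        direction = dict(zip(genes, signs))
    return GeneSet(name=name, genes=frozenset(genes), direction=direction, **kw)
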