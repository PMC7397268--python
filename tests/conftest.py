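import numpy as np
import pytest

from otrcooper import BarrelSpec, Stave


@pytest.fixture
def rng():
    return np.random.default_rng(20_0731)


@pytest.fixture
def toy_body_spec():
    """Small body window for enumerable subset-sum tests: 300 ± 0.5 mm, bung > 100 mm."""
    return BarrelSpec(body_total_width=300.0, body_width_tolerance=0.5,
                      bung_min_width=100.0, head_count_allowed=frozenset({3, 5}))


@pytest.fixture
def toy_head_spec():
    """Small 300 mm disc taking 3-stave heads, for exhaustive ordering enumeration."""
    return BarrelSpec(head_diameter=300.0, head_count_allowed=frozenset({3}),
                      body_total_width=300.0, body_width_tolerance=0.5)


def make_body_stave(i, width, otr=0.03, length=960.0):
    return Stave(id=f"b{i}", part="body", width=width, length=length, otr=otr)


def make_head_stave(i, width, length, otr=0.03):
    return Stave(id=f"h{i}", part="head", width=width, length=length, otr=otr)


@pytest.fixture
def uniform_head_staves():
    """Eleven interchangeable head staves: width 67 mm, length 600 mm."""
    return [make_head_stave(i, 67.0, 600.0, otr=0.02 + 0.001 * i) for i in range(11)]
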