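import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from probopump import ChamberGeometry, refine_until_converged
from probopump.readwrite import load_table1

#: the illustrative dimensionless parameter grid (chamber elongations x
#: opening sizes) used for field-level cross-checks
RECT_GRID = [(a, g) for a in (0.4, 1.0, 1.24) for g in (0.05, 0.1, 0.3)]
CIRC_GRID = [0.05, 0.3, 1.0]


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def solve_cache():
    """Session-wide cache of converged adaptive solves, keyed by geometry."""
    cache = {}

    def get(shape, **kw):
        key = (str(shape), tuple(sorted(kw.items())))
        if key not in cache:
            ch = ChamberGeometry.from_dimensionless(shape, **kw)
            cache[key] = refine_until_converged(ch)
        return cache[key]

    return get
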