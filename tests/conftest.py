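import pytest

from agestage import Cohort, IndividualRecord, StageSchema


@pytest.fixture
def toy_schema() -> StageSchema:
    return StageSchema(
        stages=("egg", "female_adult"), reproductive_stages=("female_adult",)
    )


@pytest.fixture
def toy_cohort(toy_schema) -> Cohort:
    """Two-individual worked example used throughout the unit tests.

    ind1: egg on day 0, female adult on days 1-2 laying (2, 1) eggs, then
    dies.  ind2: egg on days 0-1, dies without developing.  Hand-derivable:
    l = (1, 1, 0.5), phi = (0, 1, 0.5), R0 = 1.5 and the intrinsic rate
    solves exp(-2r) + 0.5 exp(-3r) = 1.
    """
    return Cohort(
        schema=toy_schema,
        records=[
            IndividualRecord("ind1", [("egg", 0), ("female_adult", 2), ("female_adult", 1)]),
            IndividualRecord("ind2", [("egg", 0), ("egg", 0)]),
        ],
        label="toy",
    )


@pytest.fixture
def toy_r() -> float:
    """Independent root of the toy Euler-Lotka equation via np.roots.

    With u = exp(-r) the equation is 0.5 u^3 + u^2 - 1 = 0; the unique
    positive real root gives r = -ln(u).
    """
    import numpy as np

    roots = np.roots([0.5, 1.0, 0.0, -1.0])
    u = next(z.real for z in roots if abs(z.imag) < 1e-12 and z.real > 0)
    return float(-np.log(u))
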