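import numpy as np
import pytest
from hypothesis import settings

from polymuscle import PolynomialModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Wrist extension-flexion moment arm of extensor carpi ulnaris as a
#: degree-4 polynomial in wrist e-f (x1) and s-p (x2) angles, mm.
ECU_COEFFS = {
    (): -5.43,
    (1,): 2.14,
    (2,): 1.09,
    (1, 1): 2.27,
    (1, 2): 1.23,
    (2, 2): 0.69,
    (1, 1, 1): -1.23,
    (1, 1, 2): -1.27,
    (1, 2, 2): 0.41,
    (2, 2, 2): 0.16,
    (1, 1, 1, 2): 0.42,
    (1, 1, 2, 2): -0.41,
    (1, 2, 2, 2): -0.5,
    (2, 2, 2, 2): -0.12,
}


@pytest.fixture(scope="session")
def ecu_moment_arm() -> PolynomialModel:
    """The 14-coefficient ECU wrist moment-arm polynomial."""
    return PolynomialModel(2, ECU_COEFFS)


@pytest.fixture(scope="session")
def wrist_grid():
    """A 9-point 2-DOF wrist posture grid (e-f x s-p), 81 postures."""
    from polymuscle import DofSpec, make_grid

    dofs = [DofSpec("ra_wr_e_f", (-1.222, 1.222)),
            DofSpec("ra_wr_s_p", (-1.5708, 1.5708))]
    return dofs, make_grid(dofs, points=9)


def assert_structures_equal(got, expected):
    def fmt(S):
        return sorted(S, key=lambda t: (len(t), t))

    assert frozenset(got) == frozenset(expected), (
        f"structures differ: {fmt(got)} vs {fmt(expected)}"
    )
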