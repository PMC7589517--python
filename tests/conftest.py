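import numpy as np
import pytest

from bactoline import AssayConstants, BindingParams
from bactoline.simulate import STUDY_CONSTANTS, build_default_calibration


@pytest.fixture(scope="session")
def constants():
    """Plain assay constants (corr = 1): the unit-conversion reference."""
    return AssayConstants()


@pytest.fixture(scope="session")
def study_constants():
    """Constants of the default synthetic study (corr reconciles scales)."""
    return STUDY_CONSTANTS


@pytest.fixture(scope="session")
def default_params():
    return BindingParams(kd_app=1.5, epitope_total=10.0)


@pytest.fixture(scope="session")
def refit_cal(study_constants):
    """The default refit calibration map; built once, reused everywhere."""
    return build_default_calibration(study_constants)


def fixed_point_equilibrium(total_a, total_b, kd, tol=1e-15, max_iter=200_000):
    """Independent oracle for the 1:1 binding quadratic.

    Iterates the mass-action fixed point x <- A*B / (A + B + kd - x) for
    the complex concentration x (the contraction form converging to the
    physical root), stopping on the mass-action residual.  Deliberately
    avoids the closed-form solution used by the implementation.
    """
    a, b = float(total_a), float(total_b)
    s = a + b + kd
    x = 0.0
    for _ in range(max_iter):
        x_new = a * b / (s - x)
        if abs(x_new - x) < tol * max(x_new, 1e-300):
            x = x_new
            break
        x = x_new
    # residual check: (a-x)(b-x) == kd * x at the fixed point
    assert abs((a - x) * (b - x) - kd * x) < 1e-9 * max(kd * x, a * b * 1e-12)
    return x
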