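import numpy as np
import pytest

from cpgpal.equilibrium import (
    BindingParameters,
    TitrationCondition,
)

#: protein series of the standard titration design (nM)
PROTEIN_SERIES = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)
PROBE_NM = 50.0


@pytest.fixture
def titration_condition() -> TitrationCondition:
    return TitrationCondition(PROBE_NM, PROTEIN_SERIES)


@pytest.fixture
def reference_params() -> BindingParameters:
    return BindingParameters(kd_half_site=100.0, omega=5.0)


def bisection_free_protein(
    kd: float, omega: float, p_tot: float, d_tot: float, iters: int = 200
) -> float:
    """Independent brute-force solver: dense bisection on the conservation
    residual in free protein p over [0, P_tot]. Oracle for solve_species."""
    def residual(p: float) -> float:
        x = p / kd
        z = 1.0 + 2.0 * x + omega * x * x
        bound = d_tot * (2.0 * x + 2.0 * omega * x * x) / z
        return p + bound - p_tot

    lo, hi = 0.0, p_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fractions_from_free_protein(kd: float, omega: float, p: float) -> np.ndarray:
    x = p / kd
    z = 1.0 + 2.0 * x + omega * x * x
    return np.array([1.0, 2.0 * x, omega * x * x]) / z
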