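import numpy as np
import pytest

from stifflink import PolymerModel, Thermal

KT = 4.18


@pytest.fixture(scope="session")
def thermal() -> Thermal:
    return Thermal(kT=KT)


@pytest.fixture(scope="session")
def ssdna_wlc() -> PolymerModel:
    """15 nm ssDNA attachment handle, p = 1 nm."""
    return PolymerModel.wlc(15.0, 1.0)


@pytest.fixture(scope="session")
def dsdna_ewlc() -> PolymerModel:
    """Conventional 530 nm dsDNA linker, p = 50 nm, K = 1 nN."""
    return PolymerModel.ewlc(530.0, 50.0, 1000.0)


@pytest.fixture(scope="session")
def bundle_efjc() -> PolymerModel:
    """Rigid ten-helix bundle: two-segment eFJC, L = 485 nm, K = 10 nN."""
    return PolymerModel.efjc(485.0, 10000.0, 2)


def wlc_force_oracle(x: float, p: float, L: float, kT: float = KT) -> float:
    """Independent evaluation of the WLC interpolation formula."""
    z = x / L
    return (kT / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)


def wlc_extension_bisect(F: float, p: float, L: float, kT: float = KT,
                         tol: float = 1e-12) -> float:
    """Bisection oracle for the inverse WLC relation (no scipy)."""
    lo, hi = 0.0, L * (1.0 - 1e-12)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if wlc_force_oracle(mid, p, L, kT) < F:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def efjc_extension_oracle(F: float, L: float, K: float, n_seg: int,
                          kT: float = KT) -> float:
    """Hand evaluation of L (coth(Fb/kT) - kT/(Fb)) (1 + F/K)."""
    b = L / n_seg
    t = F * b / kT
    return L * (1.0 / np.tanh(t) - 1.0 / t) * (1.0 + F / K)
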