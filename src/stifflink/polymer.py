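"""Polymer elasticity laws for optical-tweezer tether elements.

Implements the standard entropic force-extension interpolation formulas used
for DNA constructs in single-molecule force spectroscopy:

* worm-like chain (WLC, Marko-Siggia interpolation) for short ssDNA handles,
* extensible WLC (eWLC) for conventional dsDNA linkers,
* extensible freely-jointed chain (eFJC) with a small number of Kuhn
  segments for rigid DNA-origami helix bundles,
* an inextensible rigid rod (used for the folded width of a hairpin).

All quantities are in nm, pN and pN nm; kT defaults to 4.18 pN nm (30 degC).
Elements combine mechanically in series: at common tension the extensions add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import quad

__all__ = [
    "PolymerModel",
    "Thermal",
    "wlc_force",
    "wlc_extension",
    "ewlc_extension",
    "efjc_extension",
    "extension",
    "series_extension",
    "force_at_extension",
    "stretch_energy",
]

#: Boltzmann constant times 303 K, pN nm.
KT_DEFAULT = 4.18

#: Rise per base pair of B-form DNA, nm.
NM_PER_BP = 0.34


@dataclass(frozen=True)
class Thermal:
    """Thermal energy scale kT in pN nm (default: 30 degC)."""

    kT: float = KT_DEFAULT

    def __post_init__(self) -> None:
        if not self.kT > 0:
            raise ValueError(f"kT must be positive, got {self.kT}")


@dataclass(frozen=True)
class PolymerModel:
    """One tether element: a parametric force-extension law.

    Parameters
    ----------
    kind :
        One of ``"wlc"``, ``"ewlc"``, ``"efjc"``, ``"rigid"``.
    contour_length :
        Fully stretched backbone length L, nm.
    persistence_length :
        Bending persistence length p, nm (wlc/ewlc).
    stretch_modulus :
        Enthalpic stretch modulus K, pN; ``inf`` means inextensible
        (plain WLC).
    n_segments :
        Number of Kuhn segments for the eFJC; ``n_segments=2`` with a large
        K models a rigid ten-helix bundle hinged at its center.
    """

    kind: str
    contour_length: float
    persistence_length: float | None = None
    stretch_modulus: float = math.inf
    n_segments: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("wlc", "ewlc", "efjc", "rigid"):
            raise ValueError(f"unknown polymer kind {self.kind!r}")
        if not self.contour_length > 0:
            raise ValueError("contour_length must be positive")
        if self.kind in ("wlc", "ewlc"):
            if self.persistence_length is None or not self.persistence_length > 0:
                raise ValueError(f"{self.kind} requires persistence_length > 0")
        if self.kind in ("ewlc", "efjc") and not self.stretch_modulus > 0:
            raise ValueError("stretch_modulus must be positive (or inf)")
        if self.kind == "efjc":
            if self.n_segments is None or self.n_segments < 1:
                raise ValueError("efjc requires n_segments >= 1")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def wlc(cls, contour_length: float, persistence_length: float) -> "PolymerModel":
        return cls("wlc", contour_length, persistence_length)

    @classmethod
    def ewlc(
        cls, contour_length: float, persistence_length: float, stretch_modulus: float
    ) -> "PolymerModel":
        return cls("ewlc", contour_length, persistence_length, stretch_modulus)

    @classmethod
    def efjc(
        cls, contour_length: float, stretch_modulus: float, n_segments: int
    ) -> "PolymerModel":
        return cls("efjc", contour_length, stretch_modulus=stretch_modulus,
                   n_segments=n_segments)

    @classmethod
    def rigid(cls, length: float) -> "PolymerModel":
        return cls("rigid", length)

    @property
    def kuhn_length(self) -> float:
        if self.kind != "efjc":
            raise AttributeError("kuhn_length only defined for efjc")
        return self.contour_length / self.n_segments


def _wlc_rel_force(z: float) -> float:
    """Marko-Siggia interpolation in reduced units: F p / kT as a function of x/L."""
    return 0.25 / (1.0 - z) ** 2 - 0.25 + z


def wlc_force(x, model: PolymerModel, thermal: Thermal = Thermal()):
    """WLC interpolation force at extension ``x`` (nm) -> pN.

    F(x) = (kT/p) [ 1/(4(1-x/L)^2) - 1/4 + x/L ];  valid for 0 <= x < L.
    """
    if model.kind != "wlc":
        raise ValueError("wlc_force requires a wlc model")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= model.contour_length):
        raise ValueError("extension must satisfy 0 <= x < contour_length")
    z = x / model.contour_length
    out = (thermal.kT / model.persistence_length) * (
        0.25 / (1.0 - z) ** 2 - 0.25 + z
    )
    return out if out.ndim else float(out)


def _wlc_rel_extension(f_red: float) -> float:
    """Invert the Marko-Siggia interpolation: x/L from reduced force F p / kT."""
    if f_red < 0:
        raise ValueError("force must be non-negative")
    if f_red == 0.0:
        return 0.0
    return optimize.brentq(
        lambda z: _wlc_rel_force(z) - f_red, 0.0, 1.0 - 1e-14, xtol=1e-15, rtol=1e-15
    )


def wlc_extension(F, model: PolymerModel, thermal: Thermal = Thermal()):
    """Inverse of :func:`wlc_force`: extension (nm) at tension F (pN)."""
    if model.kind != "wlc":
        raise ValueError("wlc_extension requires a wlc model")
    p, L, kT = model.persistence_length, model.contour_length, thermal.kT
    f = np.asarray(F, dtype=float)
    z = np.vectorize(lambda fi: _wlc_rel_extension(fi * p / kT))(f)
    out = L * z
    return float(out) if np.ndim(F) == 0 else out


def ewlc_extension(F, model: PolymerModel, thermal: Thermal = Thermal()):
    """Extensible WLC extension at tension F (pN) -> nm.

    Uses the Marko-Siggia interpolation written in the shifted variable
    l = x/L - F/K, so x = L (l(F) + F/K): entropic extension plus an
    enthalpic term that lets x exceed L at high load.
    """
    if model.kind != "ewlc":
        raise ValueError("ewlc_extension requires an ewlc model")
    p, L, K, kT = (model.persistence_length, model.contour_length,
                   model.stretch_modulus, thermal.kT)
    f = np.asarray(F, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    l = np.vectorize(lambda fi: _wlc_rel_extension(fi * p / kT))(f)
    out = L * (l + (f / K if math.isfinite(K) else 0.0))
    return float(out) if np.ndim(F) == 0 else out


def efjc_extension(F, model: PolymerModel, thermal: Thermal = Thermal()):
    """Extensible freely-jointed-chain extension at tension F (pN) -> nm.

    x(F) = L [coth(F b / kT) - kT/(F b)] (1 + F/K), with Kuhn length
    b = L / n_segments.  The two-segment, 10 nN variant models a rigid
    helix bundle that is effectively a stiff rod hinged at its middle.
    """
    if model.kind != "efjc":
        raise ValueError("efjc_extension requires an efjc model")
    L, K, b, kT = (model.contour_length, model.stretch_modulus,
                   model.kuhn_length, thermal.kT)
    f = np.asarray(F, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    t = f * b / kT
    # Langevin function, series for small argument to avoid cancellation
    small = t < 1e-4
    with np.errstate(over="ignore"):
        lang = np.where(small, t / 3.0 - t**3 / 45.0,
                        1.0 / np.tanh(np.where(small, 1.0, t))
                        - 1.0 / np.where(small, 1.0, t))
    out = L * lang * (1.0 + (f / K if math.isfinite(K) else 0.0))
    return float(out) if np.ndim(F) == 0 else out


def extension(F, model: PolymerModel, thermal: Thermal = Thermal()):
    """Extension of a single element at tension F, dispatching on kind."""
    if model.kind == "wlc":
        return wlc_extension(F, model, thermal)
    if model.kind == "ewlc":
        return ewlc_extension(F, model, thermal)
    if model.kind == "efjc":
        return efjc_extension(F, model, thermal)
    if model.kind == "rigid":
        out = np.full_like(np.asarray(F, dtype=float), model.contour_length)
        return float(out) if np.ndim(F) == 0 else out
    raise ValueError(model.kind)


def series_extension(F, chain: Sequence[PolymerModel] | PolymerModel,
                     thermal: Thermal = Thermal()):
    """Total extension of elements in mechanical series at common tension F."""
    if isinstance(chain, PolymerModel):
        chain = [chain]
    if not chain:
        raise ValueError("chain must be non-empty")
    f = np.asarray(F, dtype=float)
    total = sum(np.asarray(extension(f, m, thermal)) for m in chain)
    return float(total) if np.ndim(F) == 0 else total


def rest_length(chain: Sequence[PolymerModel] | PolymerModel) -> float:
    """Extension at zero force (rigid elements only contribute)."""
    if isinstance(chain, PolymerModel):
        chain = [chain]
    return sum(m.contour_length for m in chain if m.kind == "rigid")


def max_extension(chain: Sequence[PolymerModel] | PolymerModel,
                  f_max: float, thermal: Thermal = Thermal()) -> float:
    """Series extension at tension ``f_max`` (upper end of the usable domain)."""
    return float(series_extension(f_max, chain, thermal))


def force_at_extension(x: float, chain: Sequence[PolymerModel] | PolymerModel,
                       thermal: Thermal = Thermal(), f_max: float = 1e4) -> float:
    """Tension F (pN) at which the series chain reaches extension ``x`` (nm).

    Monotone bracketed root search; returns 0 for x at or below the chain's
    rest length.  Raises if x is unreachable below ``f_max``.
    """
    if isinstance(chain, PolymerModel):
        chain = [chain]
    if x <= rest_length(chain):
        return 0.0
    hi = series_extension(f_max, chain, thermal)
    if x >= hi:
        raise ValueError(
            f"extension {x} nm unreachable below {f_max} pN (max {hi:.3f} nm)"
        )
    return optimize.brentq(
        lambda f: series_extension(f, chain, thermal) - x, 0.0, f_max,
        xtol=1e-12, rtol=1e-12,
    )


def _wlc_energy_closed(x: float, model: PolymerModel, kT: float) -> float:
    # integral of the Marko-Siggia interpolation from 0 to x:
    # (kT/p) [ L z / (4(1-z)) - x/4 + x^2/(2L) ], z = x/L
    L, p = model.contour_length, model.persistence_length
    z = x / L
    return (kT / p) * (L * z / (4.0 * (1.0 - z)) - x / 4.0 + x * x / (2.0 * L))


def stretch_energy(x: float, model: Sequence[PolymerModel] | PolymerModel,
                   thermal: Thermal = Thermal()) -> float:
    """Stretching free energy E(x) = integral of F dx' from 0 (pN nm).

    Closed form for the pure WLC; otherwise computed through the Legendre
    transform E = F x - int_0^F x(F') dF' with adaptive quadrature, which
    avoids nesting root finds inside the integrand.
    """
    if isinstance(model, PolymerModel) and model.kind == "rigid":
        return 0.0
    if isinstance(model, PolymerModel) and model.kind == "wlc":
        if not 0 <= x < model.contour_length:
            raise ValueError("extension out of WLC domain")
        return _wlc_energy_closed(x, model, thermal.kT)
    chain = [model] if isinstance(model, PolymerModel) else list(model)
    if x <= rest_length(chain):
        return 0.0
    F = force_at_extension(x, chain, thermal)
    if F == 0.0:
        return 0.0
    integral, _ = quad(lambda f: series_extension(f, chain, thermal), 0.0, F,
                       limit=200)
    return F * x - integral
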