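"""Metropolis Monte-Carlo simulation of a dual-trap optical-tweezer assay.

Two beads sit in 3D anisotropic harmonic traps and are connected by a tether
of polymer elements in mechanical series (dsDNA, rigid helix bundles, ssDNA
handles), optionally interrupted by a two-state DNA hairpin.  All six bead
coordinates are perturbed simultaneously by uniform steps and accepted with
Boltzmann-weighted probability; in the pulling protocol one trap retreats by
a fixed increment after every accepted move, and traces are block-averaged
down to the output rate.

Hairpin kinetics: Metropolis time is not physical time, so hopping kinetics
are imposed as a telegraph process with user-supplied physical rates (the
bead ensemble is then sampled conditionally on the hidden state).  Without
imposed rates the hairpin state is itself a Metropolis degree of freedom, so
equilibrium occupancies remain Boltzmann-consistent.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid

from ._mc_kernel import _tether_energy, run_mc
from .io import Trace
from .polymer import (
    PolymerModel,
    Thermal,
    rest_length,
    series_extension,
    stretch_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrapModel",
    "HairpinModel",
    "AssayConfig",
    "SystemState",
    "TetherTable",
    "total_energy",
    "mc_step",
    "simulate_pull",
    "simulate_constant_distance",
    "downsample",
    "equilibrium_force",
    "separation_for_force",
    "calibrate_dG0",
    "tune_step_size",
]

FOLDED, UNFOLDED = 0, 1


@dataclass(frozen=True)
class TrapModel:
    """Anisotropic 3D harmonic optical trap.

    Axis convention: index 0 is the pulling axis and index 1 the second
    direction perpendicular to the laser beam (both with
    ``stiffness_perpendicular``); index 2 is along the beam
    (``stiffness_axial_beam``).
    """

    stiffness_perpendicular: float = 0.4
    stiffness_axial_beam: float = 0.04
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.stiffness_perpendicular > 0 and self.stiffness_axial_beam > 0):
            raise ValueError("trap stiffnesses must be positive")

    @property
    def k_vector(self) -> np.ndarray:
        return np.array(
            [
                self.stiffness_perpendicular,
                self.stiffness_perpendicular,
                self.stiffness_axial_beam,
            ]
        )


@dataclass(frozen=True)
class HairpinModel:
    """Two-state DNA hairpin inserted in the tether.

    When folded it contributes a short rigid segment of ``folded_width``;
    when unfolded it contributes ``released_nt`` nucleotides of ssDNA modeled
    as a WLC with ``ssdna_p`` persistence length and ``nm_per_nt`` contour
    per nucleotide.  ``dG0`` is the unfolding free energy at zero force
    (energy added to the unfolded state).
    """

    released_nt: int
    nm_per_nt: float = 0.59
    folded_width: float = 2.0
    ssdna_p: float = 1.0
    dG0: float = 0.0

    def __post_init__(self) -> None:
        if self.released_nt < 0:
            raise ValueError("released_nt must be >= 0")
        if not (self.nm_per_nt > 0 and self.folded_width > 0 and self.ssdna_p > 0):
            raise ValueError("hairpin lengths must be positive")

    @property
    def ssdna_contour(self) -> float:
        return self.released_nt * self.nm_per_nt

    def element(self, folded: bool) -> PolymerModel:
        if folded:
            return PolymerModel.rigid(self.folded_width)
        return PolymerModel.wlc(self.ssdna_contour, self.ssdna_p)

    def extension_change(self, force: float,
                         thermal: Thermal | None = None) -> float:
        """Analytic extension gained on unfolding at fixed tension (nm).

        WLC extension of the released ssDNA at ``force`` minus the folded
        hairpin width — the separation of the two populations along the
        extension axis at that load.
        """
        from .polymer import wlc_extension

        thermal = thermal or Thermal()
        x_ss = wlc_extension(force, self.element(False), thermal)
        return float(x_ss) - self.folded_width


@dataclass(frozen=True)
class AssayConfig:
    """Full dual-trap system configuration."""

    trap1: TrapModel = TrapModel()
    trap2: TrapModel = TrapModel()
    tether: tuple[PolymerModel, ...] = ()
    hairpin: HairpinModel | None = None
    thermal: Thermal = field(default_factory=Thermal)
    pulling_speed: float = 500.0  # nm/s
    mc_rate: float = 1e5  # Hz: one MC iteration per tick
    output_rate: float = 2e4  # Hz after block-mean downsampling
    step_size: float = 0.25  # nm, proposal half-width
    seed: int = 0
    f_max: float = 60.0  # pN, upper end of the tabulated tether domain

    def __post_init__(self) -> None:
        object.__setattr__(self, "tether", tuple(self.tether))
        factor = self.mc_rate / self.output_rate
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("mc_rate must be an integer multiple of output_rate")
        if self.pulling_speed < 0:
            raise ValueError("pulling_speed must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")

    @property
    def downsample_factor(self) -> int:
        return int(round(self.mc_rate / self.output_rate))

    @property
    def trap_separation(self) -> float:
        return float(self.trap2.center[0] - self.trap1.center[0])

    def with_separation(self, d: float) -> "AssayConfig":
        trap2 = replace(self.trap2, center=(self.trap1.center[0] + d,
                                            self.trap2.center[1],
                                            self.trap2.center[2]))
        return replace(self, trap2=trap2)

    def chain_for_state(self, folded: bool = True) -> tuple[PolymerModel, ...]:
        """Tether composition including the hairpin element for one state."""
        if self.hairpin is None:
            return self.tether
        return self.tether + (self.hairpin.element(folded),)

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class SystemState:
    """Instantaneous bead coordinates plus hidden hairpin state."""

    bead1: np.ndarray
    bead2: np.ndarray
    hairpin_folded: bool = True
    trap_separation: float = 0.0

    def __post_init__(self) -> None:
        self.bead1 = np.asarray(self.bead1, dtype=float)
        self.bead2 = np.asarray(self.bead2, dtype=float)
        if not (np.all(np.isfinite(self.bead1)) and np.all(np.isfinite(self.bead2))):
            raise ValueError("bead coordinates must be finite")


# ---------------------------------------------------------------------------
# tether energy tables


class TetherTable:
    """Tabulated stretching energy/tension of a series chain vs end distance.

    Energy is the integral of the series tension; evaluated by cubic Hermite
    interpolation in the MC kernel.  Distances above the extension at
    ``f_max`` are treated as forbidden (effectively infinite energy).
    """

    N_TABLE = 4096
    N_FINE = 16

    def __init__(self, chain: Sequence[PolymerModel], thermal: Thermal,
                 f_max: float = 60.0, dr: float | None = None):
        self.chain = tuple(chain)
        self.thermal = thermal
        self.f_max = f_max
        if not self.chain:
            # free beads: zero tether energy over a wide distance range
            self.r0 = 0.0
            self.r = np.linspace(0.0, 1e5, self.N_TABLE)
            self.dr = self.r[1] - self.r[0]
            self.E = np.zeros(self.N_TABLE)
            self.F = np.zeros(self.N_TABLE)
            return
        f_grid = np.concatenate([[0.0], np.geomspace(1e-5, f_max, 4095)])
        x_of_f = np.asarray(series_extension(f_grid, self.chain, thermal))
        r_hi = x_of_f[-1]
        # an externally imposed grid spacing lets two tables (folded/unfolded
        # hairpin) share one grid, as the MC kernel requires
        if dr is None:
            n_tab = self.N_TABLE
        else:
            n_tab = max(8, int(r_hi / dr) + 1)
            r_hi = dr * (n_tab - 1)
        n_fine = (n_tab - 1) * self.N_FINE + 1
        r_fine = np.linspace(0.0, r_hi, n_fine)
        F_fine = np.interp(r_fine, x_of_f, f_grid)
        E_fine = np.concatenate(
            [[0.0], cumulative_trapezoid(F_fine, r_fine)]
        )
        sub = slice(0, None, self.N_FINE)
        self.r = r_fine[sub]
        self.E = np.ascontiguousarray(E_fine[sub])
        self.F = np.ascontiguousarray(F_fine[sub])
        self.r0 = 0.0
        self.dr = self.r[1] - self.r[0]

    def energy(self, r: float) -> float:
        return float(_tether_energy(r, self.r0, self.dr, self.E, self.F))

    @property
    def r_max(self) -> float:
        return float(self.r[-1])


def _tables(config: AssayConfig) -> tuple[TetherTable, TetherTable]:
    """(folded, unfolded) tether tables on a shared grid spacing."""
    if config.hairpin is None:
        tf = TetherTable(config.chain_for_state(True), config.thermal,
                         config.f_max)
        return tf, tf
    r_hi = max(
        float(series_extension(config.f_max, config.chain_for_state(s),
                               config.thermal))
        for s in (True, False)
    )
    dr = r_hi / (TetherTable.N_TABLE - 1)
    tf = TetherTable(config.chain_for_state(True), config.thermal,
                     config.f_max, dr=dr)
    tu = TetherTable(config.chain_for_state(False), config.thermal,
                     config.f_max, dr=dr)
    return tf, tu


# ---------------------------------------------------------------------------
# energies and single steps (reference, table-free where practical)


def total_energy(state: SystemState, config: AssayConfig) -> float:
    """Total free energy: two trap terms + tether stretch (+ hairpin dG0).

    Exact (adaptive-quadrature) tether energy; the MC kernel uses the
    tabulated equivalent.  Overstretching the tether past the tabulated
    force range returns ``inf`` (the move will be rejected), not an error.
    """
    c1 = np.array(config.trap1.center)
    c2 = np.array(config.trap2.center)
    u1 = state.bead1 - c1
    u2 = state.bead2 - c2
    e = 0.5 * float(np.sum(config.trap1.k_vector * u1**2))
    e += 0.5 * float(np.sum(config.trap2.k_vector * u2**2))
    chain = config.chain_for_state(state.hairpin_folded)
    r = float(np.linalg.norm(state.bead2 - state.bead1))
    if chain:
        x_max = series_extension(config.f_max, chain, config.thermal)
        if r >= x_max:
            return math.inf
        e += stretch_energy(r, chain, config.thermal)
    if config.hairpin is not None and not state.hairpin_folded:
        e += config.hairpin.dG0
    return e


def mc_step(state: SystemState, config: AssayConfig,
            rng: np.random.Generator) -> tuple[SystemState, bool]:
    """One Metropolis step: perturb all six bead coordinates simultaneously.

    Proposals are uniform in ``[-n, n]`` per coordinate with n the configured
    step size; acceptance probability is ``min(1, exp(-dE/kT))``.  Rejected
    proposals return the input state object unchanged.
    """
    n = config.step_size
    prop = SystemState(
        bead1=state.bead1 + rng.uniform(-n, n, 3),
        bead2=state.bead2 + rng.uniform(-n, n, 3),
        hairpin_folded=state.hairpin_folded,
        trap_separation=state.trap_separation,
    )
    dE = total_energy(prop, config) - total_energy(state, config)
    if dE <= 0 or rng.random() < math.exp(-dE / config.thermal.kT):
        return prop, True
    return state, False


# ---------------------------------------------------------------------------
# deterministic force balance


def equilibrium_force(config: AssayConfig, separation: float | None = None,
                      folded: bool = True) -> float:
    """Tension at mechanical equilibrium for a given trap separation.

    Solves ``F/k1 + F/k2 + x_tether(F) = d`` along the pulling axis.
    """
    d = config.trap_separation if separation is None else separation
    chain = config.chain_for_state(folded)
    if not chain:
        raise ValueError("no tether elements configured")
    k1 = config.trap1.stiffness_perpendicular
    k2 = config.trap2.stiffness_perpendicular

    def gap(f: float) -> float:
        return f / k1 + f / k2 + series_extension(f, chain, config.thermal) - d

    if gap(0.0) >= 0:
        return 0.0
    if gap(config.f_max) <= 0:
        raise ValueError(
            f"separation {d} nm not reachable below f_max={config.f_max} pN"
        )
    return optimize.brentq(gap, 0.0, config.f_max, xtol=1e-12, rtol=1e-14)


def separation_for_force(config: AssayConfig, force: float,
                         folded: bool = True) -> float:
    """Trap separation at which the equilibrium tension equals ``force``."""
    chain = config.chain_for_state(folded)
    k1 = config.trap1.stiffness_perpendicular
    k2 = config.trap2.stiffness_perpendicular
    return float(force / k1 + force / k2
                 + series_extension(force, chain, config.thermal))


def _balanced_displacements(config: AssayConfig, d: float, folded: bool
                            ) -> tuple[np.ndarray, np.ndarray]:
    if not config.chain_for_state(folded):
        return np.zeros(3), np.zeros(3)
    f = equilibrium_force(config.with_separation(d), folded=folded)
    u1 = np.array([f / config.trap1.stiffness_perpendicular, 0.0, 0.0])
    u2 = np.array([-f / config.trap2.stiffness_perpendicular, 0.0, 0.0])
    return u1, u2


def calibrate_dG0(config: AssayConfig, separation: float | None = None
                  ) -> float:
    """Unfolding free energy dG0 that equalizes the two states' free energies.

    Integrates the configurational partition function over the two axial bead
    coordinates (transverse fluctuations contribute almost identically to
    both states) on the tabulated energies and returns
    ``dG0 = kT ln(Z_unfolded(dG0=0) / Z_folded)``.  With this value the
    hairpin occupancy at the given trap separation is 50 %.
    """
    if config.hairpin is None:
        raise ValueError("calibrate_dG0 requires a hairpin")
    d = config.trap_separation if separation is None else separation
    kT = config.thermal.kT
    tf, tu = _tables(config)
    f_mid = equilibrium_force(config, d, folded=True)
    k1 = config.trap1.stiffness_perpendicular
    k2 = config.trap2.stiffness_perpendicular
    # integration grid around the folded equilibrium, wide enough for both states
    s1 = math.sqrt(kT / k1)
    s2 = math.sqrt(kT / k2)
    pad = 8.0 + (config.hairpin.ssdna_contour + config.hairpin.folded_width)
    x1 = f_mid / k1 + np.linspace(-8 * s1 - pad, 8 * s1 + pad, 801)
    x2 = -f_mid / k2 + np.linspace(-8 * s2 - pad, 8 * s2 + pad, 801)
    X1, X2 = np.meshgrid(x1, x2, indexing="ij")
    R = d + X2 - X1

    def logZ(table: TetherTable) -> float:
        Et = np.interp(R, table.r, table.E, right=np.inf)
        E = 0.5 * k1 * X1**2 + 0.5 * k2 * X2**2 + Et
        w = np.exp(-(E - E.min()) / kT)
        return math.log(np.trapezoid(np.trapezoid(w, x2, axis=1), x1)) - E.min() / kT

    return kT * (logZ(tu) - logZ(tf))


# ---------------------------------------------------------------------------
# protocols


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _trace_from_kernel(config: AssayConfig, out, protocol: str,
                       seed: int, has_state: bool) -> Trace:
    sep, d1, d2, f, x, sfrac = out[:6]
    n_out = out[8]
    t = np.arange(n_out) / config.output_rate
    if has_state:
        state = np.where(sfrac == 0.0, 0.0, np.where(sfrac == 1.0, 1.0, np.nan))
    else:
        state = np.full(n_out, np.nan)
    meta = {
        "seed": seed,
        "sample_rate": config.output_rate,
        "mc_rate": config.mc_rate,
        "protocol": protocol,
        "config": config.digest(),
    }
    return Trace(time=t, trap_sep=sep[:n_out], defl1=d1[:n_out], defl2=d2[:n_out],
                 force=f[:n_out], extension=x[:n_out], state=state[:n_out],
                 meta=meta)


def simulate_pull(config: AssayConfig, max_force: float = 30.0,
                  start_force: float = 0.1, seed: int | None = None,
                  p_flip: float = 0.01) -> Trace:
    """Pulling protocol: the trap retreats by dx after every accepted move.

    dx = pulling_speed / mc_rate (0.005 nm at the defaults).  The run starts
    from mechanical equilibrium at ``start_force`` and stops once the trap
    separation reaches the deterministic balance point for ``max_force``.
    With a hairpin present the state hops in equilibrium (Metropolis flips).
    """
    if max_force <= 0:
        raise ValueError("max_force must be positive")
    seed = config.seed if seed is None else seed
    kseed = _spawn_seeds(seed, 1)[0]
    tf, tu = _tables(config)
    d0 = separation_for_force(config, start_force, folded=True)
    d_stop = separation_for_force(config, max_force, folded=True)
    dx = config.pulling_speed / config.mc_rate
    if dx <= 0:
        raise ValueError("pulling_speed must be positive for simulate_pull")
    n_max = int(3.0 * (d_stop - d0) / dx) + 10 * config.downsample_factor
    n_max -= n_max % config.downsample_factor
    u1, u2 = _balanced_displacements(config, d0, folded=True)
    dG = config.hairpin.dG0 if config.hairpin is not None else 0.0
    out = run_mc(
        kseed, n_max, config.downsample_factor,
        config.trap1.k_vector, config.trap2.k_vector,
        d0, dx, d_stop, config.step_size, config.thermal.kT,
        tf.r0, tf.dr, tf.E, tf.F, tu.E, tu.F, dG,
        np.empty(0, dtype=np.int8),
        p_flip if config.hairpin is not None else 0.0,
        FOLDED, u1, u2,
    )
    return _trace_from_kernel(config, out, "pull", seed,
                              config.hairpin is not None)


def _telegraph_states(k_fold: float, k_unfold: float, n_steps: int, dt: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Imposed hidden-state sequence: exponential dwells at MC resolution."""
    states = np.empty(n_steps, dtype=np.int8)
    if k_fold + k_unfold <= 0:
        states[:] = FOLDED
        return states
    p_unfolded = (k_unfold / (k_fold + k_unfold)) if (k_fold + k_unfold) else 0.0
    s = UNFOLDED if rng.random() < p_unfolded else FOLDED
    i = 0
    while i < n_steps:
        rate = k_unfold if s == FOLDED else k_fold
        if rate <= 0:
            states[i:] = s
            break
        ndw = max(1, int(round(rng.exponential(1.0 / rate) / dt)))
        j = min(n_steps, i + ndw)
        states[i:j] = s
        i = j
        s = 1 - s
    return states


def simulate_constant_distance(
    config: AssayConfig,
    duration: float,
    rates: tuple[float, float] | None = None,
    separation: float | None = None,
    seed: int | None = None,
    p_flip: float = 0.02,
    max_samples: float = 2e7,
) -> Trace:
    """Constant-trap-distance protocol.

    ``rates=(k_fold, k_unfold)`` imposes a physical telegraph process on the
    hairpin (dwell times exponential with the given rates); bead coordinates
    are sampled by Metropolis sweeps conditional on the current state.
    Without ``rates`` and with a hairpin, the state is a Metropolis degree of
    freedom (Boltzmann-consistent occupancy, unphysical time scale).
    """
    if duration * config.output_rate > max_samples:
        raise ValueError(
            f"requested {duration * config.output_rate:.3g} output samples "
            f"exceeds cap {max_samples:.3g}"
        )
    if rates is not None and config.hairpin is None:
        raise ValueError("rates given but no hairpin configured")
    seed = config.seed if seed is None else seed
    kseed, tseed = _spawn_seeds(seed, 2)
    d = config.trap_separation if separation is None else separation
    if d <= 0:
        raise ValueError("trap separation must be positive (set trap centers)")
    tf, tu = _tables(config)
    n_steps = int(round(duration * config.mc_rate))
    n_steps -= n_steps % config.downsample_factor
    if rates is not None:
        k_fold, k_unfold = rates
        rng = np.random.default_rng(tseed)
        states = _telegraph_states(k_fold, k_unfold, n_steps, 1.0 / config.mc_rate,
                                   rng)
        init_state = int(states[0])
        flip = 0.0
    else:
        states = np.empty(0, dtype=np.int8)
        init_state = FOLDED
        flip = p_flip if config.hairpin is not None else 0.0
    u1, u2 = _balanced_displacements(config, d, folded=(init_state == FOLDED))
    dG = config.hairpin.dG0 if config.hairpin is not None else 0.0
    out = run_mc(
        kseed, n_steps, config.downsample_factor,
        config.trap1.k_vector, config.trap2.k_vector,
        d, 0.0, 0.0, config.step_size, config.thermal.kT,
        tf.r0, tf.dr, tf.E, tf.F, tu.E, tu.F, dG,
        states, flip, init_state, u1, u2,
    )
    return _trace_from_kernel(config, out, "constant_distance", seed,
                              config.hairpin is not None)


def downsample(series: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means; a trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    series = np.asarray(series)
    factor = int(factor)
    if factor == 1:
        return series.copy()
    n = len(series) // factor
    if n * factor != len(series):
        logger.warning(
            "downsample: dropping trailing partial block of %d samples",
            len(series) - n * factor,
        )
    return series[: n * factor].reshape(n, factor).mean(axis=1)


def tune_step_size(config: AssayConfig, separation: float | None = None,
                   target: tuple[float, float] = (0.4, 0.6),
                   n_probe: int = 20000, seed: int = 12345) -> float:
    """Adjust the proposal half-width until acceptance lands in ``target``.

    Returns the tuned step size (the config itself is immutable).
    """
    d = config.trap_separation if separation is None else separation
    tf, tu = _tables(config)
    dG = config.hairpin.dG0 if config.hairpin is not None else 0.0
    step = config.step_size
    for _ in range(30):
        u1, u2 = _balanced_displacements(config, d, folded=True)
        out = run_mc(
            seed, n_probe, n_probe,
            config.trap1.k_vector, config.trap2.k_vector,
            d, 0.0, 0.0, step, config.thermal.kT,
            tf.r0, tf.dr, tf.E, tf.F, tu.E, tu.F, dG,
            np.empty(0, dtype=np.int8), 0.0, FOLDED, u1, u2,
        )
        acc = out[9] / n_probe
        lo, hi = target
        if lo <= acc <= hi:
            return step
        step *= 1.5 if acc > hi else 1 / 1.5
    return step
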