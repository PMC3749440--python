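"""Synthetic inputs: telegraph signals, preset assay configurations and
2D semiflexible-chain backbones with tracing noise.

The chain generator emulates negative-stain TEM data of DNA-origami helix
bundles adsorbed on a grid: chains are equilibrated in the plane, so the
tangent correlation is ``<t(0) t(s)> = exp(-s/2p)`` with ``p`` the 3D
persistence length, and the traced backbone acquires iid Gaussian vertex
jitter from the tracing step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polymer import NM_PER_BP, PolymerModel, Thermal
from .tweezer import AssayConfig, HairpinModel, TrapModel

__all__ = [
    "TelegraphSpec",
    "ChainSpec",
    "telegraph_signal",
    "chain_ensemble_2d",
    "preset_config",
    "PRESETS",
    "bundle_contour_length",
]

#: Scaffold length (bases) of the origami design; an N-helix bundle made from
#: it has contour length ~ (SCAFFOLD_BASES / N) * 0.34 nm.
SCAFFOLD_BASES = 7560


def bundle_contour_length(n_helices: int) -> float:
    """Expected contour length (nm) of an N-helix bundle from the scaffold."""
    return SCAFFOLD_BASES / n_helices * NM_PER_BP


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state telegraph signal with Gaussian observation noise.

    ``k12`` is the rate out of state 1, ``k21`` out of state 2 (1/s); the
    stationary occupancy of state 1 is ``k21/(k12+k21)``.
    """

    k12: float
    k21: float
    level1: float = 0.0
    level2: float = 3.0
    noise_sd: float = 0.5
    sample_rate: float = 2e4
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("rates must be >= 0")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")


def telegraph_signal(spec: TelegraphSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``(signal, states)``; states are 0 (level1) / 1 (level2).

    Dwell times are exponential with the state's exit rate; the observation
    adds iid Gaussian noise around the state level.  Fully seed-determined.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate
    states = np.empty(n, dtype=np.int8)
    total = spec.k12 + spec.k21
    p1 = spec.k21 / total if total > 0 else 1.0
    s = 0 if rng.random() < p1 else 1
    i = 0
    while i < n:
        rate = spec.k12 if s == 0 else spec.k21
        if rate <= 0:
            states[i:] = s
            break
        ndw = max(1, int(round(rng.exponential(1.0 / rate) / dt)))
        j = min(n, i + ndw)
        states[i:j] = s
        i = j
        s = 1 - s
    levels = np.array([spec.level1, spec.level2])
    signal = levels[states]
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, n)
    return signal, states


@dataclass(frozen=True)
class ChainSpec:
    """Ensemble of 2D-equilibrated semiflexible chains with tracing noise."""

    persistence_length: float
    contour_length: float
    n_segments: int = 50
    pixel_size: float = 2.0  # nm
    tracing_jitter_sd: float = 1.0  # pixels
    n_chains: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 10:
            raise ValueError("n_segments must be >= 10")
        if not (self.persistence_length > 0 and self.contour_length > 0):
            raise ValueError("p and L must be positive")


def chain_ensemble_2d(spec: ChainSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Generate ``(true_polylines, noisy_polylines)``; each an (n+1, 2) array.

    Tangent angles perform a Gaussian random walk with per-step variance
    ``ds/p``, giving ``<t(0) t(s)> = exp(-s/2p)`` — the 2D-equilibrated
    convention where ``p`` is the 3D persistence length.  The noisy copy adds
    iid Gaussian jitter ``tracing_jitter_sd * pixel_size`` to every vertex.
    """
    rng = np.random.default_rng(spec.seed)
    ds = spec.contour_length / spec.n_segments
    sigma_theta = np.sqrt(ds / spec.persistence_length)
    jitter = spec.tracing_jitter_sd * spec.pixel_size
    true_chains, noisy_chains = [], []
    for _ in range(spec.n_chains):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        dtheta = rng.normal(0.0, sigma_theta, spec.n_segments - 1)
        theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
        steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
        verts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        true_chains.append(verts)
        noisy_chains.append(verts + rng.normal(0.0, jitter, verts.shape))
    return true_chains, noisy_chains


# ---------------------------------------------------------------------------
# assay presets

_BUNDLE = PolymerModel.efjc(485.0, 10000.0, 2)
_SS_HANDLE = PolymerModel.wlc(15.0, 1.0)
_DSDNA = PolymerModel.ewlc(530.0, 50.0, 1000.0)

#: 6 bp stem x2 + 4 nt loop; 20 bp stem x2 + 4 nt loop.
_HAIRPIN6 = HairpinModel(released_nt=16)
_HAIRPIN20 = HairpinModel(released_nt=44)

PRESETS = (
    "dsDNA_linker",
    "tenhelix_linker",
    "tenhelix_hairpin6",
    "tenhelix_hairpin20",
    "dsDNA_hairpin6",
    "dsDNA_hairpin20",
    "control_no_hairpin",
)


def preset_config(name: str, seed: int = 0) -> AssayConfig:
    """Named assay configurations for the standard constructs.

    ``dsDNA_linker``: one 530 nm eWLC (p=50 nm, K=1 nN) for the whole tether.
    ``tenhelix_linker``: one rigid ten-helix bundle (two-segment eFJC,
    L=485 nm, K=10 nN) plus a 15 nm ssDNA attachment WLC (p=1 nm).
    Hairpin presets flank the hairpin with two such bundles (one ssDNA handle
    per bundle) or use the dsDNA tether; ``control_no_hairpin`` is the
    bundle-dimer construct with the linkers joined directly.
    """
    base = dict(trap1=TrapModel(), trap2=TrapModel(), thermal=Thermal(),
                seed=seed)
    if name == "dsDNA_linker":
        return AssayConfig(tether=(_DSDNA,), **base)
    if name == "tenhelix_linker":
        return AssayConfig(tether=(_BUNDLE, _SS_HANDLE), **base)
    if name == "tenhelix_hairpin6":
        return AssayConfig(tether=(_BUNDLE, _SS_HANDLE, _SS_HANDLE, _BUNDLE),
                           hairpin=_HAIRPIN6, **base)
    if name == "tenhelix_hairpin20":
        return AssayConfig(tether=(_BUNDLE, _SS_HANDLE, _SS_HANDLE, _BUNDLE),
                           hairpin=_HAIRPIN20, **base)
    if name == "dsDNA_hairpin6":
        return AssayConfig(tether=(_DSDNA,), hairpin=_HAIRPIN6, **base)
    if name == "dsDNA_hairpin20":
        return AssayConfig(tether=(_DSDNA,), hairpin=_HAIRPIN20, **base)
    if name == "control_no_hairpin":
        return AssayConfig(tether=(_BUNDLE, _SS_HANDLE, _SS_HANDLE, _BUNDLE),
                           **base)
    raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESETS)}")
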