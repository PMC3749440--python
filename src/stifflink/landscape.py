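"""Free-energy-landscape reconstruction from deflection statistics.

The measured extension histogram of a hopping construct is the convolution
of the underlying state density with the measurement point-spread function
(PSF) — the distribution the same bead/linker system produces when no
conformational transition is present.  The pipeline is:

1. histogram the constant-distance extension signal,
2. estimate the PSF from a hairpin-free control construct at similar load,
3. deconvolve (damped multiplicative Richardson-Lucy-type iteration,
   non-negative and normalized by construction, returning the iterate with
   the lowest reconvolution residual),
4. Boltzmann-invert ``G = -kT ln p`` above a density floor,
5. optionally map the extension axis to released ssDNA contour length via
   the WLC at the local force, with a small (|offset| <= 5 nm) shift that
   puts the folded minimum at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Trace
from .polymer import PolymerModel, Thermal, _wlc_rel_extension

__all__ = [
    "Histogram",
    "Psf",
    "Landscape",
    "deflection_histogram",
    "estimate_psf",
    "convolve",
    "deconvolve",
    "boltzmann_invert",
    "to_contour_length",
]


class LandscapeError(RuntimeError):
    pass


@dataclass
class Histogram:
    """Normalized density on uniform bins (sum(density) * bin_width = 1)."""

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.density = np.asarray(self.density, float)
        if len(self.bin_centers) != len(self.density):
            raise ValueError("bin_centers and density must match")
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, self.bin_width, rtol=1e-6):
            raise ValueError("bins must be uniform")

    def normalized(self) -> "Histogram":
        total = self.density.sum() * self.bin_width
        return Histogram(self.bin_centers, self.density / total, self.bin_width)


@dataclass
class Psf:
    """Centered measurement kernel on the same bin width as the data."""

    density: np.ndarray  # centered: index len//2 corresponds to zero shift
    bin_width: float
    sd: float
    force: float = np.nan

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, float)
        if np.any(self.density < 0):
            raise ValueError("PSF density must be non-negative")

    @classmethod
    def gaussian(cls, sd: float, bin_width: float, half_width: float = 5.0,
                 force: float = np.nan) -> "Psf":
        """Synthetic Gaussian kernel (for simulation work); extends to
        ``half_width`` SDs each side."""
        n = int(np.ceil(half_width * sd / bin_width))
        x = np.arange(-n, n + 1) * bin_width
        dens = np.exp(-0.5 * (x / sd) ** 2)
        dens /= dens.sum() * bin_width
        return cls(density=dens, bin_width=bin_width, sd=sd, force=force)


@dataclass
class Landscape:
    """Free energy vs a spatial coordinate, relative to the minimum.

    Bins whose density fell below the inversion floor carry NaN.
    """

    coordinate: np.ndarray
    G: np.ndarray  # pN nm
    coordinate_kind: str  # "extension" | "contour"

    def __post_init__(self) -> None:
        if self.coordinate_kind not in ("extension", "contour"):
            raise ValueError("coordinate_kind must be 'extension' or 'contour'")


def deflection_histogram(signal: np.ndarray, bin_width: float = 0.25,
                         limits: tuple[float, float] | None = None
                         ) -> Histogram:
    """Normalized density of a constant-distance extension signal.

    ``limits`` fixes the histogram support (snapped to bin-width multiples),
    e.g. to put several histograms on one grid; default spans the data.
    """
    signal = np.asarray(signal, float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if len(signal) < 1000:
        raise ValueError("need >= 1000 samples for a stable histogram")
    lo_raw, hi_raw = (signal.min(), signal.max()) if limits is None else limits
    lo = np.floor(lo_raw / bin_width) * bin_width
    hi = np.ceil(hi_raw / bin_width) * bin_width
    if hi - lo < bin_width:  # constant signal: one occupied bin
        hi = lo + bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(signal, bins=n_bins, range=(lo, hi),
                                 density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(bin_centers=centers, density=counts, bin_width=bin_width)


def _modes(density: np.ndarray, rel_height: float = 0.1) -> np.ndarray:
    """Indices of prominent local maxima above ``rel_height`` of the maximum.

    The density is lightly smoothed and peaks must be prominent (not noise
    wiggles) to count as modes of an empirical histogram.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import find_peaks

    d = uniform_filter1d(np.asarray(density, float), size=5, mode="nearest")
    peaks, _ = find_peaks(d, height=rel_height * d.max(),
                          prominence=rel_height * d.max())
    return peaks


def estimate_psf(control: Trace | np.ndarray, bin_width: float = 0.25
                 ) -> Psf:
    """Empirical PSF from a hairpin-free control at constant trap distance.

    The control extension signal is centered on its mean and histogrammed;
    a bimodal control (two modes above 10 % of the maximum separated by more
    than 3 bins) indicates contamination and raises.
    """
    if isinstance(control, Trace):
        signal = control.extension
        force = float(np.mean(control.force))
    else:
        signal = np.asarray(control, float)
        force = np.nan
    centered = signal - signal.mean()
    if np.ptp(centered) < bin_width:
        dens = np.array([1.0 / bin_width])
        return Psf(density=dens, bin_width=bin_width, sd=0.0, force=force)
    hist = deflection_histogram(centered, bin_width)
    modes = _modes(hist.density)
    if len(modes) >= 2 and (modes[-1] - modes[0]) > 3:
        raise LandscapeError(
            "control histogram is bimodal; control construct contaminated"
        )
    # symmetrize the support around zero so the kernel is centered
    m = len(hist.density)
    i0 = int(np.argmin(np.abs(hist.bin_centers)))
    half = max(i0, m - 1 - i0)
    dens = np.zeros(2 * half + 1)
    dens[half - i0 : half - i0 + m] = hist.density
    dens /= dens.sum() * bin_width
    return Psf(density=dens, bin_width=bin_width, sd=float(np.std(centered)),
               force=force)


def convolve(hist: Histogram, psf: Psf) -> Histogram:
    """Forward model: density blurred by the centered PSF (same grid)."""
    _check_grids(hist, psf)
    blurred = np.convolve(hist.density, psf.density, mode="same") * psf.bin_width
    return Histogram(hist.bin_centers, blurred, hist.bin_width).normalized()


def _check_grids(hist: Histogram, psf: Psf) -> None:
    if abs(hist.bin_width - psf.bin_width) > 1e-9 * hist.bin_width:
        raise ValueError("histogram and PSF must share the bin width")
    if len(psf.density) % 2 != 1:
        raise ValueError("PSF support must have odd length (centered kernel)")


def deconvolve(measured: Histogram, psf: Psf, damping: float = 0.5,
               max_iter: int = 100000, tol: float = 1e-8) -> Histogram:
    """Iterative constrained deconvolution of a deflection histogram.

    Damped multiplicative (Richardson-Lucy-type) update: each iterate is
    multiplied by the PSF-correlated ratio of measured to reconvolved
    density raised to ``damping``, which preserves non-negativity and is
    renormalized every step.  The undamped update is the classical
    Richardson-Lucy step; damping < 1 slows the approach to the spiky
    maximum-likelihood limit of this ill-conditioned problem and acts as
    regularization.  Iteration stops when the L2 reconvolution residual
    stops improving by more than ``tol`` (relative) over a patience window
    or at ``max_iter``; the iterate with the best residual is returned.
    A non-convergent run warns and still returns the best iterate.
    """
    _check_grids(measured, psf)
    measured = measured.normalized()
    m = measured.density
    q = psf.density * psf.bin_width  # discrete kernel, sums to 1
    if not 0 < damping <= 1:
        raise ValueError("damping must be in (0, 1]")
    if len(q) == 1:
        return Histogram(measured.bin_centers, m.copy(), measured.bin_width)
    q_flip = q[::-1]
    eps = 1e-300
    p = m.copy()
    best = p.copy()
    best_res = np.inf
    stalled = 0
    for _ in range(max_iter):
        c = np.convolve(p, q, mode="same")
        res = float(np.linalg.norm(c - m))
        if res < best_res * (1.0 - tol):
            best, best_res = p.copy(), res
            stalled = 0
        else:
            if res < best_res:
                best, best_res = p.copy(), res
            stalled += 1
            if stalled >= 50:
                break
        ratio = m / np.maximum(c, eps)
        corr = np.convolve(ratio, q_flip, mode="same")
        p = p * np.power(np.maximum(corr, eps), damping)
        total = p.sum() * measured.bin_width
        if total <= 0:
            break
        p /= total
    else:
        warnings.warn("deconvolution did not converge; returning best iterate")
    return Histogram(measured.bin_centers, best, measured.bin_width).normalized()


def boltzmann_invert(p: Histogram, thermal: Thermal = Thermal(),
                     floor: float = 1e-4) -> Landscape:
    """G(x) = -kT ln p(x), shifted so min(G) = 0.

    Bins with density below ``floor`` times the maximum are undefined (NaN)
    rather than infinite.
    """
    dens = p.normalized().density
    mask = dens > floor * dens.max()
    G = np.full(len(dens), np.nan)
    G[mask] = -thermal.kT * np.log(dens[mask])
    G -= np.nanmin(G)
    return Landscape(coordinate=p.bin_centers.copy(), G=G,
                     coordinate_kind="extension")


def to_contour_length(landscape: Landscape, elastic: PolymerModel,
                      force: float, offset: float = 0.0,
                      thermal: Thermal = Thermal()) -> Landscape:
    """Map the extension axis to released ssDNA contour length at fixed force.

    For a WLC at tension F the extension is proportional to contour length
    (x = L z(F)), so each extension bin maps to L = x / z(F).  ``offset``
    (|offset| <= 5 nm) then shifts the folded-state minimum to zero contour.
    """
    if landscape.coordinate_kind != "extension":
        raise ValueError("landscape must be in extension coordinates")
    if elastic.kind != "wlc":
        raise ValueError("elastic model must be a (ssDNA) WLC")
    if abs(offset) > 5.0:
        raise ValueError("offset magnitude exceeds 5 nm")
    z = _wlc_rel_extension(force * elastic.persistence_length / thermal.kT)
    if z <= 0:
        raise ValueError("force too low: extension-contour map not invertible")
    contour = landscape.coordinate / z - offset
    keep = contour >= 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} bins mapping to negative contour"
        )
    return Landscape(coordinate=contour[keep], G=landscape.G[keep].copy(),
                     coordinate_kind="contour")
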