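# Methods

## System and energy model

The assay is two beads in 3D harmonic optical traps connected by a tether of
polymer elements in mechanical series. Beads are treated as points at the
tether ends: the energy function has no bead-surface term, so the bead
radius matters only for contact-detection fixtures. Trap stiffness is
anisotropic — 0.4 pN/nm along the two directions perpendicular to the laser
beam (one of which is the pulling axis) and 0.04 pN/nm along the beam. The
total energy is

E = ½ Σ k_i (u_i − c_i)² (both beads, three axes) + E_tether(r) [+ ΔG₀],

with r the Euclidean bead–bead distance and E_tether the integral of the
series force–extension law. Tether elements:

| element | law | parameters |
|---|---|---|
| dsDNA linker | extensible WLC | p = 50 nm, L = 530 nm, K = 1 nN |
| ten-helix bundle | 2-segment extensible FJC | L = 485 nm, K = 10 nN |
| ssDNA handle | WLC | p = 1 nm, L = 15 nm |
| folded hairpin | rigid rod | 2.0 nm |
| unfolded hairpin | ssDNA WLC | released_nt × 0.59 nm, p = 1 nm |

The WLC uses the Marko–Siggia interpolation; the eWLC the substitution
l = x/L − F/K; the eFJC the Langevin form with Kuhn length b = L/n_segments
times (1 + F/K). A two-segment eFJC with K = 10 nN represents a rigid beam
hinged at its center. kT defaults to 4.18 pN·nm (30 °C) and is configurable.
Hairpin geometry (0.59 nm/nt, 4-nt loop, 2 nm folded width) are
literature-standard constants carried as configuration fields.

The double-bundle hairpin constructs place one 15 nm ssDNA handle per
bundle (two per construct); the single-bundle construct carries one,
matching the attachment chemistry of each design.

## Monte-Carlo scheme

All six bead coordinates are perturbed simultaneously by uniform steps in
[−n, +n] and accepted with probability min(1, e^(−ΔE/kT)). In the pulling
protocol one trap retreats by dx = pulling_speed / mc_rate (0.005 nm at the
defaults) after each accepted move; traces are recorded at mc_rate (100 kHz)
and block-mean downsampled to output_rate (20 kHz). Runs start from the
deterministic force balance F/k₁ + F/k₂ + x_tether(F) = d to avoid
transients.

For speed, the tether energy is pre-tabulated on a uniform grid of bead–bead
distances (4096 nodes, values + tensions, cubic Hermite interpolation; the
folded/unfolded variants share one grid spacing). Beyond the tabulated force
range (f_max = 60 pN) the energy continues with the end-point tension plus a
stiff quadratic wall: a constant "infinite" cap would zero the energy
*difference* between two out-of-domain states and let the walker diffuse
freely if an imposed refolding event strands the system past the folded
chain's domain. The Python-level `total_energy` (the reference
implementation) returns `inf` out of domain.

**Step size.** The default proposal half-width is 0.25 nm;
`tune_step_size` adjusts it to 40–60 % acceptance. The step size sets the
artificial MC time scale of the bead response: at 0.25 nm the extension
correlation time is ~3 ms (and ~25 ms for the weakly confined beam axis),
which is *not* small compared with typical hairpin dwell times and acts as a
low-pass filter on imposed hopping. Analyses that compare per-state
observables therefore use the tuned step (~2.8 nm for the stiff-linker
construct, bead response ~0.1 ms), which is the regime a real
microsecond-relaxation bead operates in.

**Hairpin kinetics.** Metropolis time is unphysical, so hopping kinetics are
imposed as a telegraph process with user-supplied physical rates; bead
coordinates are sampled conditionally on the hidden state. Without imposed
rates the hairpin state is itself a Metropolis move (proposal probability
0.02 per step), so equilibrium occupancies are Boltzmann-consistent — this
is verified against a partition-function oracle that integrates the two
axial bead coordinates numerically (`calibrate_dG0` returns the ΔG₀ that
equalizes the state free energies; the MC occupancy then sits at 50 %).
ΔG₀ is a free parameter because the source experiments report
mid-transition forces, not zero-force folding energies.

## Analysis pipeline

* **Noise profile**: SD of extension and mean force in a moving window of
  200 samples, stride 1.
* **Apparent stiffness**: least-squares slope of force vs extension in a
  force window; invariant to extension offsets.
* **Contact detection**: windowed Pearson r of the two deflection signals;
  the first sample after r falls below −0.25 (midway between 0 and the
  ≈ −0.5 seen at bead contact) marks the deflection zero.
* **Dwell rates**: Schmitt-trigger state assignment (hysteresis band around
  a midpoint), then k = 1/⟨dwell⟩ per state with the censored first/last
  dwells excluded; se = k/√n (exact for exponential MLE).
* **HMM**: two-state Gaussian-emission EM (hmmlearn backend), initialized by
  a 2-quantile split, relative log-likelihood tolerance 1e−6, max 500
  iterations. Rates are a_ij·f_s (the small-probability limit; differs from
  −f_s ln(1−a) by <1 % for a < 0.02, the regime of every analysis here).
  The fit is declared unconverged when EM stalls or the fitted means are
  closer than the pooled emission SD — the one-broad-population signature of
  noise-dominated (floppy-linker) data.
* **Landscapes**: histograms on uniform bins (default 0.25 nm, ~¼ of the
  PSF width); the PSF is the *empirical* centered histogram of a
  hairpin-free control at similar load (a Gaussian constructor exists for
  synthetic work); deconvolution is a damped multiplicative
  Richardson–Lucy-type iteration (damping exponent 0.5, tol 1e−8,
  max 10⁵ iterations, best-reconvolution iterate returned — the undamped
  ML limit of this ill-conditioned problem is spiky, and damping slows the
  approach to it; acceleration schemes reach the spiky limit faster and
  were rejected for that reason). Boltzmann inversion uses a density floor
  of 1e−4 of the maximum; bins below it are undefined (NaN), not ±∞. The
  contour-length transform divides extension by the WLC relative extension
  z(F) at the local force — a pure rescaling — and allows a shift of at
  most ±5 nm to put the folded minimum at zero.

## Shape statistics

Filaments adsorbed on a support equilibrate in 2D, so the tangent
correlation is ⟨t(0)·t(s)⟩ = e^(−s/2p) with p the 3D persistence length,
and ⟨R²⟩ = 4pL[1 − (2p/L)(1 − e^(−L/2p))] — a self-consistent pair
(cross-validated against numerical double integration). The generator draws
Gaussian tangent increments of variance Δs/p. Whether the underlying
micrograph statistics are 2D-equilibrated or projected-3D is a modeling
choice; the 2D convention is adopted throughout and generator and estimator
use the same convention, so recovery tests are internally consistent.

Backbone tracing measures arc length of a vertex-smoothed polyline
(centered moving average, window 5, with shrinking windows at the ends —
full-window padding would pull the terminal vertices inward and bias the
contour low by ~window/2 segments). Tracing fixtures use a vertex spacing
of ~4 pixels (8 nm at 2 nm/px): spacing well below that amplifies the
upward arc-length bias of vertex jitter; well above it, curvature is
undersampled. Persistence length is fitted from ⟨R²⟩ alone (contour and
end-to-end are what tracing measures), by bisection on the closed form,
with a 1000-resample bootstrap percentile CI; when ⟨R²⟩ is within one
standard error of L̄² the data only support a lower bound
(`lower_bound_only`).

## Problem sizes and seeds

Everything is seed-deterministic (`numpy.random.SeedSequence` spawning, one
stream per component). Default study sizes: 200 traces per noise-profile
ensemble (reducible; tests use 20 per arm), 500 chains for persistence
fits, 200 chains per tracing preset, 2–3 s constant-distance runs at
100 kHz for hairpin analyses. `scripts/acceptance.py` runs the full
pipeline at these sizes in well under a minute on one core.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical structure* the analyses rely on:
Boltzmann bead fluctuations, series-elasticity force partitioning,
exponential two-state dwells, Gaussian tracing jitter. They do not model
hydrodynamic drag (MC time is rescaled by the step size, see above),
detector/hardware filtering (the 32.6 kHz Butterworth stage is replaced by
plain block averaging), beam crosstalk baselines, instrument calibration
error, or image-domain particle picking. Passing tests therefore certify
the estimators and the simulator against each other and against closed
forms — not against instrument systematics.

## Known limitations

* Apparent-stiffness trap dependence: in real data k_app correlates
  *positively* with trap stiffness because absolute-displacement
  calibration errors propagate into extension. This simulator has no
  calibration error, and the faithful in-scope effect is slightly negative
  (noise attenuation vs force–extension noise correlation); only the
  order-of-magnitude gap k_app ≪ N·K/L is reproduced.
* The HMM resolvability flag (means closer than pooled SD) is a sharp
  threshold; signals sitting exactly at separation ≈ noise SD can fall on
  either side.
* PSFs are used at the nearest control force; no interpolation between
  control loads.
* Dwell-time discretization at 20 kHz biases rates above ~1000 s⁻¹.
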