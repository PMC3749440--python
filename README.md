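# stifflink

Simulation and analysis toolkit for dual-trap optical-tweezer assays that use
**rigid DNA helix-bundle linkers** instead of conventional double-stranded DNA
to tether the molecule of interest between two trapped beads.

## The problem

In a dual-trap assay the measured signal is the bead deflection; every degree
of freedom of the bead/linker system carries k_BT/2 of thermal energy, so the
*stiffness of the linkers* decides how much of that energy appears as
extension noise. Soft dsDNA linkers let the beads wander; a DNA-origami beam
of N parallel cross-linked helices (persistence length of micrometers,
stretch stiffness ~N·K/L) clamps them. This package lets you simulate the
assay and run the complete downstream analysis, for people who design such
experiments or develop analysis methods for them:

* **Polymer elasticity** (`stifflink.polymer`) — worm-like chain
  (Marko–Siggia interpolation), extensible WLC (substitution
  l = x/L − F/K) and extensible freely-jointed chain
  x(F) = L [coth(Fb/kT) − kT/(Fb)] (1 + F/K), composed in mechanical series.
* **Metropolis Monte-Carlo simulator** (`stifflink.tweezer`) — two beads in
  3D anisotropic harmonic traps (0.4 / 0.04 pN/nm) joined by a tether chain,
  with pulling (trap retreat per accepted move) and constant-trap-distance
  protocols, optional two-state DNA hairpin, traces block-averaged from
  100 kHz to 20 kHz.
* **Synthetic data** (`stifflink.synth`) — telegraph signals, preset assay
  configurations for the standard constructs, and 2D-equilibrated
  semiflexible backbones with tracing jitter (TEM stand-in).
* **Trace analysis** (`stifflink.traces`) — moving-window noise profiles,
  apparent stiffness fits, expected bundle stiffness N·K/L, bead-contact
  detection via windowed Pearson correlation.
* **Kinetics** (`stifflink.kinetics`) — Schmitt-trigger state assignment +
  dwell-time maximum likelihood, and a two-state Gaussian-emission HMM;
  force-dependent rate tables.
* **Landscapes** (`stifflink.landscape`) — deflection histograms, empirical
  point-spread functions from hairpin-free controls, damped multiplicative
  (Richardson–Lucy-type) deconvolution, Boltzmann inversion
  G = −kT ln p, and the extension→contour-length transform.
* **Beam statistics** (`stifflink.beam`) — 2D worm-like-filament
  ⟨R²⟩ = 4pL[1 − (2p/L)(1 − e^(−L/2p))], backbone tracing, and
  persistence-length fits with bootstrap CIs.

Units package-wide: nm, pN, pN·nm, s, Hz; kT = 4.18 pN·nm (30 °C).

## Worked example

`examples/03_hairpin_kinetics.py` simulates a stable 20 bp hairpin flanked by
two ten-helix bundles hopping at imposed 50/50 s⁻¹ under a ~14 pN load and
re-estimates the rates two independent ways:

```
trap separation for a 14 pN folded-state load: 1063.3 nm
expected state separation: 16.3 nm
dwell analysis : k_unfold =  43.3 +- 4.1 /s,  k_fold =  48.4 +- 4.5 /s  (227 dwells)
HMM            : k_unfold =  43.5 /s,  k_fold =  52.5 /s,  state separation = 13.57 nm
```

The dwell and HMM estimates bracket the imposed rates within a few standard
errors, and the fitted state separation (13.6 nm measured at constant trap
distance, vs 16.3 nm at fixed force — the difference is trap compliance) is
the released-ssDNA length the construct should show. The other example
scripts cover the elasticity laws, the noise-suppression comparison between
stiff and floppy linkers, energy-landscape reconstruction by PSF
deconvolution, and persistence-length fitting from traced backbones — each
prints its numbers with a line on what they mean.

A thin CLI wraps the same functions for shell use:

```sh
stifflink synth chains -p 2000 -L 428 --n-chains 200 --seed 1 --out chains.tsv
stifflink beamfit --chains chains.tsv --out report.tsv
stifflink simulate-pull --preset tenhelix_linker --seed 7 --out pull.tsv
stifflink analyze-fx --trace pull.tsv --out profile.tsv
```

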