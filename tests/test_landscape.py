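"""Landscape reconstruction: histograms, PSF estimation, constrained
deconvolution, Boltzmann inversion and the contour-length transform."""

import warnings

import numpy as np
import pytest

import stifflink as sl
from stifflink.landscape import (
    Histogram,
    LandscapeError,
    Psf,
    boltzmann_invert,
    convolve,
    deconvolve,
    deflection_histogram,
    estimate_psf,
    to_contour_length,
)
from stifflink.polymer import PolymerModel, Thermal

BW = 0.25


def _two_gaussian(x, mu, sigma=0.6, w=0.5):
    d = w * np.exp(-0.5 * ((x + mu) / sigma) ** 2)
    d += (1 - w) * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return d / (d.sum() * BW)


@pytest.fixture()
def grid():
    return np.arange(-8, 8, BW) + BW / 2


class TestDeflectionHistogram:
    def test_constant_signal_single_bin(self):
        h = deflection_histogram(np.full(2000, 1.3), BW)
        assert np.count_nonzero(h.density) == 1

    def test_normalization(self):
        rng = np.random.default_rng(1)
        h = deflection_histogram(rng.normal(0, 1, 20_000), BW)
        assert h.density.sum() * h.bin_width == pytest.approx(1.0)

    def test_two_gaussian_modes_recovered(self):
        rng = np.random.default_rng(2)
        sig = np.r_[rng.normal(-1.5, 0.6, 30_000), rng.normal(1.5, 0.6, 30_000)]
        h = deflection_histogram(sig, BW)
        from stifflink.landscape import _modes

        modes = h.bin_centers[_modes(h.density)]
        assert len(modes) == 2
        assert abs(modes[0] + 1.5) <= BW and abs(modes[1] - 1.5) <= BW

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            deflection_histogram(np.r_[np.zeros(2000), np.nan], BW)


class TestEstimatePsf:
    def test_gaussian_control_sd(self):
        rng = np.random.default_rng(3)
        psf = estimate_psf(rng.normal(10.0, 1.2, 50_000), BW)
        assert psf.sd == pytest.approx(1.2, rel=0.02)
        assert psf.density.sum() * psf.bin_width == pytest.approx(1.0)

    def test_constant_control_delta(self):
        psf = estimate_psf(np.full(2000, 7.0), BW)
        assert len(psf.density) == 1
        assert psf.sd == 0.0

    def test_bimodal_control_rejected(self):
        rng = np.random.default_rng(4)
        sig = np.r_[rng.normal(-2, 0.4, 20_000), rng.normal(2, 0.4, 20_000)]
        with pytest.raises(LandscapeError, match="bimodal"):
            estimate_psf(sig, BW)


class TestDeconvolve:
    def test_delta_psf_identity(self, grid):
        h = Histogram(grid, _two_gaussian(grid, 1.5), BW)
        psf = Psf(np.array([1.0 / BW]), BW, sd=0.0)
        out = deconvolve(h, psf)
        np.testing.assert_allclose(out.density, h.density)

    def test_round_trip_recovers_modes(self, grid):
        true = _two_gaussian(grid, 1.5)
        h = Histogram(grid, true, BW)
        psf = Psf.gaussian(1.0, BW)
        blurred = convolve(h, psf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = deconvolve(blurred, psf)
        # mode positions within one bin, separation within 10 %
        from stifflink.landscape import _modes

        m = grid[_modes(rec.density)]
        assert len(m) == 2
        assert abs(m[0] + 1.5) <= BW and abs(m[1] - 1.5) <= BW
        assert (m[1] - m[0]) == pytest.approx(3.0, rel=0.10)
        # L2 round-trip error < 5 % (mode separation = 3 x PSF sd)
        err = np.linalg.norm(rec.density - true) / np.linalg.norm(true)
        assert err < 0.05

    def test_output_reconvolves_no_worse_than_input(self, grid):
        true = _two_gaussian(grid, 1.2)
        psf = Psf.gaussian(1.0, BW)
        blurred = convolve(Histogram(grid, true, BW), psf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = deconvolve(blurred, psf, max_iter=500)
        q = psf.density * BW
        res_out = np.linalg.norm(np.convolve(rec.density, q, "same")
                                 - blurred.density)
        res_in = np.linalg.norm(np.convolve(blurred.density, q, "same")
                                - blurred.density)
        assert res_out <= res_in

    def test_result_nonnegative_normalized(self, grid):
        true = _two_gaussian(grid, 1.5)
        psf = Psf.gaussian(0.8, BW)
        blurred = convolve(Histogram(grid, true, BW), psf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = deconvolve(blurred, psf, max_iter=2000)
        assert np.all(rec.density >= 0)
        assert rec.density.sum() * BW == pytest.approx(1.0)

    def test_mismatched_bin_width_rejected(self, grid):
        h = Histogram(grid, _two_gaussian(grid, 1.5), BW)
        with pytest.raises(ValueError):
            deconvolve(h, Psf.gaussian(1.0, BW / 2))


class TestBoltzmannInvert:
    def test_uniform_density_flat_landscape(self, grid):
        h = Histogram(grid, np.full(grid.size, 1.0 / (grid.size * BW)), BW)
        land = boltzmann_invert(h)
        np.testing.assert_allclose(land.G, 0.0, atol=1e-12)

    def test_density_ratio_e_gives_kT(self):
        centers = np.array([0.0, BW])
        dens = np.array([np.e, 1.0])
        h = Histogram(centers, dens / (dens.sum() * BW), BW).normalized()
        land = boltzmann_invert(h, Thermal(kT=4.18))
        assert land.G[1] - land.G[0] == pytest.approx(4.18, rel=1e-9)

    def test_double_well_with_barrier(self, grid):
        true = _two_gaussian(grid, 1.5, sigma=0.6)
        land = boltzmann_invert(Histogram(grid, true, BW))
        mid = np.argmin(np.abs(grid))
        i1, i2 = np.nanargmin(np.abs(grid + 1.5)), np.nanargmin(np.abs(grid - 1.5))
        assert land.G[mid] > land.G[i1] and land.G[mid] > land.G[i2]
        assert np.nanmin(land.G) == 0.0

    def test_floor_bins_undefined_not_infinite(self, grid):
        true = _two_gaussian(grid, 1.5, sigma=0.4)
        land = boltzmann_invert(Histogram(grid, true, BW))
        assert np.any(np.isnan(land.G))
        assert not np.any(np.isinf(land.G))


class TestContourTransform:
    def test_mapping_is_monotone_and_linear(self, grid):
        land = boltzmann_invert(
            Histogram(grid + 10, _two_gaussian(grid, 1.5), BW)
        )
        ss = PolymerModel.wlc(9.44, 1.0)
        out = to_contour_length(land, ss, force=6.25, offset=0.0)
        assert out.coordinate_kind == "contour"
        assert np.all(np.diff(out.coordinate) > 0)
        # WLC at fixed force: contour = extension / z(F), a pure rescaling
        ratio = np.diff(out.coordinate) / BW
        np.testing.assert_allclose(ratio, ratio[0])
        assert ratio[0] > 1.0  # contour exceeds extension below full stretch

    def test_offset_bound_enforced(self, grid):
        land = boltzmann_invert(Histogram(grid + 10, _two_gaussian(grid, 1.5),
                                          BW))
        ss = PolymerModel.wlc(9.44, 1.0)
        with pytest.raises(ValueError, match="offset"):
            to_contour_length(land, ss, force=6.25, offset=6.0)

    def test_negative_contour_bins_dropped(self, grid):
        land = boltzmann_invert(Histogram(grid, _two_gaussian(grid, 1.5), BW))
        ss = PolymerModel.wlc(9.44, 1.0)
        with pytest.warns(UserWarning, match="negative contour"):
            out = to_contour_length(land, ss, force=6.25, offset=0.0)
        assert np.all(out.coordinate >= 0)


def test_reconvolution_consistency_between_linker_systems():
    """The underlying density recovered from stiff-linker data, re-blurred
    with the broad dsDNA PSF, reproduces the dsDNA-linker histogram
    (chi-square at alpha = 0.01 on decimated, approximately independent
    samples)."""
    from scipy import stats

    def centered(tr):
        return tr.extension - tr.extension.mean()

    stiff = sl.preset_config("tenhelix_hairpin6", seed=0)
    tr_s = sl.simulate_constant_distance(
        stiff, 3.0, rates=(50.0, 50.0),
        separation=sl.separation_for_force(stiff, 6.25), seed=21)
    floppy = sl.preset_config("dsDNA_hairpin6", seed=0)
    tr_f = sl.simulate_constant_distance(
        floppy, 3.0, rates=(50.0, 50.0),
        separation=sl.separation_for_force(floppy, 6.25), seed=22)
    ctrl_s = sl.preset_config("control_no_hairpin", seed=0)
    trc_s = sl.simulate_constant_distance(
        ctrl_s, 2.0, separation=sl.separation_for_force(ctrl_s, 6.25), seed=23)
    ctrl_f = sl.preset_config("dsDNA_linker", seed=0)
    trc_f = sl.simulate_constant_distance(
        ctrl_f, 2.0, separation=sl.separation_for_force(ctrl_f, 6.25), seed=24)

    h_s = deflection_histogram(centered(tr_s), BW, limits=(-15, 15))
    psf_s = estimate_psf(trc_s, BW)
    psf_f = estimate_psf(trc_f, BW)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_under = deconvolve(h_s, psf_s)
    pred = convolve(p_under, psf_f)

    dec = centered(tr_f)[::40]  # decimate past the MC correlation time
    counts, _ = np.histogram(
        dec, bins=len(pred.density),
        range=(pred.bin_centers[0] - BW / 2, pred.bin_centers[-1] + BW / 2))
    expected = pred.density * BW * counts.sum()
    sel = expected >= 5
    chi2 = ((counts[sel] - expected[sel]) ** 2 / expected[sel]).sum()
    chi2 += ((counts[~sel].sum() - expected[~sel].sum()) ** 2
             / max(expected[~sel].sum(), 1e-9))
    pval = stats.chi2.sf(chi2, int(sel.sum()))
    assert pval > 0.01
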