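"""Metropolis dual-trap simulator: energies, acceptance rule, equipartition,
protocols, downsampling, determinism and energy bookkeeping."""

import dataclasses

import numpy as np
import pytest

from stifflink import (
    AssayConfig,
    HairpinModel,
    PolymerModel,
    SystemState,
    Thermal,
    TrapModel,
    calibrate_dG0,
    downsample,
    equilibrium_force,
    mc_step,
    separation_for_force,
    simulate_constant_distance,
    simulate_pull,
    stretch_energy,
    total_energy,
)
from stifflink._mc_kernel import run_mc
from stifflink.tweezer import FOLDED, TetherTable, _tables

KT = 4.18

# kernel return indices
N_OUT, N_ACCEPT, SUM_DE, E_FIRST, E_LAST = 8, 9, 10, 11, 12


def _free_bead_config(**kw):
    return AssayConfig(tether=(), **kw)


class TestTotalEnergy:
    def test_displaced_bead_harmonic_energy(self):
        cfg = _free_bead_config().with_separation(100.0)
        state = SystemState(bead1=np.array([3.0, 0, 0]),
                            bead2=np.array([100.0, 0, 0]))
        # 1/2 * 0.4 * 3^2 = 1.8 pN nm
        assert total_energy(state, cfg) == pytest.approx(1.8)

    def test_beads_at_centers_only_stretch_term(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,)).with_separation(400.0)
        state = SystemState(bead1=np.zeros(3), bead2=np.array([400.0, 0, 0]))
        assert total_energy(state, cfg) == pytest.approx(
            stretch_energy(400.0, [dsdna_ewlc])
        )

    def test_full_system_is_sum_of_parts(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,)).with_separation(450.0)
        b1 = np.array([2.0, 1.0, -3.0])
        b2 = np.array([448.0, -1.0, 2.0])
        state = SystemState(bead1=b1, bead2=b2)
        k = np.array([0.4, 0.4, 0.04])
        manual = 0.5 * np.sum(k * b1**2)
        manual += 0.5 * np.sum(k * (b2 - np.array([450.0, 0, 0])) ** 2)
        manual += stretch_energy(float(np.linalg.norm(b2 - b1)), [dsdna_ewlc])
        assert total_energy(state, cfg) == pytest.approx(manual, rel=1e-12)

    def test_overstretched_tether_infinite_energy_not_exception(self, ssdna_wlc):
        cfg = AssayConfig(tether=(ssdna_wlc,)).with_separation(20.0)
        state = SystemState(bead1=np.zeros(3), bead2=np.array([20.0, 0, 0]))
        assert total_energy(state, cfg) == np.inf

    def test_hairpin_state_swaps_composition(self, bundle_efjc, ssdna_wlc):
        hp = HairpinModel(released_nt=16, dG0=10.0)
        cfg = AssayConfig(tether=(bundle_efjc, ssdna_wlc), hairpin=hp)
        cfg = cfg.with_separation(500.0)
        b1, b2 = np.zeros(3), np.array([490.0, 0, 0])
        r = 490.0
        ef = total_energy(SystemState(b1, b2, hairpin_folded=True), cfg)
        eu = total_energy(SystemState(b1, b2, hairpin_folded=False), cfg)
        chain_f = [bundle_efjc, ssdna_wlc, PolymerModel.rigid(2.0)]
        chain_u = [bundle_efjc, ssdna_wlc, PolymerModel.wlc(16 * 0.59, 1.0)]
        expected = 10.0 + stretch_energy(r, chain_u) - stretch_energy(r, chain_f)
        assert eu - ef == pytest.approx(expected, rel=1e-9)


class _FixedProposalRng:
    """uniform() returns a prescribed displacement; random() is genuine."""

    def __init__(self, d1, d2, seed):
        self.d1, self.d2 = np.asarray(d1, float), np.asarray(d2, float)
        self._rng = np.random.default_rng(seed)
        self._count = 0

    def uniform(self, lo, hi, size):
        self._count += 1
        return self.d1 if self._count % 2 == 1 else self.d2

    def random(self):
        return self._rng.random()


class TestMcStep:
    def test_downhill_always_accepted(self):
        cfg = _free_bead_config().with_separation(50.0)
        # start displaced; propose moving exactly back to the trap center
        start = SystemState(bead1=np.array([3.0, 0, 0]),
                            bead2=np.array([50.0, 0, 0]))
        rng = _FixedProposalRng([-3.0, 0, 0], [0, 0, 0], seed=0)
        _, accepted = mc_step(start, cfg, rng)
        assert accepted

    def test_rejected_step_leaves_state_unchanged(self, ssdna_wlc):
        cfg = AssayConfig(tether=(ssdna_wlc,), step_size=5.0)
        cfg = cfg.with_separation(12.0)
        state = SystemState(bead1=np.zeros(3), bead2=np.array([12.0, 0, 0]))
        rng = np.random.default_rng(3)
        saw_reject = False
        for _ in range(50):
            new, accepted = mc_step(state, cfg, rng)
            if not accepted:
                assert new is state
                saw_reject = True
            state = new
        assert saw_reject

    def test_uphill_acceptance_frequency_is_boltzmann(self):
        """A fixed dE = +kT proposal is accepted with frequency e^-1."""
        cfg = _free_bead_config().with_separation(50.0)
        delta = np.sqrt(2 * KT / 0.4)  # 1/2 k d^2 = kT
        start = SystemState(bead1=np.zeros(3), bead2=np.array([50.0, 0, 0]))
        n = 100_000
        rng = _FixedProposalRng([delta, 0, 0], [0, 0, 0], seed=7)
        accepted = sum(mc_step(start, cfg, rng)[1] for _ in range(n))
        p = np.exp(-1.0)
        assert abs(accepted / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestEquipartition:
    def test_variance_matches_kT_over_k_per_axis(self, thermal):
        """Long tether-free runs: var = kT/k on each trap axis (5 %)."""
        cfg = _free_bead_config(mc_rate=1e5, output_rate=1e5, seed=0)
        table = TetherTable((), thermal)
        n = 6_000_000
        out = run_mc(
            42, n, 1,
            cfg.trap1.k_vector, cfg.trap2.k_vector,
            100.0, 0.0, 0.0, cfg.step_size, KT,
            table.r0, table.dr, table.E, table.F, table.E, table.F, 0.0,
            np.empty(0, dtype=np.int8), 0.0, FOLDED,
            np.zeros(3), np.zeros(3),
        )
        defl1, y1, z1 = out[1], out[6], out[7]
        for series, k in [(defl1, 0.4), (y1, 0.4), (z1, 0.04)]:
            assert np.std(series) == pytest.approx(np.sqrt(KT / k), rel=0.05)


class TestEnergyBookkeeping:
    def test_accepted_deltas_telescope(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,), seed=0)
        d = separation_for_force(cfg, 5.0)
        tf, tu = _tables(cfg)
        out = run_mc(
            9, 50_000, 5,
            cfg.trap1.k_vector, cfg.trap2.k_vector,
            d, 0.0, 0.0, cfg.step_size, KT,
            tf.r0, tf.dr, tf.E, tf.F, tu.E, tu.F, 0.0,
            np.empty(0, dtype=np.int8), 0.0, FOLDED,
            np.array([5.0 / 0.4, 0, 0]), np.array([-5.0 / 0.4, 0, 0]),
        )
        assert out[SUM_DE] == pytest.approx(out[E_LAST] - out[E_FIRST],
                                            rel=1e-6)


class TestSimulatePull:
    def test_no_tether_free_bead_fluctuations(self):
        # covered by equipartition; here: slack tether gives near-zero force
        cfg = AssayConfig(tether=(PolymerModel.ewlc(530, 50, 1000),))
        tr = simulate_constant_distance(cfg, 0.5, separation=200.0, seed=2)
        assert abs(np.mean(tr.force)) < 0.1

    def test_pull_reaches_max_force_and_records_all_columns(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,), seed=0)
        tr = simulate_pull(cfg, max_force=15.0, seed=4)
        assert tr.force[-1] == pytest.approx(15.0, abs=1.5)
        assert np.all(np.diff(tr.trap_sep) >= 0)
        # extension = trap separation minus both deflections
        np.testing.assert_allclose(
            tr.extension, tr.trap_sep - tr.defl1 - tr.defl2, atol=1e-9
        )

    def test_determinism_same_seed_identical_trace(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,), seed=0)
        a = simulate_pull(cfg, max_force=5.0, seed=11)
        b = simulate_pull(cfg, max_force=5.0, seed=11)
        assert np.array_equal(a.extension, b.extension)
        assert np.array_equal(a.force, b.force)


class TestSimulateConstantDistance:
    def test_one_second_gives_exact_sample_count(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,), output_rate=2e4)
        tr = simulate_constant_distance(cfg, 1.0, separation=400.0, seed=1)
        assert len(tr) == 20_000

    def test_sample_cap_enforced(self, dsdna_ewlc):
        cfg = AssayConfig(tether=(dsdna_ewlc,))
        with pytest.raises(ValueError, match="cap"):
            simulate_constant_distance(cfg, 1.0, separation=400.0,
                                       max_samples=1000)

    def test_never_folding_rates_single_population(self, bundle_efjc,
                                                   ssdna_wlc):
        hp = HairpinModel(released_nt=16)
        cfg = AssayConfig(tether=(bundle_efjc, ssdna_wlc, ssdna_wlc,
                                  bundle_efjc), hairpin=hp)
        d = separation_for_force(cfg, 6.0)
        tr = simulate_constant_distance(cfg, 0.3, rates=(0.0, 0.0),
                                        separation=d, seed=5)
        states = tr.state[~np.isnan(tr.state)]
        assert np.all(states == states[0])

    def test_transition_count_poisson(self, bundle_efjc, ssdna_wlc):
        """k_fold = k_unfold = 50/s for 10 s: ~500 transitions (3 sigma)."""
        hp = HairpinModel(released_nt=16)
        cfg = AssayConfig(tether=(bundle_efjc, ssdna_wlc, ssdna_wlc,
                                  bundle_efjc), hairpin=hp)
        d = separation_for_force(cfg, 6.25)
        tr = simulate_constant_distance(cfg, 10.0, rates=(50.0, 50.0),
                                        separation=d, seed=6)
        s = tr.state[~np.isnan(tr.state)]
        n_trans = int(np.sum(np.diff(s) != 0))
        assert abs(n_trans - 500) <= 3 * np.sqrt(500)

    def test_boltzmann_consistent_occupancy_at_equal_free_energy(
            self, bundle_efjc, ssdna_wlc):
        """With dG0 calibrated so the state free energies are equal, the
        Metropolis-flip mode occupies each state half the time."""
        hp = HairpinModel(released_nt=16)
        cfg = AssayConfig(tether=(bundle_efjc, ssdna_wlc, ssdna_wlc,
                                  bundle_efjc), hairpin=hp)
        d = separation_for_force(cfg, 6.25)
        dg = calibrate_dG0(cfg, d)
        cfg = dataclasses.replace(cfg, hairpin=HairpinModel(released_nt=16,
                                                            dG0=dg))
        tr = simulate_constant_distance(cfg, 10.0, separation=d, seed=7)
        occ = float(np.nanmean(tr.state))
        assert abs(occ - 0.5) < 0.05


class TestDownsample:
    def test_constant_series_unchanged(self):
        s = np.full(100, 3.3)
        np.testing.assert_allclose(downsample(s, 5), np.full(20, 3.3))

    def test_factor_one_identity(self):
        s = np.arange(10.0)
        np.testing.assert_array_equal(downsample(s, 1), s)

    def test_gaussian_sd_scales_with_sqrt_factor(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1.0, 200_000)
        sd = downsample(s, 5).std()
        expect = 1.0 / np.sqrt(5)
        n = 40_000
        assert abs(sd - expect) < 3 * expect / np.sqrt(2 * (n - 1))

    def test_trailing_partial_block_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="stifflink.tweezer"):
            out = downsample(np.arange(11.0), 5)
        assert len(out) == 2
        assert any("partial block" in r.message for r in caplog.records)


def test_equilibrium_force_balance_consistency(dsdna_ewlc):
    cfg = AssayConfig(tether=(dsdna_ewlc,))
    d = separation_for_force(cfg, 8.0)
    assert equilibrium_force(cfg, d) == pytest.approx(8.0, rel=1e-9)
    # a nearly slack entropic tether carries almost no tension
    assert 0.0 <= equilibrium_force(cfg, 100.0) < 0.05


def test_config_validation():
    with pytest.raises(ValueError, match="integer multiple"):
        AssayConfig(tether=(), mc_rate=1e5, output_rate=3e4)
    with pytest.raises(ValueError):
        TrapModel(stiffness_perpendicular=-0.1)
    with pytest.raises(ValueError):
        HairpinModel(released_nt=-1)
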