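import numpy as np
import pytest

from tomovsm.beam_model import ParticleState
from tomovsm.phantom import VoxelPhantom
from tomovsm.synth import make_slab_phantom, make_static_open_field_plan
from tomovsm.transport import (DoseGrid, TransportConfig,
                               first_interaction_depths,
                               mean_relative_uncertainty, read_dose,
                               relative_uncertainty, run_simulation,
                               simulate_primaries, transport_electron,
                               transport_photon, write_dose)


def water_block(nx=20, ny=60, nz=20, voxel=0.5, density=1.0):
    origin = (-nx * voxel / 2, 0.0, -nz * voxel / 2)
    return VoxelPhantom(origin, (voxel,) * 3,
                        np.full((nx, ny, nz), density))


def pencil(n, energy=2.0):
    pos = np.tile([0.0, -1.0, 0.0], (n, 1))
    dirs = np.tile([0.0, 1.0, 0.0], (n, 1))
    return pos, dirs, np.full(n, energy)


class TestPhotonTransport:
    def test_vacuum_phantom_all_energy_escapes(self, cfg):
        ph = water_block(density=0.0)
        pos, dirs, e = pencil(200)
        tally = simulate_primaries(pos, dirs, e, ph, cfg)
        assert tally.deposited_mev == 0.0
        assert tally.escaped_mev == pytest.approx(tally.launched_mev)

    def test_energy_ledger_closes(self, cfg):
        ph = water_block()
        pos, dirs, e = pencil(2000)
        tally = simulate_primaries(pos, dirs, e, ph, cfg)
        balance = tally.launched_mev - tally.deposited_mev - tally.escaped_mev
        assert abs(balance) < 1e-9 * tally.launched_mev

    def test_narrow_beam_attenuation(self, cfg):
        """First-interaction depths of a 2 MeV pencil beam in water follow
        exp(-mu d) with the engine's own attenuation coefficient."""
        ph = water_block(ny=60)
        n = 100_000
        pos, dirs, e = pencil(n, energy=2.0)
        depths = first_interaction_depths(pos, dirs, e, ph, cfg) - 1.0
        mu = float(cfg.materials().mu_total_at(2.0))  # density 1
        for d in (2.0, 5.0, 10.0):
            p_surv = np.exp(-mu * d)
            observed = np.mean(depths > d)
            sigma = np.sqrt(p_surv * (1 - p_surv) / n)
            assert abs(observed - p_surv) < 3 * sigma + 1e-12

    def test_photon_below_cutoff_deposits_locally(self, cfg):
        ph = water_block()
        state = ParticleState(np.array([0.0, 5.0, 0.0]),
                              np.array([0.0, 1.0, 0.0]), energy=0.04)
        tally = transport_photon(state, ph, cfg)
        assert tally.deposited_mev == pytest.approx(0.04)
        ix, iz = ph.dims[0] // 2, ph.dims[2] // 2
        assert tally.edep_mev[ix, 10, iz] == pytest.approx(0.04)


class TestElectronTransport:
    def test_below_cutoff_deposits_in_one_large_voxel(self):
        cfg = TransportConfig(seed=3)
        ph = VoxelPhantom((-5, -5, -5), (10, 10, 10), np.ones((1, 1, 1)))
        state = ParticleState(np.zeros(3), np.array([0, 1.0, 0]), energy=0.15)
        tally = transport_electron(state, ph, cfg)
        assert tally.edep_mev[0, 0, 0] == pytest.approx(0.15)
        assert tally.escaped_mev == 0.0

    def test_1mev_penetration_bracketed_by_csda_range(self, cfg):
        """Mean forward penetration of 1 MeV electrons in water lies below
        the CSDA range integral (~0.44 cm) and above 0.1 cm."""
        ph = VoxelPhantom((-5.0, 0.0, -5.0), (10.0, 0.02, 10.0),
                          np.ones((1, 60, 1)))
        n = 3000
        pos = np.tile([0.0, 1e-6, 0.0], (n, 1))
        dirs = np.tile([0.0, 1.0, 0.0], (n, 1))
        tally = simulate_primaries(pos, dirs, np.ones(n), ph, cfg,
                                   ptypes=np.ones(n, dtype=np.int8))
        depth = (np.arange(60) + 0.5) * 0.02
        edep = tally.edep_mev[0, :, 0]
        mean_depth = float((depth * edep).sum() / edep.sum())
        csda = float(cfg.materials().csda_range_at(1.0))
        assert 0.1 < mean_depth < csda
        assert csda == pytest.approx(0.44, abs=0.03)

    def test_bremsstrahlung_yield_increases_with_energy(self, cfg):
        """The escaping-energy fraction of electrons in a thin slab grows
        with energy as radiative losses take over."""
        ph = VoxelPhantom((-20, 0, -20), (40, 4.0, 40), np.ones((1, 1, 1)))
        fracs = []
        for e0 in (0.5, 5.0):
            n = 20_000
            pos = np.tile([0.0, 1e-6, 0.0], (n, 1))
            dirs = np.tile([0.0, 1.0, 0.0], (n, 1))
            tally = simulate_primaries(pos, dirs, np.full(n, e0), ph, cfg,
                                       ptypes=np.ones(n, dtype=np.int8))
            fracs.append(tally.escaped_mev / tally.launched_mev)
        assert fracs[1] > fracs[0]


class TestRunSimulation:
    def test_symmetric_field_gives_symmetric_profile(self, model):
        cfg = TransportConfig(seed=5)
        ph = make_slab_phantom()
        plan = make_static_open_field_plan(2.5)
        dose = run_simulation(plan, model, ph, cfg, 60_000)
        # longitudinal (z) profile through the jaw edges, averaged over
        # the upstream water region to tame MC noise
        prof = dose.dose[:, 4:20, :].mean(axis=(0, 1))
        asym = np.abs(prof - prof[::-1]).max() / prof.max()
        assert asym < 0.15

    def test_seed_determinism(self, model):
        ph = make_slab_phantom()
        plan = make_static_open_field_plan(2.5)
        d1 = run_simulation(plan, model, ph, TransportConfig(seed=9), 20_000)
        d2 = run_simulation(plan, model, ph, TransportConfig(seed=9), 20_000)
        assert np.array_equal(d1.dose, d2.dose)
        d3 = run_simulation(plan, model, ph, TransportConfig(seed=10), 20_000)
        assert not np.array_equal(d1.dose, d3.dose)

    def test_worker_count_invariance(self, model):
        ph = make_slab_phantom()
        plan = make_static_open_field_plan(2.5)
        d1 = run_simulation(plan, model, ph,
                            TransportConfig(seed=9, n_workers=1), 20_000)
        d4 = run_simulation(plan, model, ph,
                            TransportConfig(seed=9, n_workers=4), 20_000)
        assert np.array_equal(d1.dose, d4.dose)

    def test_missed_phantom_warns_and_zeroes(self, model):
        cfg = TransportConfig(seed=1)
        ph = VoxelPhantom((100.0, 100.0, 100.0), (1, 1, 1), np.ones((2, 2, 2)))
        plan = make_static_open_field_plan(2.5)
        with pytest.warns(UserWarning, match="did not intersect"):
            dose = run_simulation(plan, model, ph, cfg, 100)
        assert dose.dose.max() == 0.0

    def test_zero_histories_rejected(self, model, cfg):
        plan = make_static_open_field_plan(2.5)
        with pytest.raises(ValueError):
            run_simulation(plan, model, make_slab_phantom(), cfg, 0)


class TestUncertainty:
    def test_poisson_scaling(self, model):
        """Doubling the histories shrinks the mean relative uncertainty by
        about 1/sqrt(2)."""
        ph = make_slab_phantom()
        plan = make_static_open_field_plan(2.5)
        u1 = mean_relative_uncertainty(
            run_simulation(plan, model, ph, TransportConfig(seed=21), 50_000))
        u2 = mean_relative_uncertainty(
            run_simulation(plan, model, ph, TransportConfig(seed=22), 100_000))
        assert u2 / u1 == pytest.approx(1 / np.sqrt(2), rel=0.25)

    def test_zero_variance_gives_zero_uncertainty(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.ones((2, 2, 2)),
                        np.zeros((2, 2, 2)), 10, 10)
        rel = relative_uncertainty(grid)
        assert np.nanmax(rel) == 0.0

    def test_single_batch_rejected(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.ones((1, 1, 1)),
                        np.zeros((1, 1, 1)), 10, 1)
        with pytest.raises(ValueError):
            relative_uncertainty(grid)

    def test_empty_grid_rejected(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((1, 1, 1)),
                        np.zeros((1, 1, 1)), 10, 10)
        with pytest.raises(ValueError):
            relative_uncertainty(grid)


class TestDoseIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = DoseGrid((0, 1, 2), (0.5, 0.5, 0.5), rng.random((3, 4, 5)),
                        rng.random((3, 4, 5)), 1000, 10, 1.0, 0.6, 0.4)
        path = tmp_path / "dose.npz"
        write_dose(grid, path)
        back = read_dose(path)
        assert np.array_equal(back.dose, grid.dose)
        assert np.array_equal(back.variance, grid.variance)
        assert back.n_histories == 1000 and back.n_batches == 10
        assert back.energy_deposited_mev == pytest.approx(0.6)
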