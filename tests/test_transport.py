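"""Stepping engine: limits with physics disabled, geometry, bookkeeping."""

import numpy as np
import pytest

from protonfocus import optics, physics
from protonfocus.beam_source import BeamConfig, ParticleBatch, sample_beam
from protonfocus.physics import LEAD, WATER, LOW_ENERGY_CUTOFF_MEV
from protonfocus.scoring import find_peak_depth
from protonfocus.transport import (
    Geometry,
    PhysicsOptions,
    ScenarioParams,
    TransportError,
    collimator_length_for_energy,
    run_scenario,
    run_transport,
)

BALLISTIC = PhysicsOptions(stopping=False, scattering=False,
                           straggling=False, nuclear=False)
DETERMINISTIC_STOPPING = PhysicsOptions(stopping=True, scattering=False,
                                        straggling=False, nuclear=False)


class TestCollimatorLength:
    def test_stops_design_energy(self):
        length = collimator_length_for_energy(250.0)
        assert length >= physics.csda_range(LEAD, 250.0)
        assert length < physics.csda_range(LEAD, 250.0) + 1.5

    def test_monotone_in_energy(self):
        lengths = [collimator_length_for_energy(e) for e in (50, 150, 250, 350)]
        assert all(a <= b for a, b in zip(lengths, lengths[1:]))

    def test_minimum_length_floor(self):
        assert collimator_length_for_energy(0.1) == 1.0


class TestBallisticLimit:
    def test_focused_beam_reaches_vacuum_spot_size(self):
        # with every interaction disabled the engine is a pure drift, so
        # the RMS at the focal plane is sigma0/sqrt(1+alpha0^2)
        config = BeamConfig(kinetic_energy=150.0, sigma0=15.0, alpha0=20.0,
                            d_T=155.0, n_protons=100_000, seed=1)
        batch = sample_beam(config)
        geo = Geometry(phantom_length_mm=155.0)
        run_transport(batch, geo, opts=BALLISTIC, seed=2)
        expected = 15.0 * optics.magnification(20.0)
        assert batch.x.std() == pytest.approx(expected, rel=5e-3)
        assert batch.y.std() == pytest.approx(expected, rel=5e-3)

    def test_ballistic_engine_is_seed_independent(self):
        config = BeamConfig(kinetic_energy=150.0, sigma0=6.0, n_protons=2000,
                            seed=4)
        geo = Geometry(phantom_length_mm=50.0)
        tallies = []
        for seed in (1, 99):
            batch = sample_beam(config)
            tallies.append(run_transport(batch, geo,
                                         opts=DETERMINISTIC_STOPPING, seed=seed))
        assert np.array_equal(tallies[0].wide_mev, tallies[1].wide_mev)


class TestDeterministicStopping:
    def test_pencil_beam_peak_at_csda_range(self):
        # oracle: 1-D deterministic integration of dE/dz = -S(E) rho gives
        # the stop depth; with scattering and straggling off every proton
        # follows it exactly
        config = BeamConfig(kinetic_energy=150.0, sigma0=1e-6,
                            energy_spread_frac=0.0, n_protons=64, seed=0)
        batch = sample_beam(config)
        tally = run_transport(batch, Geometry(), opts=DETERMINISTIC_STOPPING,
                              seed=0)

        e, z, dz = 150.0, 0.0, 0.01
        while e > LOW_ENERGY_CUTOFF_MEV:
            e -= physics.mass_stopping_power(WATER, e) * WATER.density * dz / 10.0
            z += dz
        assert abs(z - physics.csda_range(WATER, 150.0)) < 1.0  # oracle sanity

        peak = find_peak_depth(tally.narrow_gy_per_proton())
        assert abs(peak - z) <= 0.4  # within a voxel of the oracle
        # all energy is deposited in the phantom
        assert tally.total_tallied_mev() == pytest.approx(
            tally.energy_entering_mev, rel=1e-12)


class TestCollimatedGeometry:
    def test_transparent_collimator_passes_everything(self):
        params = ScenarioParams(energy_mev=150.0, sigma0_mm=6.0,
                                collimator_radius_mm=60.0, n_protons=5000,
                                seed=3, phantom_length_mm=10.0)
        _, entering = run_scenario("CECP", params, opts=BALLISTIC)
        assert entering == 5000

    def test_narrow_bore_fraction_without_scatter(self):
        # closed-form oracle: a parallel Gaussian beam passes a bore of
        # radius R with probability 1 - exp(-R^2/(2 sigma0^2)); protons in
        # the lead stop (the collimator is ranged for 250 MeV), so without
        # scattering the entering count is the direct-bore count
        n, radius, sigma0 = 100_000, 1.0, 6.0
        params = ScenarioParams(energy_mev=150.0, sigma0_mm=sigma0,
                                collimator_radius_mm=radius, n_protons=n,
                                seed=5, phantom_length_mm=10.0)
        opts = PhysicsOptions(scattering=False, straggling=False, nuclear=False)
        _, entering = run_scenario("CECP", params, opts=opts)
        expected = n * (1.0 - np.exp(-radius**2 / (2.0 * sigma0**2)))
        assert entering == pytest.approx(expected, rel=0.05)

    def test_edge_scatter_adds_survivors(self):
        params = ScenarioParams(energy_mev=150.0, sigma0_mm=6.0,
                                collimator_radius_mm=1.0, n_protons=50_000,
                                seed=5, phantom_length_mm=10.0)
        no_scatter = PhysicsOptions(scattering=False, straggling=False,
                                    nuclear=False)
        _, n_direct = run_scenario("CECP", params, opts=no_scatter)
        _, n_full = run_scenario("CECP", params)
        assert n_full > n_direct


class TestBookkeepingAndErrors:
    def test_energy_conservation_full_physics(self):
        params = ScenarioParams(energy_mev=150.0, sigma0_mm=15.0, alpha0=20.0,
                                d_T_mm=155.0, n_protons=20_000, seed=6)
        tally, _ = run_scenario("CEFP", params)
        residual = (tally.energy_entering_mev - tally.total_tallied_mev()
                    - tally.energy_exiting_mev - tally.energy_discarded_mev)
        assert abs(residual) / tally.energy_entering_mev < 1e-3

    def test_fixed_seed_reproducibility(self):
        params = ScenarioParams(energy_mev=100.0, sigma0_mm=15.0, alpha0=10.0,
                                d_T_mm=76.0, n_protons=10_000, seed=7,
                                phantom_length_mm=100.0)
        t1, _ = run_scenario("CEFP", params)
        t2, _ = run_scenario("CEFP", params)
        assert np.array_equal(t1.narrow_mev, t2.narrow_mev)
        assert np.array_equal(t1.slice_mev, t2.slice_mev)

    def test_dose_scales_linearly_with_proton_count(self):
        def run(n, seed):
            params = ScenarioParams(energy_mev=100.0, sigma0_mm=6.0,
                                    alpha0=0.0, collimator_radius_mm=None,
                                    n_protons=n, seed=seed)
            config = BeamConfig(kinetic_energy=100.0, sigma0=6.0,
                                n_protons=n, seed=seed)
            batch = sample_beam(config)
            return run_transport(batch, Geometry(phantom_length_mm=100.0),
                                 seed=seed + 1)

        w1 = run(20_000, 11).wide_gy_per_proton()
        w2 = run(40_000, 12).wide_gy_per_proton()
        mask = w1 > 0.1 * w1.max()
        assert np.allclose(w1[mask], w2[mask], rtol=0.05)

    def test_empty_batch_gives_empty_tally(self):
        batch = ParticleBatch(x=np.empty(0), y=np.empty(0), xp=np.empty(0),
                              yp=np.empty(0), z=np.empty(0),
                              energy=np.empty(0),
                              alive=np.empty(0, dtype=bool))
        tally = run_transport(batch, Geometry())
        assert tally.total_tallied_mev() == 0.0
        assert tally.entering_protons == 0

    def test_nan_coordinates_rejected_at_construction(self):
        with pytest.raises(ValueError, match="finite"):
            ParticleBatch(x=np.array([np.nan]), y=np.zeros(1),
                          xp=np.zeros(1), yp=np.zeros(1), z=np.zeros(1),
                          energy=np.array([150.0]),
                          alive=np.ones(1, dtype=bool))

    def test_nan_coordinates_abort_transport(self):
        batch = sample_beam(BeamConfig(kinetic_energy=150.0, sigma0=6.0,
                                       n_protons=10, seed=0))
        batch.x[3] = np.nan  # corrupted in flight
        with pytest.raises(TransportError, match="NaN"):
            run_transport(batch, Geometry())

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("XRAY", ScenarioParams(energy_mev=150.0, sigma0_mm=6.0))

    def test_oversized_step_rejected(self):
        batch = sample_beam(BeamConfig(kinetic_energy=150.0, sigma0=6.0,
                                       n_protons=10, seed=0))
        with pytest.raises(ValueError, match="step"):
            run_transport(batch, Geometry(), step_mm=1.0)


def test_geometry_validation():
    with pytest.raises(ValueError):
        Geometry(phantom_radius_mm=-1.0)
    with pytest.raises(ValueError):
        Geometry(collimator=True, collimator_radius_mm=300.0,
                 collimator_length_mm=50.0)
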