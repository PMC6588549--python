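"""Brownian-dynamics engine: spring law, advection, diffusion, globule."""

import numpy as np
import pytest

from shearfold import (
    Frame,
    SimParams,
    Trajectory,
    a2_tensions,
    bd_step,
    equilibrate,
    fene_tension,
    radius_of_gyration,
    shear_velocity,
    simulate,
)
from shearfold.simulation import (
    OverExtensionError,
    _fene_forces,
    _harmonic_forces,
    _lj_pair_forces,
    _rpy_mobility,
)


class TestFeneTension:
    def test_zero_extension_gives_zero_force(self):
        assert fene_tension(0.0, k=1.0, r0=1.0) == 0.0

    def test_worked_value(self):
        # k r / (1 - (r/r0)^2) at r=0.5, k=1, r0=1
        assert fene_tension(0.5, 1.0, 1.0) == pytest.approx(2.0 / 3.0, rel=1e-9)

    def test_diverges_approaching_maximum_extension(self):
        assert fene_tension(0.999999 * 60, 0.0825, 60.0) > 1e5

    def test_strictly_increasing(self):
        r = np.linspace(0.0, 0.99, 200)
        f = fene_tension(r, 2.0, 1.0)
        assert np.all(np.diff(f) > 0)

    def test_small_extension_linear_within_one_percent(self):
        r = np.linspace(1e-6, 0.05, 50)
        f = fene_tension(r, 3.0, 1.0)
        assert np.allclose(f, 3.0 * r, rtol=0.01)

    def test_over_extension_is_domain_error(self):
        with pytest.raises(OverExtensionError):
            fene_tension(60.0, 0.0825, 60.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fene_tension(0.5, -1.0, 1.0)
        with pytest.raises(ValueError):
            fene_tension(-0.5, 1.0, 1.0)


class TestShearVelocity:
    @pytest.mark.parametrize(
        "z,rate,expected", [(0.0, 1e5, 0.0), (123.0, 0.0, 0.0), (2.0, 3.0, 6.0)]
    )
    def test_linear_profile(self, z, rate, expected):
        assert shear_velocity(z, rate) == expected


class TestA2Tensions:
    def test_coincident_pairs_have_zero_tension(self):
        p = SimParams()
        pos = np.repeat(np.arange(50)[:, None] * 100.0, 2, axis=0) * [1, 0, 0]
        t = a2_tensions(pos.astype(float), p)
        assert t.shape == (50,)
        assert np.allclose(t, 0.0)

    def test_matches_scalar_spring_law(self):
        p = SimParams(n_beads=4)
        pos = np.zeros((4, 3))
        pos[1, 0] = 13.0
        pos[3, 1] = 40.0
        pos[2:] += 500.0  # separate the monomers
        t = a2_tensions(pos, p)
        assert t[0] == pytest.approx(fene_tension(13.0, p.fene_k, p.fene_r0))
        assert t[1] == pytest.approx(fene_tension(40.0, p.fene_k, p.fene_r0))

    def test_hundred_beads_give_fifty_tensions(self):
        p = SimParams()
        pos = np.zeros((100, 3))
        pos[:, 0] = np.arange(100) * 24.0
        assert a2_tensions(pos, p).shape == (50,)

    def test_over_extended_spring_rejected(self):
        p = SimParams(n_beads=2)
        pos = np.array([[0.0, 0.0, 0.0], [p.fene_r0 + 1.0, 0.0, 0.0]])
        with pytest.raises(OverExtensionError):
            a2_tensions(pos, p)


class TestBdStep:
    def _quiet_params(self, **kw):
        defaults = dict(n_beads=4, temperature=0.0, lj_eps=0.0, shear_rate=0.0)
        defaults.update(kw)
        return SimParams(**defaults)

    def test_no_forces_no_noise_no_flow_leaves_positions(self):
        p = self._quiet_params()
        pos = np.zeros((4, 3))
        pos[2:, 0] = p.harmonic_r0  # harmonic bond at rest, FENE at zero
        frame = Frame(0.0, pos, a2_tensions(pos, p))
        out = bd_step(frame, p, np.random.default_rng(0))
        assert np.allclose(out.positions, pos, atol=1e-12)
        assert out.time == pytest.approx(p.dt)

    def test_pure_advection_displaces_by_shear_times_height(self):
        p = self._quiet_params(shear_rate=2.0e5)
        z0 = 37.0
        pos = np.full((2, 3), [0.0, 0.0, z0])  # one monomer, spring at rest
        frame = Frame(0.0, pos, np.zeros(1))
        out = bd_step(frame, p, np.random.default_rng(0))
        assert np.allclose(out.positions[:, 0], p.shear_rate * z0 * p.dt, rtol=1e-12)
        assert np.allclose(out.positions[:, 1:], pos[:, 1:], atol=1e-12)

    def test_pairwise_mode_runs_and_matches_invariants(self):
        p = SimParams(n_beads=4, hi_mode="pairwise")
        pos = np.array([[0, 0, 0], [10, 0, 0], [40, 0, 0], [52, 0, 0]], dtype=float)
        frame = Frame(0.0, pos, a2_tensions(pos, p))
        out = bd_step(frame, p, np.random.default_rng(1))
        assert out.positions.shape == (4, 3)
        assert np.all(np.isfinite(out.positions))


class TestDiffusion:
    def test_free_bead_msd_obeys_einstein_relation(self):
        """MSD/(6 t) of force-free beads matches kBT / (6 pi eta a) within 5%."""
        from shearfold.simulation import _NeighborState, _run_kernel

        p = SimParams(
            n_beads=2, lj_eps=0.0, shear_rate=0.0, fene_k=1e-12, fene_r0=1e9,
            sample_interval=SimParams().dt * 20,
        )
        lag = 25  # samples, i.e. 500 steps
        ratios = []
        for seed in (1, 2, 3):
            pos = np.zeros((2, 3))
            pos[1] = 1e5  # independent beads
            n_steps = 120_000
            out_pos, _ = _run_kernel(
                pos, p, n_steps, p.steps_per_sample, 0.0,
                np.random.default_rng(seed),
            )
            disp = out_pos[lag:] - out_pos[:-lag]
            msd = np.mean(np.sum(disp**2, axis=2))
            t = lag * p.sample_interval
            ratios.append(msd / (6.0 * t))
        assert np.mean(ratios) == pytest.approx(p.diffusivity, rel=0.05)


class TestConservativeForces:
    def test_internal_forces_sum_to_zero(self, rng):
        p = SimParams(n_beads=20)
        pos = rng.standard_normal((20, 3)) * 30.0
        total = (
            _lj_pair_forces(pos, p)
            + _harmonic_forces(pos, p)
            + _fene_forces(pos * 0.3, p) * 0  # FENE checked separately below
        ).sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-9)
        assert np.allclose(_fene_forces(pos * 0.3, p).sum(axis=0), 0.0, atol=1e-9)


class TestEquilibrate:
    def test_attractive_chain_collapses_to_globule(self, tiny_params):
        rgs = []
        for seed in (11, 12, 13):
            frame = equilibrate(tiny_params, seed=seed)
            rgs.append(radius_of_gyration(frame.positions))
        assert np.mean(rgs) < 0.2 * tiny_params.contour_length

    def test_repulsive_variant_is_larger(self, tiny_params):
        wca = tiny_params.replaced(lj_cutoff=2 ** (1 / 6) * tiny_params.lj_sigma)
        rg_attr = np.mean([
            radius_of_gyration(equilibrate(tiny_params, seed=s).positions)
            for s in (11, 12, 13)
        ])
        # a repulsive coil's Rg fluctuates freely, so use a looser plateau
        rg_rep = np.mean([
            radius_of_gyration(equilibrate(wca, seed=s, rg_tol=0.08).positions)
            for s in (11, 12, 13)
        ])
        assert rg_rep > rg_attr

    def test_deterministic_under_fixed_seed(self, tiny_params):
        f1 = equilibrate(tiny_params, seed=5)
        f2 = equilibrate(tiny_params, seed=5)
        assert np.array_equal(f1.positions, f2.positions)


class TestSimulate:
    def test_bit_identical_trajectories_for_same_seed(self, tiny_params):
        t1 = simulate(tiny_params, replicas=[0])[0]
        t2 = simulate(tiny_params, replicas=[0])[0]
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.tensions, t2.tensions)

    def test_replicas_are_distinct(self, tiny_params):
        t1, t2 = simulate(tiny_params, replicas=[0, 1])
        assert not np.array_equal(t1.positions, t2.positions)

    def test_shear_extends_chain_in_flow_direction(self, tiny_params):
        sheared = simulate(tiny_params, replicas=[0])[0]
        quiet = simulate(tiny_params.replaced(shear_rate=0.0), replicas=[0])[0]

        def mean_x_span(tr):
            x = tr.positions[:, :, 0]
            return (x.max(axis=1) - x.min(axis=1)).mean()

        assert mean_x_span(sheared) > mean_x_span(quiet)

    def test_tension_count_matches_monomers(self, tiny_params):
        p = tiny_params.replaced(n_beads=100, n_samples=3)
        traj = simulate(p, replicas=[0])[0]
        assert traj.tensions.shape == (3, 50)

    def test_frame_times_uniform(self, tiny_params):
        traj = simulate(tiny_params, replicas=[0])[0]
        dt = np.diff(traj.times)
        assert np.allclose(dt, dt[0])
        with pytest.raises(ValueError):
            Trajectory(traj.times[::-1], traj.positions, traj.tensions, tiny_params)


class TestRpyMobility:
    def test_symmetric_positive_definite(self, rng):
        p = SimParams(n_beads=6)
        pos = rng.standard_normal((6, 3)) * 60.0
        m = _rpy_mobility(pos, p)
        assert np.allclose(m, m.T)
        assert np.all(np.linalg.eigvalsh(m) > 0)

    def test_far_apart_beads_decouple_toward_stokes_drag(self):
        p = SimParams(n_beads=4)
        pos = np.array([[0, 0, 0], [1e6, 0, 0], [2e6, 0, 0], [3e6, 0, 0]], dtype=float)
        m = _rpy_mobility(pos, p)
        off = m.copy()
        for i in range(4):
            off[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = 0.0
        assert np.abs(off).max() < 1e-4 / p.zeta
        assert m[0, 0] == pytest.approx(1.0 / p.zeta)
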