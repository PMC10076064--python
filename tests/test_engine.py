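"""Engine correctness: forces vs numerical gradients, constraints,
integrator order, thermostats, barostat, tail corrections, run loop."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from aquarigid import constants as c
from aquarigid.core import SITES_PER_MOL, SystemState, Topology
from aquarigid.engine import (ForceField, RunConfig, apply_constraints,
                              initialize_velocities, kinetic_energy,
                              lj_tail_correction, project_velocities,
                              run, temperature, thermostat_step,
                              velocity_verlet_step)
from aquarigid.errors import (BlowUpError, ConfigError, SingularityError)
from aquarigid.fixtures import (harmonic_water_model, ideal_gas_model,
                                water_lattice)
from aquarigid.models import monomer_positions


def water_box(model, n_side=2, density=0.0300, seed=1, jitter=0.0):
    return water_lattice(n_side**3, model, density=density, seed=seed,
                         jitter=jitter)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

class TestForceConsistency:
    @pytest.mark.parametrize("rigid", [True, False])
    def test_forces_match_central_differences(self, qtip4pf, qtip4pf_mg,
                                              rigid):
        """Every sampled force component is the negative energy gradient
        on a random 8-water box (M site rebuilt at each displacement)."""
        model = qtip4pf_mg if rigid else qtip4pf
        state, topo = water_box(model, n_side=2, density=0.008, seed=3,
                                jitter=1.0)
        cfg = RunConfig(cutoff=4.9, ewald_accuracy=1e-8,
                        tail_correction=False)
        ff = ForceField(topo, cfg)
        f, rep = ff.compute(state)
        h = 1e-5
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(16):
            s = int(rng.integers(0, topo.n_sites))
            if s % SITES_PER_MOL == 3:
                s -= 1                      # M is not an independent site
            a = int(rng.integers(0, 3))
            xp, xm = state.copy(), state.copy()
            xp.positions[s, a] += h
            xm.positions[s, a] -= h
            ep = ForceField(topo, cfg).compute(xp)[1].potential
            em = ForceField(topo, cfg).compute(xm)[1].potential
            worst = max(worst, abs(-(ep - em) / (2 * h) - f[s, a]))
        assert worst < 1e-6 * max(1.0, np.abs(f).max())

    def test_energy_report_total_is_sum_of_parts(self, qtip4pf_mg):
        state, topo = water_box(qtip4pf_mg, seed=4)
        cfg = RunConfig(cutoff=3.1, tail_correction=True)
        _, rep = ForceField(topo, cfg).compute(state)
        parts = (rep.kinetic + rep.lj + rep.coul_real + rep.coul_recip
                 + rep.coul_self_excl + rep.intramolecular + rep.tail)
        assert rep.total == pytest.approx(parts, rel=1e-9)

    def test_distant_monomers_noninteracting(self, qtip4pf_mg):
        """Two monomers 25 Å apart with an 9 Å cutoff: LJ and real-space
        Coulomb vanish; only tiny reciprocal dipole-dipole energy remains."""
        base = monomer_positions(qtip4pf_mg.model_geometry,
                                 qtip4pf_mg.msite_a)
        pos = np.concatenate([base + 5.0, base + 30.0])
        state = SystemState(pos, np.zeros_like(pos), np.full(3, 50.0))
        topo = Topology(qtip4pf_mg, 2)
        cfg = RunConfig(cutoff=9.0, tail_correction=False)
        _, rep = ForceField(topo, cfg).compute(state)
        assert rep.lj == 0.0
        assert abs(rep.coul_real) < 1e-8
        assert abs(rep.potential) < 0.05

    def test_msite_force_redistribution_preserves_net_force(self, qtip4pf_mg):
        state, topo = water_box(qtip4pf_mg, seed=6)
        cfg = RunConfig(cutoff=3.1, tail_correction=False)
        f, _ = ForceField(topo, cfg).compute(state)
        fm = f.reshape(topo.n_molecules, SITES_PER_MOL, 3)
        assert np.allclose(fm[:, 3], 0.0)                 # M carries none
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)  # Newton's third law

    def test_overlapping_sites_raise_singularity(self, qtip4pf_mg):
        base = monomer_positions(qtip4pf_mg.model_geometry,
                                 qtip4pf_mg.msite_a)
        pos = np.concatenate([base + 10.0, base + 10.0 + 0.03])
        state = SystemState(pos, np.zeros_like(pos), np.full(3, 30.0))
        topo = Topology(qtip4pf_mg, 2)
        with pytest.raises(SingularityError):
            ForceField(topo, RunConfig(cutoff=9.0,
                                       tail_correction=False)).compute(state)


class TestTailCorrection:
    def test_infinite_cutoff_vanishes(self, qtip4pf_mg):
        e, p = lj_tail_correction(0.0334, qtip4pf_mg, 1e6)
        assert abs(e) < 1e-12 and abs(p) < 1e-9

    def test_wail_schema_zero_regardless_of_cutoff(self, qtip4pf):
        from dataclasses import replace
        no_tail = replace(qtip4pf, apply_dispersion_tail=False)
        assert lj_tail_correction(0.0334, no_tail, 9.0) == (0.0, 0.0)

    def test_matches_numerical_quadrature(self, qtip4pf_mg):
        """Energy tail equals 2πρ ∫ u(r) r² dr beyond the cutoff."""
        rho, rc = 0.0334, 9.0
        lj = qtip4pf_mg.lj_sites["O"]

        def u(r):
            sr6 = (lj.sigma / r) ** 6
            return 4.0 * lj.epsilon * (sr6**2 - sr6) * r * r

        expect = 2.0 * math.pi * rho * quad(u, rc, np.inf)[0]
        e, _ = lj_tail_correction(rho, qtip4pf_mg, rc)
        assert e == pytest.approx(expect, rel=1e-10)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

class TestConstraints:
    def _topo(self, model, n=4, seed=0):
        rng = np.random.default_rng(seed)
        base = monomer_positions(model.model_geometry, model.msite_a)
        pos = np.concatenate([base + rng.normal(0, 8, 3) for _ in range(n)])
        return pos, Topology(model, n)

    def test_satisfied_geometry_is_identity(self, qtip4pf_mg):
        pos, topo = self._topo(qtip4pf_mg)
        vel = np.zeros_like(pos)
        out, v = apply_constraints(pos, pos.copy(), vel, topo, tol=1e-10)
        assert np.allclose(out, pos, atol=1e-12)

    def test_noise_restored_within_tol_com_preserved(self, qtip4pf_mg):
        pos, topo = self._topo(qtip4pf_mg, seed=1)
        rng = np.random.default_rng(2)
        pert = pos + rng.normal(0, 1e-3, pos.shape)
        vel = np.zeros_like(pos)
        out, _ = apply_constraints(pos, pert, vel, topo, tol=1e-10)
        g = qtip4pf_mg.rigid_geometry
        p = out.reshape(-1, SITES_PER_MOL, 3)
        for (a, b), d0 in zip(((0, 1), (0, 2), (1, 2)),
                              (g.r_OH, g.r_OH, g.r_HH)):
            d = np.linalg.norm(p[:, a] - p[:, b], axis=1)
            assert np.abs(d / d0 - 1.0).max() < 1e-9
        m = np.array([c.MASS_O, c.MASS_H, c.MASS_H, 0.0])
        com_in = (pert.reshape(-1, 4, 3) * m[None, :, None]).sum(1)
        com_out = (p * m[None, :, None]).sum(1)
        assert np.abs(com_out - com_in).max() < 1e-12

    def test_velocity_projection_removes_bond_rates(self, qtip4pf_mg):
        pos, topo = self._topo(qtip4pf_mg, seed=3)
        rng = np.random.default_rng(4)
        vel = rng.normal(0, 0.01, pos.shape)
        v = project_velocities(pos, vel, topo)
        p = pos.reshape(-1, 4, 3)
        vv = v.reshape(-1, 4, 3)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            d = p[:, a] - p[:, b]
            assert np.abs(((vv[:, a] - vv[:, b]) * d).sum(1)).max() < 1e-12

    def test_linear_momentum_unchanged_by_projection(self, qtip4pf_mg):
        pos, topo = self._topo(qtip4pf_mg, seed=5)
        rng = np.random.default_rng(6)
        vel = rng.normal(0, 0.01, pos.shape)
        vel[3::4] = 0.0
        m = topo.masses
        v = project_velocities(pos, vel, topo)
        assert np.allclose((m[:, None] * v).sum(0),
                           (m[:, None] * vel).sum(0), atol=1e-12)

    def test_long_rigid_dimer_run_zero_bond_drift(self, qtip4pf_mg):
        """Rigid NVE water dimer, 2 fs steps, 10 ps: constrained distances
        hold to the solver tolerance throughout."""
        base = monomer_positions(qtip4pf_mg.model_geometry,
                                 qtip4pf_mg.msite_a)
        pos = np.concatenate([base + 14.0, base + 14.0 + [2.9, 0.4, 0.2]])
        state = SystemState(pos, np.zeros_like(pos), np.full(3, 28.0))
        topo = Topology(qtip4pf_mg, 2)
        initialize_velocities(state, topo, 200.0, seed=9)
        cfg = RunConfig(timestep=2.0, ensemble="NVE", cutoff=9.0,
                        tail_correction=False, output_every=500)
        traj = run(state, topo, cfg, 5000)
        g = qtip4pf_mg.rigid_geometry
        p = traj.positions[-1].reshape(-1, 4, 3)
        d = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        assert np.abs(d - g.r_OH).max() < 1e-6


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

class TestIntegrator:
    def test_zero_forces_zero_velocities_only_time_advances(self):
        model = ideal_gas_model()   # fully non-interacting
        state, topo0 = water_box(model, n_side=2, density=0.01)
        cfg = RunConfig(timestep=1.0, cutoff=6.0, tail_correction=False)
        f = np.zeros_like(state.positions)
        new, _, _ = velocity_verlet_step(state, f, topo0, cfg)
        assert np.allclose(new.positions, state.positions)
        assert np.allclose(new.velocities, 0.0)
        assert new.time == state.time + 1.0

    def test_free_rigid_water_conserves_kinetic_energy(self):
        model = ideal_gas_model()
        state, topo = water_box(model, n_side=2, density=0.005)
        initialize_velocities(state, topo, 300.0, seed=2)
        cfg = RunConfig(timestep=1.0, ensemble="NVE", cutoff=6.0,
                        tail_correction=False, blowup_bound=1e9)
        k0 = kinetic_energy(state.velocities, topo.masses)
        ff = ForceField(topo, cfg)
        f, _ = ff.compute(state)
        for _ in range(50):
            state, f, rep = velocity_verlet_step(state, f, topo, cfg, ff)
        k1 = kinetic_energy(state.velocities, topo.masses)
        assert k1 == pytest.approx(k0, rel=1e-10)

    def test_integration_error_is_second_order(self):
        """Halving the timestep reduces the energy error ~4x for a single
        flexible harmonic molecule with an excited stretch."""
        model = harmonic_water_model(flexible=True)
        base = monomer_positions(model.model_geometry, model.msite_a)
        errs = []
        for dt in (1.0, 0.5):
            pos = base.copy() + 10.0
            d = pos[1] - pos[0]
            pos[1] += 0.02 * d / np.linalg.norm(d)
            state = SystemState(pos, np.zeros_like(pos), np.full(3, 20.0))
            topo = Topology(model, 1)
            cfg = RunConfig(timestep=dt, ensemble="NVE", cutoff=6.0,
                            tail_correction=False, output_every=1)
            traj = run(state, topo, cfg, int(round(200.0 / dt)))
            e = traj.energies["total"].to_numpy()
            errs.append(np.abs(e - e[0]).max())
        assert errs[0] / errs[1] > 2.5   # ~4 expected for O(dt²)

    def test_stretch_mode_frequency_matches_hessian(self):
        """The oscillation period of an excited molecule matches the
        normal-mode frequency from a numerical mass-weighted Hessian."""
        model = harmonic_water_model(flexible=True)
        base = monomer_positions(model.model_geometry, model.msite_a) + 10.0
        topo = Topology(model, 1)
        cfg = RunConfig(timestep=0.25, ensemble="NVE", cutoff=6.0,
                        tail_correction=False, output_every=1)
        box = np.full(3, 20.0)

        # numerical Hessian over the 9 massive coordinates
        h = 1e-5
        masses = np.repeat([c.MASS_O, c.MASS_H, c.MASS_H], 3)
        H = np.zeros((9, 9))

        def grad(flat):
            pos = np.vstack([flat.reshape(3, 3), base[3]])
            st = SystemState(pos, np.zeros_like(pos), box)
            f, _ = ForceField(topo, cfg).compute(st)
            return -f[:3].reshape(-1)
        flat0 = base[:3].reshape(-1).copy()
        for k in range(9):
            fp = flat0.copy()
            fp[k] += h
            fm = flat0.copy()
            fm[k] -= h
            H[:, k] = (grad(fp) - grad(fm)) / (2 * h)
        Hm = H / np.sqrt(np.outer(masses, masses))
        w2 = np.sort(np.linalg.eigvalsh(Hm)) * c.FORCE_TO_ACC
        # highest mode: symmetric/antisymmetric stretch, rad/fs
        omega = math.sqrt(max(w2))

        # excite a stretch and measure the dominant frequency
        pos = base.copy()
        d = pos[1] - pos[0]
        pos[1] += 0.01 * d / np.linalg.norm(d)
        state = SystemState(pos, np.zeros_like(pos), box)
        traj = run(state, topo, cfg, 4800)
        bond = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0],
                              axis=1)
        sig = bond - bond.mean()
        freqs = np.fft.rfftfreq(len(sig), d=0.25) * 2.0 * math.pi
        peak = freqs[np.argmax(np.abs(np.fft.rfft(sig))[1:]) + 1]
        assert peak == pytest.approx(omega, rel=0.03)

    def test_momentum_conserved_in_nve(self, equilibrated_rigid_box):
        state, topo, _ = equilibrated_rigid_box
        cfg = RunConfig(timestep=1.0, ensemble="NVE", cutoff=4.5,
                        tail_correction=False, remove_com_every=0,
                        output_every=1000)
        m = topo.masses
        traj = run(state, topo, cfg, 1000)
        p0 = (m[:, None] * state.velocities).sum(0)
        p1 = (m[:, None] * traj.final_state.velocities).sum(0)
        assert np.abs(p1 - p0).max() < 1e-10


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

class TestRunLoop:
    def test_nve_drift_small_at_half_fs(self, equilibrated_rigid_box):
        """Rigid-water NVE at 0.5 fs over 2 ps drifts ≪ 0.01% (the 10 ps
        check lives in the acceptance suite)."""
        state, topo, _ = equilibrated_rigid_box
        cfg = RunConfig(timestep=0.5, ensemble="NVE", cutoff=4.5,
                        tail_correction=False, output_every=400)
        traj = run(state, topo, cfg, 2000)
        assert abs(traj.meta["drift_relative"]) < 1e-4

    def test_two_fs_rigid_nve_within_ten_times_half_fs_drift(
            self, equilibrated_rigid_box):
        """2 fs rigid NVE drifts, but its secular slope is no worse than
        10× the 0.5 fs run — the documented caution about large-step
        microcanonical runs.  The slope is fitted past the initial
        transient because the larger step's O(dt²) energy *fluctuation*
        (≈16×) is not drift."""
        state, topo, _ = equilibrated_rigid_box
        slopes, slope_errs = {}, {}
        for dt in (0.5, 2.0):
            cfg = RunConfig(timestep=dt, ensemble="NVE", cutoff=4.5,
                            tail_correction=False,
                            output_every=int(round(100.0 / dt)))
            traj = run(state, topo, cfg, int(round(6000.0 / dt)))
            e = traj.energies
            t = e["time"].to_numpy()
            tot = e["total"].to_numpy()
            sel = t > 500.0
            coef, cov = np.polyfit(t[sel], tot[sel], 1, cov=True)
            slopes[dt] = abs(coef[0]) / abs(tot.mean())
            slope_errs[dt] = np.sqrt(cov[0, 0]) / abs(tot.mean())
        # the 2 fs secular slope, beyond its own measurement noise, is
        # bounded by 10x the 0.5 fs slope
        assert slopes[2.0] - 3.0 * slope_errs[2.0] < \
            10.0 * max(slopes[0.5], 1e-9)

    def test_same_seed_identical_output(self, equilibrated_rigid_box):
        state, topo, _ = equilibrated_rigid_box
        cfg = RunConfig(timestep=1.0, ensemble="NVT", T_target=280.0,
                        tau_t=200.0, cutoff=4.5, tail_correction=False,
                        seed=99, output_every=50)
        t1 = run(state, topo, cfg, 300)
        t2 = run(state, topo, cfg, 300)
        assert np.array_equal(t1.positions, t2.positions)
        assert t1.energies.equals(t2.energies)

    def test_nvt_ideal_gas_equipartition(self):
        """Mean kinetic energy of a thermostatted ideal gas matches
        (Ndof/2) kT."""
        model = ideal_gas_model()
        state, topo = water_box(model, n_side=3, density=0.005)
        initialize_velocities(state, topo, 250.0, seed=3)
        cfg = RunConfig(timestep=2.0, ensemble="NVT", T_target=250.0,
                        tau_t=200.0, cutoff=8.0, tail_correction=False,
                        seed=4, output_every=10)
        traj = run(state, topo, cfg, 20000)
        t_mean = traj.energies["temperature"][200:].mean()
        assert t_mean == pytest.approx(250.0, rel=0.02)

    def test_blowup_detected(self):
        """A timestep far beyond the stretch period makes a flexible
        model's energy diverge, which the run loop must flag."""
        model = harmonic_water_model(flexible=True)
        state, topo = water_box(model, n_side=2, density=0.01, seed=8)
        initialize_velocities(state, topo, 300.0, seed=8)
        cfg = RunConfig(timestep=25.0, ensemble="NVE", cutoff=4.0,
                        tail_correction=False, blowup_bound=5.0,
                        output_every=1)
        with pytest.raises((BlowUpError, SingularityError)):
            run(state, topo, cfg, 400)

    def test_nve_config_forbids_thermostat_flags(self):
        cfg = RunConfig(ensemble="NVE")
        assert not cfg.thermostat_active and not cfg.barostat_active
        with pytest.raises(ConfigError):
            RunConfig(timestep=-1.0)


# ---------------------------------------------------------------------------
# thermostats
# ---------------------------------------------------------------------------

class TestThermostats:
    def _gas(self, n_side=3, T=300.0, seed=0):
        model = ideal_gas_model()
        state, topo = water_box(model, n_side=n_side, density=0.004,
                                seed=seed)
        initialize_velocities(state, topo, T, seed=seed)
        return state, topo

    def test_target_equals_current_near_identity(self):
        state, topo = self._gas()
        t0 = temperature(state.velocities, topo)
        v0 = state.velocities.copy()
        # deterministic part: infinite relaxation time → no rescale
        thermostat_step(state, topo, "nose_hoover", tau=1e9, T_target=t0,
                        dt=1.0)
        assert np.allclose(state.velocities, v0, rtol=1e-8)

    @pytest.mark.parametrize("kind", ["nose_hoover", "stochastic_rescale"])
    def test_canonical_mean_and_variance(self, kind):
        """Ideal gas under either thermostat: mean T on target within 2%,
        kinetic-energy fluctuations near the canonical value."""
        state, topo = self._gas(n_side=3, T=220.0, seed=11)
        cfg = RunConfig(timestep=2.0, ensemble="NVT", thermostat=kind,
                        T_target=260.0, tau_t=100.0, cutoff=8.0,
                        tail_correction=False, seed=12, output_every=5)
        traj = run(state, topo, cfg, 25000)
        t = traj.energies["temperature"].to_numpy()[200:]
        assert t.mean() == pytest.approx(260.0, rel=0.02)
        ndof = topo.n_dof()
        var_expect = 2.0 * 260.0**2 / ndof
        assert np.var(t) == pytest.approx(var_expect, rel=0.25)

    def test_stochastic_rescale_deterministic_under_seed(self):
        state, topo = self._gas(seed=5)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        s1, s2 = state.copy(), state.copy()
        for _ in range(10):
            thermostat_step(s1, topo, "stochastic_rescale", 100.0, 280.0,
                            1.0, rng=rng1)
            thermostat_step(s2, topo, "stochastic_rescale", 100.0, 280.0,
                            1.0, rng=rng2)
        assert np.array_equal(s1.velocities, s2.velocities)


# ---------------------------------------------------------------------------
# barostat
# ---------------------------------------------------------------------------

class TestBarostat:
    def test_no_rescale_at_target_pressure(self, qtip4pf_mg):
        from aquarigid.core import EnergyReport
        from aquarigid.engine import barostat_step
        state, topo = water_box(qtip4pf_mg, seed=9)
        rep = EnergyReport()
        rep.pressure_tensor = np.eye(3) * 500.0
        box0 = state.box.copy()
        barostat_step(state, topo, rep, tau=2000.0, P_target=500.0, dt=1.0)
        assert np.allclose(state.box, box0)

    def test_anisotropic_axes_relax_independently(self, tip4p_ice):
        """An ice cell under per-axis coupling changes its axis ratios."""
        from aquarigid import builders
        ice = builders.build_ice(32, seed=1)
        state, topo = ice.to_state(tip4p_ice)
        initialize_velocities(state, topo, 150.0, seed=1)
        cfg = RunConfig(timestep=2.0, ensemble="NPT", T_target=150.0,
                        tau_t=200.0, barostat_mode="anisotropic_orthorhombic",
                        tau_p=500.0, P_target=0.0, cutoff=3.8,
                        tail_correction=False, seed=2, output_every=100)
        traj = run(state, topo, cfg, 2000)
        r0 = state.box / state.box[0]
        r1 = traj.final_state.box / traj.final_state.box[0]
        assert not np.allclose(r0, r1, atol=1e-6)

    def test_npt_density_consistent_with_nvt_pressure_curve(self):
        """Monte-Carlo-barostat NPT density matches the density at which
        independent NVT runs give the target pressure (LJ fluid).

        The inversion error is propagated from the NVT block errors; the
        agreement tolerance is 2% or the 3-sigma statistical bound,
        whichever is larger at this system size."""
        model = ideal_gas_model()
        from dataclasses import replace
        from aquarigid.models import LJSite
        lj_model = replace(model, name="lj-fluid",
                           lj_sites={"O": LJSite(0.7749, 3.1589)})
        state, topo = water_lattice(64, lj_model, density=0.0095, seed=21)
        initialize_velocities(state, topo, 300.0, seed=21)
        npt = RunConfig(timestep=2.0, ensemble="NPT", barostat="monte_carlo",
                        T_target=300.0, tau_t=200.0, P_target=400.0,
                        cutoff=7.0, tail_correction=False, seed=22,
                        output_every=20, mc_volume_every=10, mc_dlnv=0.03)
        traj = run(state, topo, npt, 12000)
        sel = traj.times > traj.times[-1] / 3
        rho_npt = (topo.n_molecules / traj.boxes[sel].prod(axis=1)).mean()

        # oracle: NVT pressure at two bracketing densities, inverted
        def nvt_pressure(rho, seed):
            st, tp = water_lattice(64, lj_model, density=rho, seed=seed)
            initialize_velocities(st, tp, 300.0, seed=seed)
            nvt = RunConfig(timestep=2.0, ensemble="NVT", T_target=300.0,
                            tau_t=200.0, cutoff=7.0, tail_correction=False,
                            seed=seed, output_every=10)
            tr = run(st, tp, nvt, 20000)
            p = tr.energies["pressure"].to_numpy()[200:]
            bm = np.array([b.mean() for b in np.array_split(p, 10)])
            return bm.mean(), bm.std(ddof=1) / math.sqrt(10)

        r1, r2 = rho_npt * 0.94, rho_npt * 1.06
        p1, s1 = nvt_pressure(r1, 23)
        p2, s2 = nvt_pressure(r2, 24)
        assert p2 > p1                       # monotone equation of state
        slope = (p2 - p1) / (r2 - r1)
        rho_inverted = r1 + (400.0 - p1) / slope
        rho_err = math.hypot(s1, s2) / slope
        tol = max(0.02 * rho_npt, 3.0 * rho_err)
        assert abs(rho_npt - rho_inverted) < tol
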