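"""Deterministic synthetic fixtures with embedded ground truth.

Each generator owns an independent RNG stream derived from (seed, kind),
so adding fixtures never perturbs existing ones, and stores its
ground-truth parameters in ``Trajectory.meta["truth"]`` for the test
harness to read back.  These fixtures exercise the estimators — they do
not emulate water thermodynamics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from . import constants as c
from .core import SITES_PER_MOL, SystemState, Topology, Trajectory
from .engine import rebuild_msites
from .models import (BendTerm, LJSite, MonomerGeometry, StretchTerm,
                     WaterModel, monomer_dipole, monomer_positions)

__all__ = ["FixtureSpec", "rng_for", "gen_ideal_dipole_gas", "gen_brownian",
           "gen_plateau_pair", "gen_parabola_density", "water_lattice",
           "ideal_gas_model", "harmonic_water_model", "random_rotations"]


@dataclass(frozen=True)
class FixtureSpec:
    """Descriptor of a generated fixture: kind, parameters, ground truth."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def rng_for(kind: str, seed: int) -> np.random.Generator:
    """Independent RNG stream per fixture kind."""
    return np.random.default_rng([seed, zlib.crc32(kind.encode()) & 0x7FFFFFFF])


def random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices via unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                  2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                  2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                  1 - 2 * (x * x + y * y)], axis=-1),
    ], axis=1)


# ---------------------------------------------------------------------------
# model variants used by fixtures
# ---------------------------------------------------------------------------

def ideal_gas_model(mu: float = 0.0,
                    geom: MonomerGeometry = MonomerGeometry(0.9572, 104.52),
                    a: float = 0.13) -> WaterModel:
    """Rigid four-site model with no LJ and charges tuned to dipole ``mu`` D.

    With mu = 0 the model is fully non-interacting (an ideal gas of
    rigid rotors).
    """
    probe = WaterModel(name="probe", q_H=1.0, msite_a=a, mode="MG",
                       rigid_geometry=geom, apply_dispersion_tail=False)
    mu_unit = monomer_dipole(probe)
    q_h = mu / mu_unit if mu else 0.0
    return WaterModel(name=f"dipole-gas-{mu:g}D", q_H=q_h, msite_a=a,
                      mode="MG", rigid_geometry=geom,
                      apply_dispersion_tail=False)


def harmonic_water_model(flexible: bool = True, interacting: bool = False,
                         k_r: float = 3000.0, k_theta: float = 400.0,
                         geom: MonomerGeometry = MonomerGeometry(0.9572, 104.52),
                         ) -> WaterModel:
    """Harmonic water for equipartition tests.

    Fully harmonic intramolecular terms; intermolecular interactions off
    by default so the heat capacity is exactly the equipartition count.
    """
    lj = {"O": LJSite(0.65, 3.16)} if interacting else {}
    q = 0.5 if interacting else 0.0
    if flexible:
        return WaterModel(
            name="harmonic-water", q_H=q, msite_a=0.13, lj_sites=lj,
            stretch=StretchTerm(kind="harmonic", r0=geom.r_OH, k_r=k_r),
            bend=BendTerm(k_theta=k_theta, theta0=geom.theta_HOH), mode="FL",
            apply_dispersion_tail=False)
    return WaterModel(name="harmonic-water-rigid", q_H=q, msite_a=0.13,
                      lj_sites=lj, mode="MG", rigid_geometry=geom,
                      apply_dispersion_tail=False)


def water_lattice(n_molecules: int, model: WaterModel,
                  density: float = 0.0334, seed: int = 0,
                  jitter: float = 0.0) -> Tuple[SystemState, Topology]:
    """Molecules on a cubic grid with random orientations.

    ``density`` in molecules/Å³ (0.0334 ≈ 1 g/cm³).  A generic starting
    point for equilibration runs and estimator tests.
    """
    rng = rng_for("water_lattice", seed)
    n_side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = (1.0 / density) ** (1.0 / 3.0)
    base = monomer_positions(model.model_geometry, model.msite_a)
    rots = random_rotations(rng, n_molecules)
    cells = np.array([(i, j, k) for i in range(n_side)
                      for j in range(n_side) for k in range(n_side)]
                     [:n_molecules], dtype=float)
    centers = spacing * cells + spacing / 2.0
    if jitter:
        centers += rng.normal(0.0, jitter, centers.shape)
    pos = np.einsum("sd,nde->nse", base, np.transpose(rots, (0, 2, 1)))
    pos = (pos + centers[:, None, :]).reshape(-1, 3)
    box = np.full(3, n_side * spacing)
    topo = Topology(model, n_molecules)
    rebuild_msites(pos, topo)
    return SystemState(pos, np.zeros_like(pos), box), topo


# ---------------------------------------------------------------------------
# estimator oracles
# ---------------------------------------------------------------------------

def _thermalize_harmonic_geometry(state, model, n_molecules, T, rng):
    """Draw each monomer's bonds/angle from the harmonic canonical
    distribution at T (exact for independent harmonic terms); the
    orientation of each molecule is preserved."""
    from . import constants as _c
    from .engine import rebuild_msites
    from .core import SITES_PER_MOL as _S

    kt = _c.KB * T
    sig_r = np.sqrt(kt / model.stretch.harmonic_k)
    sig_th = np.sqrt(kt / model.bend.k_theta)
    pos = state.positions.reshape(n_molecules, _S, 3)
    for m in range(n_molecules):
        o, h1, h2 = pos[m, 0], pos[m, 1], pos[m, 2]
        u1 = (h1 - o) / np.linalg.norm(h1 - o)
        u2 = (h2 - o) / np.linalg.norm(h2 - o)
        b = u1 + u2
        b /= np.linalg.norm(b)
        p1 = u1 - (u1 @ b) * b
        p1 /= np.linalg.norm(p1)
        r1 = model.stretch.r0 + rng.normal(0.0, sig_r)
        r2 = model.stretch.r0 + rng.normal(0.0, sig_r)
        th = np.radians(model.bend.theta0) + rng.normal(0.0, sig_th)
        pos[m, 1] = o + r1 * (np.cos(th / 2) * b + np.sin(th / 2) * p1)
        pos[m, 2] = o + r2 * (np.cos(th / 2) * b - np.sin(th / 2) * p1)
    from .core import Topology as _T
    rebuild_msites(state.positions, _T(model, n_molecules))


def harmonic_cv_pair(flexible: bool, n_molecules: int = 128,
                     t_cold: float = 220.0, t_hot: float = 380.0,
                     n_draws: int = 8, equil_time: float = 3000.0,
                     nve_time: float = 2000.0, seed: int = 0):
    """Paired NVE runs of a harmonic (non-interacting) water box.

    For each of the two temperatures, ``n_draws`` configurations are
    sampled from stochastic-rescaling NVT parents and relaxed in NVE;
    the pooled energy logs form one trajectory per temperature, ready
    for the finite-difference heat capacity.  Classical equipartition
    fixes the answer: 6R for the flexible box (9 kinetic + 3 potential
    quadratic DOF per molecule), 3R for the rigid one — so the
    flexible-minus-rigid difference is 3R ≈ 25 J/(mol·K).
    """
    import pandas as pd
    from .core import Trajectory as _Trajectory
    from .engine import RunConfig, initialize_velocities, run

    model = harmonic_water_model(flexible=flexible)
    dt = 0.5 if flexible else 2.0
    pooled = []
    for ti, T in enumerate((t_cold, t_hot)):
        logs = []
        for draw in range(n_draws):
            sub = 10000 * ti + 100 * draw + seed
            state, topo = water_lattice(n_molecules, model, density=0.002,
                                        seed=sub)
            if flexible:
                # canonical geometry draw: without it, non-interacting
                # molecules under a global thermostat would keep a
                # non-canonical vibrational energy share forever
                _thermalize_harmonic_geometry(state, model, n_molecules,
                                              T, rng_for("cv_geom", sub))
            initialize_velocities(state, topo, T, seed=sub + 1)
            nvt = RunConfig(timestep=dt, ensemble="NVT",
                            thermostat="stochastic_rescale", tau_t=100.0,
                            T_target=T, cutoff=6.0, tail_correction=False,
                            seed=sub + 2, output_every=10**9)
            eq = run(state, topo, nvt, max(1, int(round(equil_time / dt))))
            nve = RunConfig(timestep=dt, ensemble="NVE", cutoff=6.0,
                            tail_correction=False, seed=sub + 3,
                            output_every=max(1, int(round(20.0 / dt))))
            tr = run(eq.final_state, topo, nve,
                     max(1, int(round(nve_time / dt))))
            logs.append(tr.energies)
        df = pd.concat(logs, ignore_index=True)
        pooled.append(_Trajectory(np.zeros((1, 4, 3)), np.ones((1, 3)),
                                  np.zeros(1), energies=df,
                                  meta={"T_parent": T, "n_draws": n_draws,
                                        "flexible": flexible}))
    return pooled[1], pooled[0]   # (hot, cold)


def gen_ideal_dipole_gas(n: int, mu: float, T: float, volume: float,
                         n_frames: int, seed: int = 0) -> Trajectory:
    """Independently, uniformly oriented rigid dipoles, re-drawn each frame.

    The orientational dielectric constant of non-interacting dipoles is
    known in closed form:  ε_o − 1 = 4π ρ μ² / (3 k_B T)  (Gaussian
    units folded into the Coulomb constant).  Stored in meta["truth"].
    """
    rng = rng_for("ideal_dipoles", seed)
    model = ideal_gas_model(mu=mu)
    topo = Topology(model, n)
    base = monomer_positions(model.model_geometry, model.msite_a)
    L = volume ** (1.0 / 3.0)
    frames = np.empty((n_frames, n * SITES_PER_MOL, 3))
    for f in range(n_frames):
        rots = random_rotations(rng, n)
        centers = rng.uniform(0.0, L, (n, 3))
        pos = np.einsum("sd,nde->nse", base, np.transpose(rots, (0, 2, 1)))
        frames[f] = (pos + centers[:, None, :]).reshape(-1, 3)
    mu_ea = mu / c.EA_TO_DEBYE
    eps_true = 1.0 + (4.0 * np.pi * c.COULOMB * n * mu_ea**2
                      / (3.0 * volume * c.KB * T))
    boxes = np.tile(np.full(3, L), (n_frames, 1))
    times = np.arange(n_frames, dtype=float)
    return Trajectory(frames, boxes, times, topology=topo,
                      meta={"truth": {"eps_o": eps_true, "mu_D": mu,
                                      "T": T, "volume": volume},
                            "seed": seed, "kind": "ideal_dipoles"})


def gen_brownian(n: int, d_true: float, dt: float, n_steps: int,
                 seed: int = 0, box_length: float = 1000.0) -> Trajectory:
    """Brownian molecules: Gaussian COM steps of variance 2 D dt per axis.

    ``d_true`` in 1e-5 cm²/s (the unit the diffusion estimator reports),
    ``dt`` in fs.  Positions are unwrapped; the box is a large formality.
    """
    rng = rng_for("brownian", seed)
    model = ideal_gas_model(mu=0.0)
    topo = Topology(model, n)
    base = monomer_positions(model.model_geometry, model.msite_a)
    d_int = d_true * 1.0e-4            # Å²/fs
    steps = rng.normal(0.0, np.sqrt(2.0 * d_int * dt), (n_steps, n, 3))
    com = np.concatenate([np.zeros((1, n, 3)), np.cumsum(steps, axis=0)])
    com += box_length / 2.0
    frames = (com[:, :, None, :] + base[None, None, :, :]).reshape(
        n_steps + 1, -1, 3)
    boxes = np.tile(np.full(3, box_length), (n_steps + 1, 1))
    times = dt * np.arange(n_steps + 1, dtype=float)
    return Trajectory(frames, boxes, times, topology=topo,
                      meta={"truth": {"D": d_true, "dt_fs": dt},
                            "seed": seed, "kind": "brownian"})


def gen_plateau_pair(t_plateau: float, gap_initial: float, relax_time: float,
                     noise: float, length: float, dt: float = 100.0,
                     seed: int = 0, split_plateaus: float = 0.0):
    """Two mean-reverting temperature traces converging to a plateau.

    T_lo/T_hi start gap_initial/2 below/above ``t_plateau`` and relax
    exponentially with time constant ``relax_time`` (fs), plus AR(1)
    noise of stationary standard deviation ``noise``.  With
    ``split_plateaus`` > 0 the two traces relax to different plateaus
    (the non-converged, lost-coexistence scenario).  Returns
    ((times, T_lo), (times, T_hi), truth dict).
    """
    rng = rng_for("plateau_pair", seed)
    times = np.arange(0.0, length + 0.5 * dt, dt)
    decay = np.exp(-times / relax_time)
    phi = np.exp(-dt / max(relax_time / 10.0, dt))
    sig_innov = noise * np.sqrt(1.0 - phi * phi)

    def ar1():
        x = np.empty(len(times))
        x[0] = rng.normal(0.0, noise) if noise else 0.0
        for i in range(1, len(times)):
            x[i] = phi * x[i - 1] + (rng.normal(0.0, sig_innov)
                                     if noise else 0.0)
        return x

    lo_plateau = t_plateau - split_plateaus / 2.0
    hi_plateau = t_plateau + split_plateaus / 2.0
    lo = lo_plateau - (gap_initial / 2.0) * decay + ar1()
    hi = hi_plateau + (gap_initial / 2.0) * decay + ar1()
    truth = {"t_plateau": t_plateau, "gap_initial": gap_initial,
             "relax_time": relax_time, "noise": noise,
             "split_plateaus": split_plateaus, "dt": dt}
    return (times, lo), (times, hi), truth


def gen_parabola_density(tmd_true: float, curvature: float,
                         grid: np.ndarray, noise: float,
                         seed: int = 0, rho_max: float = 1000.0,
                         monotone: bool = False) -> Tuple[np.ndarray, dict]:
    """(T, rho, rho_err) table: parabola peaked at ``tmd_true`` plus noise.

    ``curvature`` in kg/m³/K², ``noise`` the per-point Gaussian sigma in
    kg/m³.  ``monotone`` produces a strictly decreasing curve instead
    (the no-TMD scenario).  Returns (curve, truth dict).
    """
    rng = rng_for("parabola_density", seed)
    grid = np.asarray(grid, dtype=float)
    if monotone:
        rho = rho_max - curvature * (grid - grid.min()) ** 2
    else:
        rho = rho_max - curvature * (grid - tmd_true) ** 2
    rho = rho + (rng.normal(0.0, noise, len(grid)) if noise else 0.0)
    err = np.full(len(grid), noise if noise else 0.0)
    curve = np.column_stack([grid, rho, err])
    truth = {"tmd": None if monotone else tmd_true, "curvature": curvature,
             "noise": noise, "rho_max": rho_max}
    return curve, truth
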