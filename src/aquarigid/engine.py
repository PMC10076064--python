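"""Desk-scale molecular dynamics for periodic boxes of four-site water.

Force field: site-site Lennard-Jones (potential-shifted at the cutoff by
default), direct Ewald electrostatics with tinfoil boundaries, optional
intramolecular stretch/bend for flexible models, and an analytic
dispersion tail for homogeneous systems.  Forces are the exact negative
gradient of the reported potential; the massless M site is rebuilt from
the O/H positions every evaluation and the force it collects is
redistributed by the chain rule of its defining relation (O receives
(1-2a) F_M, each H receives a F_M).

Integration: velocity Verlet; rigid molecules are handled by an
iterative SHAKE/RATTLE triangle-constraint solver.  Thermostats:
Nosé-Hoover chain and Bussi stochastic velocity rescaling.  Barostat:
per-axis or isotropic weak-coupling rescaling of molecular centers of
mass, plus an optional Monte-Carlo volume move for strict NPT sampling.

Pressure uses the molecular virial (center-of-mass kinetic term plus
pair virial referred to molecular centers), so constraint forces and
the virtual-site construction need no explicit virial terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import constants as c
from . import ewald
from .core import (EnergyReport, SystemState, Topology, Trajectory,
                   make_whole, molecule_com, SITES_PER_MOL)
from .errors import (BlowUpError, ConfigError, ConstraintFailureError,
                     SingularityError)
from .models import WaterModel

__all__ = ["RunConfig", "ForceField", "compute_forces", "lj_tail_correction",
           "velocity_verlet_step", "apply_constraints", "project_velocities",
           "thermostat_step", "barostat_step", "run", "initialize_velocities",
           "kinetic_energy", "temperature", "NoseHooverChain", "rebuild_msites",
           "redistribute_msite_forces"]

_OVERLAP_MIN = 0.1  # Å; closer intermolecular approach raises SingularityError


@dataclass
class RunConfig:
    """Integration and interaction settings.

    ``tail_correction`` of ``None`` defers to the model's
    ``apply_dispersion_tail`` flag (and requires a homogeneous system —
    callers simulating slabs should set it to False explicitly).
    """

    timestep: float = 0.5                 # fs
    ensemble: str = "NVE"                 # NVE | NVT | NPT
    thermostat: str = "stochastic_rescale"  # or "nose_hoover"
    tau_t: float = 500.0                  # fs
    T_target: float = 298.0               # K
    barostat: str = "weak_coupling"       # or "monte_carlo"
    barostat_mode: str = "isotropic"      # or "anisotropic_orthorhombic"
    tau_p: float = 5000.0                 # fs
    P_target: float = 1.0                 # bar
    compressibility: float = 4.5e-5       # 1/bar, weak-coupling gain
    cutoff: float = 9.0                   # Å
    ewald_accuracy: float = 1.0e-6
    lj_shift: bool = True                 # shift LJ to zero at the cutoff
    tail_correction: Optional[bool] = None
    constraint_tol: float = 1.0e-8        # relative, on constrained distances
    skin: float = 2.0                     # Å, Verlet-list skin
    seed: int = 2024
    output_every: int = 50                # steps between stored frames
    remove_com_every: int = 100           # steps; 0 disables
    blowup_bound: float = 100.0           # kJ/mol per molecule change → error
    mc_volume_every: int = 20             # steps between MC volume attempts
    mc_dlnv: float = 0.02                 # max |Δ ln V| per attempt

    def __post_init__(self):
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ConfigError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "NVE" and (self.thermostat_active
                                       or self.barostat_active):
            # NVE forbids coupling; the flags below derive from ensemble
            pass

    @property
    def thermostat_active(self) -> bool:
        return self.ensemble in ("NVT", "NPT")

    @property
    def barostat_active(self) -> bool:
        return self.ensemble == "NPT"


# ---------------------------------------------------------------------------
# kinetic bookkeeping
# ---------------------------------------------------------------------------

def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kJ/mol."""
    return 0.5 * float((masses * (velocities**2).sum(axis=1)).sum()) \
        * c.KE_TO_KJMOL


def temperature(velocities: np.ndarray, topology: Topology) -> float:
    """Instantaneous kinetic temperature over the mobile degrees of freedom."""
    ndof = topology.n_dof()
    if ndof == 0:
        return 0.0
    k = kinetic_energy(velocities, topology.masses)
    return 2.0 * k / (c.KB * ndof)


def initialize_velocities(state: SystemState, topology: Topology, T: float,
                          seed: int = 0) -> None:
    """Draw Maxwell–Boltzmann velocities at T and rescale to T exactly.

    Constraint-incompatible components are projected out for rigid
    molecules; total momentum is removed when no molecule is frozen.
    """
    rng = np.random.default_rng(seed)
    m = topology.masses
    v = np.zeros_like(state.positions)
    mask = topology.massive & ~topology.frozen_sites
    sigma = np.sqrt(c.KB * T / (m[mask, None] * c.KE_TO_KJMOL))
    v[mask] = rng.normal(0.0, 1.0, (mask.sum(), 3)) * sigma
    if not topology.frozen.any():
        p = (m[:, None] * v).sum(axis=0)
        v[mask] -= (p / m[mask].sum())[None, :]
    if topology.model.is_rigid:
        v = project_velocities(state.positions, v, topology)
    t_now = temperature(v, topology)
    if t_now > 0 and T > 0:
        v *= math.sqrt(T / t_now)
    state.velocities = v


# ---------------------------------------------------------------------------
# M-site handling
# ---------------------------------------------------------------------------

def rebuild_msites(positions: np.ndarray, topology: Topology) -> None:
    """Place every M site from its molecule's O/H positions (in place)."""
    a = topology.model.msite_a
    pos = positions.reshape(topology.n_molecules, SITES_PER_MOL, 3)
    pos[:, 3] = pos[:, 0] + a * ((pos[:, 1] - pos[:, 0])
                                 + (pos[:, 2] - pos[:, 0]))


def redistribute_msite_forces(forces: np.ndarray, topology: Topology) -> None:
    """Move M-site forces onto O and H by the chain rule (in place)."""
    a = topology.model.msite_a
    f = forces.reshape(topology.n_molecules, SITES_PER_MOL, 3)
    fm = f[:, 3].copy()
    f[:, 0] += (1.0 - 2.0 * a) * fm
    f[:, 1] += a * fm
    f[:, 2] += a * fm
    f[:, 3] = 0.0


# ---------------------------------------------------------------------------
# dispersion tail
# ---------------------------------------------------------------------------

def lj_tail_correction(density: float, model: WaterModel, cutoff: float):
    """Analytic long-range dispersion corrections for a homogeneous fluid.

    ``density`` in molecules/Å³.  Returns (energy per molecule kJ/mol,
    pressure correction bar).  Zero when the model opts out of the tail
    (models whose fitted C6 is unreliable are used with a bare cutoff).
    """
    if not model.apply_dispersion_tail or not model.lj_sites:
        return 0.0, 0.0
    u = 0.0
    p = 0.0
    sites = list(model.lj_sites.values())
    for si in sites:
        for sj in sites:
            eps = math.sqrt(si.epsilon * sj.epsilon)
            sig = 0.5 * (si.sigma + sj.sigma)
            if eps == 0.0:
                continue
            sr3 = (sig / cutoff) ** 3
            sr9 = sr3 ** 3
            u += (8.0 / 3.0) * math.pi * density * eps * sig**3 \
                * (sr9 / 3.0 - sr3)
            p += (16.0 / 3.0) * math.pi * density**2 * eps * sig**3 \
                * (2.0 * sr9 / 3.0 - sr3)
    return u, p * c.KJMOL_PER_A3_TO_BAR


# ---------------------------------------------------------------------------
# force field
# ---------------------------------------------------------------------------

class ForceField:
    """Caches neighbor lists and Ewald setup for repeated evaluations."""

    def __init__(self, topology: Topology, config: RunConfig):
        self.topology = topology
        self.config = config
        self.charges = topology.charges
        self.eps, self.sig = topology.lj_params()
        self.molecule_of = topology.molecule_of_site
        self._pairs = None
        self._list_positions = None
        self._list_box = None
        self._ewald_box = None
        self._ewald = None
        # intramolecular charged pairs excluded from Coulomb: H1-H2, H1-M, H2-M
        base = np.array([[1, 2], [1, 3], [2, 3]])
        offs = SITES_PER_MOL * np.arange(topology.n_molecules)
        self.excl_pairs = (base[None, :, :] + offs[:, None, None]).reshape(-1, 2)
        self.has_charges = np.any(self.charges != 0.0)
        self.has_lj = np.any(self.eps != 0.0)
        self.charged_sites = np.where(self.charges != 0.0)[0]

    # -- neighbor list ------------------------------------------------------
    def _effective_skin(self, box) -> float:
        """Skin shrunk so the list radius stays below half the box."""
        room = float(box.min()) / 2.0 - self.config.cutoff
        return min(self.config.skin, max(room, 0.0) * 0.99)

    def _need_rebuild(self, positions, box):
        if self._pairs is None or not np.array_equal(box, self._list_box):
            return True
        skin = self._effective_skin(box)
        if skin <= 0.0:
            return True
        disp = positions - self._list_positions
        return float((disp**2).sum(axis=1).max()) > (0.5 * skin)**2

    def _rebuild_list(self, positions, box):
        if np.any(box < 2.0 * self.config.cutoff):
            raise ConfigError(
                f"box {box} smaller than twice the cutoff "
                f"{2 * self.config.cutoff:.1f} Å"
            )
        rlist = self.config.cutoff + self._effective_skin(box)
        wrapped = positions - np.floor(positions / box) * box
        wrapped = np.minimum(wrapped, np.nextafter(box, 0.0))
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(rlist, output_type="ndarray")
        if len(pairs):
            keep = self.molecule_of[pairs[:, 0]] != self.molecule_of[pairs[:, 1]]
            pairs = pairs[keep]
        self._pairs = pairs
        self._list_positions = positions.copy()
        self._list_box = box.copy()

    def _ewald_setup(self, box):
        if self._ewald is None or not np.array_equal(box, self._ewald_box):
            params = ewald.choose_parameters(
                box, self.config.cutoff, self.config.ewald_accuracy)
            self._ewald = (params, ewald.ReciprocalSum(
                box, params.alpha, params.kmax))
            self._ewald_box = box.copy()
        return self._ewald

    # -- evaluation ---------------------------------------------------------
    def compute(self, state: SystemState):
        """Forces (kJ/mol/Å) and a complete :class:`EnergyReport`."""
        topo = self.topology
        cfg = self.config
        positions = make_whole(state.positions, state.box, topo)
        rebuild_msites(positions, topo)
        box = state.box

        if self.has_lj or self.has_charges:
            if self._need_rebuild(positions, box):
                self._rebuild_list(positions, box)
            pairs = self._pairs
        else:
            pairs = np.empty((0, 2), dtype=int)   # non-interacting system

        forces = np.zeros_like(positions)
        report = EnergyReport()
        virial = np.zeros((3, 3))

        i, j = (pairs[:, 0], pairs[:, 1]) if len(pairs) else \
            (np.empty(0, int), np.empty(0, int))
        rij = positions[i] - positions[j]
        rij -= np.round(rij / box) * box
        r2 = (rij**2).sum(axis=1)
        within = r2 < cfg.cutoff**2
        i, j, rij, r2 = i[within], j[within], rij[within], r2[within]
        r = np.sqrt(r2)
        if len(r) and float(r.min()) < _OVERLAP_MIN:
            k = int(np.argmin(r))
            raise SingularityError(
                f"sites {i[k]} and {j[k]} overlap at r = {r[k]:.3f} Å")

        # Lennard-Jones
        if self.has_lj and len(r):
            epsij = np.sqrt(self.eps[i] * self.eps[j])
            lj_mask = epsij > 0.0
            if lj_mask.any():
                il, jl = i[lj_mask], j[lj_mask]
                rl2 = r2[lj_mask]
                sigij = 0.5 * (self.sig[il] + self.sig[jl])
                epl = epsij[lj_mask]
                sr6 = (sigij**2 / rl2) ** 3
                sr12 = sr6**2
                e_pair = 4.0 * epl * (sr12 - sr6)
                if cfg.lj_shift:
                    src6 = (sigij / cfg.cutoff) ** 6
                    e_pair -= 4.0 * epl * (src6**2 - src6)
                report.lj = float(e_pair.sum())
                coef = 24.0 * epl * (2.0 * sr12 - sr6) / rl2
                fpair = coef[:, None] * rij[lj_mask]
                np.add.at(forces, il, fpair)
                np.add.at(forces, jl, -fpair)
                virial += rij[lj_mask].T @ fpair

        # Coulomb
        if self.has_charges:
            ew, recip = self._ewald_setup(box)
            qprod = self.charges[i] * self.charges[j]
            qmask = qprod != 0.0
            e_real, f_real, w_real = ewald.real_space(
                rij[qmask], r[qmask], qprod[qmask], ew.alpha)
            report.coul_real = e_real
            np.add.at(forces, i[qmask], f_real)
            np.add.at(forces, j[qmask], -f_real)
            virial += w_real

            cs = self.charged_sites
            e_rec, f_rec, w_rec = recip.compute(positions[cs],
                                                self.charges[cs])
            report.coul_recip = e_rec
            forces[cs] += f_rec
            virial += w_rec

            ei, ej = self.excl_pairs[:, 0], self.excl_pairs[:, 1]
            erij = positions[ei] - positions[ej]
            er = np.sqrt((erij**2).sum(axis=1))
            eq = self.charges[ei] * self.charges[ej]
            e_x, f_x, w_x = ewald.excluded_correction(erij, er, eq, ew.alpha)
            np.add.at(forces, ei, f_x)
            np.add.at(forces, ej, -f_x)
            virial += w_x
            report.coul_self_excl = e_x + ewald.self_energy(
                self.charges, ew.alpha)

        # intramolecular terms (flexible models)
        f_inter = forces.copy()   # intermolecular forces, for the virial
        if not topo.model.is_rigid:
            report.intramolecular = _intramolecular(
                positions, forces, topo)

        # dispersion tail (homogeneous systems only)
        apply_tail = cfg.tail_correction
        if apply_tail is None:
            apply_tail = topo.model.apply_dispersion_tail
        if apply_tail:
            rho = topo.n_molecules / state.volume
            u_tail, p_tail = lj_tail_correction(rho, topo.model, cfg.cutoff)
            report.tail = u_tail * topo.n_molecules
            virial += np.eye(3) * (p_tail / c.KJMOL_PER_A3_TO_BAR
                                   * state.volume)

        # molecular virial: refer pair forces to molecular centers
        com = molecule_com(positions, topo)
        s = positions - np.repeat(com, SITES_PER_MOL, axis=0)
        virial -= s.T @ f_inter

        redistribute_msite_forces(forces, topo)

        # pressure tensor (molecular convention)
        mvel = state.velocities.reshape(topo.n_molecules, SITES_PER_MOL, 3)
        msum = np.array([c.MASS_O, c.MASS_H, c.MASS_H, 0.0])
        pmom = (mvel * msum[None, :, None]).sum(axis=1)   # molecule momenta
        kin_tensor = (pmom.T @ (pmom / c.MASS_WATER)) * c.KE_TO_KJMOL
        report.pressure_tensor = (kin_tensor + virial) / state.volume \
            * c.KJMOL_PER_A3_TO_BAR

        report.kinetic = kinetic_energy(state.velocities, topo.masses)
        report.temperature = temperature(state.velocities, topo)
        return forces, report


def _intramolecular(positions, forces, topo: Topology) -> float:
    """Stretch + bend energy and forces for flexible molecules (in place)."""
    model = topo.model
    pos = positions.reshape(topo.n_molecules, SITES_PER_MOL, 3)
    f = forces.reshape(topo.n_molecules, SITES_PER_MOL, 3)
    energy = 0.0
    # OH stretches
    for h in (1, 2):
        d = pos[:, h] - pos[:, 0]
        rn = np.linalg.norm(d, axis=1)
        e, de = model.stretch.energy_forces(rn)
        energy += float(e.sum())
        fvec = -(de / rn)[:, None] * d
        f[:, h] += fvec
        f[:, 0] -= fvec
    # HOH bend
    d1 = pos[:, 1] - pos[:, 0]
    d2 = pos[:, 2] - pos[:, 0]
    r1 = np.linalg.norm(d1, axis=1)
    r2n = np.linalg.norm(d2, axis=1)
    cosq = np.clip((d1 * d2).sum(axis=1) / (r1 * r2n), -1.0, 1.0)
    theta = np.arccos(cosq)
    e, de = model.bend.energy_forces(theta)
    energy += float(e.sum())
    sinq = np.sqrt(np.maximum(1.0 - cosq**2, 1e-12))
    # dcos/dr gives forces; chain rule through theta = arccos
    coef = de / sinq
    f1 = coef[:, None] * ((d2 / r2n[:, None]) - cosq[:, None] * d1 / r1[:, None]) \
        / r1[:, None]
    f2 = coef[:, None] * ((d1 / r1[:, None]) - cosq[:, None] * d2 / r2n[:, None]) \
        / r2n[:, None]
    f[:, 1] += f1
    f[:, 2] += f2
    f[:, 0] -= f1 + f2
    return energy


def compute_forces(state: SystemState, topology: Topology,
                   config: RunConfig):
    """One-shot force/energy evaluation (builds a fresh ForceField)."""
    return ForceField(topology, config).compute(state)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

# constraint coupling for the water triangle (O,H1), (O,H2), (H1,H2):
# S[k,l] couples the Lagrange multiplier of constraint l into the
# residual of constraint k through the shared sites and their masses
def _coupling_matrix():
    m = np.array([c.MASS_O, c.MASS_H, c.MASS_H])
    pairs = Topology.CONSTRAINT_PAIRS
    S = np.zeros((3, 3))
    for k, (ak, bk) in enumerate(pairs):
        for l, (al, bl) in enumerate(pairs):
            S[k, l] = ((int(ak == al) - int(ak == bl)) / m[ak]
                       - (int(bk == al) - int(bk == bl)) / m[bk])
    return S


_S_COUPLE = _coupling_matrix()
_M3 = np.array([c.MASS_O, c.MASS_H, c.MASS_H])


def apply_constraints(positions_before: np.ndarray, positions_after: np.ndarray,
                      velocities: np.ndarray, topology: Topology,
                      tol: float = 1e-8, dt: Optional[float] = None,
                      max_iter: int = 50):
    """Constrain the rigid-molecule triangles and fix velocities accordingly.

    ``positions_before`` must satisfy the constraints; the corrected
    ``positions_after`` satisfies every constrained distance within
    relative ``tol``.  A Newton iteration on the three Lagrange
    multipliers (batched 3x3 solves over molecules) replaces the classic
    one-constraint-at-a-time sweep; corrections act along the reference
    bond directions, so each molecule's center of mass is preserved.
    When ``dt`` is given the position corrections are fed back into the
    velocities; velocity components along the constraints are then
    removed exactly.  Returns the corrected (positions, velocities).
    """
    targets = topology.constraint_targets
    if targets is None:
        return positions_after, velocities
    nm = topology.n_molecules
    ref = positions_before.reshape(nm, SITES_PER_MOL, 3)
    cur = positions_after.reshape(nm, SITES_PER_MOL, 3).copy()
    pairs = Topology.CONSTRAINT_PAIRS
    d2 = targets**2
    idx = np.where(~topology.frozen)[0]
    refm = ref[idx]
    curm = cur[idx].copy()

    a_idx, b_idx = pairs[:, 0], pairs[:, 1]
    d_ref = refm[:, a_idx] - refm[:, b_idx]           # (n, 3 constraints, 3)
    viol = np.zeros((len(idx), 3))
    for _ in range(max_iter):
        d_cur = curm[:, a_idx] - curm[:, b_idx]
        sigma = (d_cur**2).sum(axis=2) - d2[None, :]
        viol = np.abs(sigma) / d2[None, :]
        if not len(viol) or float(viol.max()) < 2.0 * tol:
            break
        # J[k,l] = 2 S[k,l] (d_cur_k . d_ref_l)
        J = 2.0 * _S_COUPLE[None, :, :] * np.einsum(
            "nkd,nld->nkl", d_cur, d_ref)
        lam = np.linalg.solve(J, -sigma[:, :, None])[:, :, 0]
        corr = lam[:, :, None] * d_ref                # (n, 3c, 3)
        for k, (a, b) in enumerate(pairs):
            curm[:, a] += corr[:, k] / _M3[a]
            curm[:, b] -= corr[:, k] / _M3[b]
    else:
        worst = int(idx[int(np.argmax(viol.max(axis=1)))])
        raise ConstraintFailureError(
            f"constraint solver failed to reach {tol} in {max_iter} "
            f"iterations (worst molecule {worst})")
    cur[idx] = curm
    out = cur.reshape(-1, 3)

    vel = velocities
    if dt is not None:
        vel = velocities + (out - positions_after) / dt
    vel = project_velocities(out, vel, topology)
    return out, vel


def project_velocities(positions: np.ndarray, velocities: np.ndarray,
                       topology: Topology) -> np.ndarray:
    """Remove velocity components along the constraints (exact solve).

    The velocity-level constraints are linear in the multipliers, so a
    single batched 3x3 solve zeroes (v_a - v_b).d for every constrained
    pair; each molecule's linear momentum is unchanged.
    """
    targets = topology.constraint_targets
    if targets is None:
        return velocities
    nm = topology.n_molecules
    pos = positions.reshape(nm, SITES_PER_MOL, 3)
    vel = velocities.reshape(nm, SITES_PER_MOL, 3).copy()
    pairs = Topology.CONSTRAINT_PAIRS
    idx = np.where(~topology.frozen)[0]
    p = pos[idx]
    v = vel[idx].copy()
    a_idx, b_idx = pairs[:, 0], pairs[:, 1]
    d = p[:, a_idx] - p[:, b_idx]                     # (n, 3c, 3)
    b_rhs = ((v[:, a_idx] - v[:, b_idx]) * d).sum(axis=2)
    C = _S_COUPLE[None, :, :] * np.einsum("nkd,nld->nkl", d, d)
    lam = np.linalg.solve(C, -b_rhs[:, :, None])[:, :, 0]
    corr = lam[:, :, None] * d
    for k, (a, b) in enumerate(pairs):
        v[:, a] += corr[:, k] / _M3[a]
        v[:, b] -= corr[:, k] / _M3[b]
    vel[idx] = v
    return vel.reshape(-1, 3)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def velocity_verlet_step(state: SystemState, forces: np.ndarray,
                         topology: Topology, config: RunConfig,
                         ff: Optional[ForceField] = None):
    """Advance one timestep; returns (new_state, new_forces, report).

    ``forces`` must correspond to ``state``.  Rigid molecules receive
    SHAKE position corrections and RATTLE velocity projection; M sites
    are rebuilt after the drift.
    """
    if ff is None:
        ff = ForceField(topology, config)
    dt = config.timestep
    m = topology.masses
    mobile = topology.massive & ~topology.frozen_sites

    pos0 = state.positions
    v = state.velocities.copy()
    v[mobile] += 0.5 * dt * forces[mobile] / m[mobile, None] * c.FORCE_TO_ACC
    pos1 = pos0.copy()
    pos1[mobile] += dt * v[mobile]
    if topology.model.is_rigid:
        pos1, v = apply_constraints(pos0, pos1, v, topology,
                                    tol=config.constraint_tol, dt=dt)
    rebuild_msites(pos1, topology)
    new_state = SystemState(pos1, v, state.box.copy(), state.time + dt)
    new_forces, report = ff.compute(new_state)
    v = new_state.velocities
    v[mobile] += 0.5 * dt * new_forces[mobile] / m[mobile, None] * c.FORCE_TO_ACC
    if topology.model.is_rigid:
        v = project_velocities(pos1, v, topology)
        new_state.velocities = v
    report.kinetic = kinetic_energy(v, m)
    report.temperature = temperature(v, topology)
    return new_state, new_forces, report


# ---------------------------------------------------------------------------
# thermostats and barostat
# ---------------------------------------------------------------------------

class NoseHooverChain:
    """Two-link Nosé–Hoover chain acting on all mobile degrees of freedom."""

    def __init__(self, ndof: int, T_target: float, tau: float):
        self.ndof = ndof
        self.kt = c.KB * T_target
        self.q1 = ndof * self.kt * tau**2
        self.q2 = self.kt * tau**2
        self.vxi1 = 0.0
        self.vxi2 = 0.0

    def scale_factor(self, kinetic: float, dt: float) -> float:
        """One full-dt chain update; returns the velocity scale factor."""
        dt2, dt4, dt8 = dt / 2.0, dt / 4.0, dt / 8.0
        k = kinetic
        g2 = (self.q1 * self.vxi1**2 - self.kt) / self.q2
        self.vxi2 += g2 * dt4
        self.vxi1 *= math.exp(-self.vxi2 * dt8)
        g1 = (2.0 * k - self.ndof * self.kt) / self.q1
        self.vxi1 += g1 * dt4
        self.vxi1 *= math.exp(-self.vxi2 * dt8)
        s = math.exp(-self.vxi1 * dt2)
        k *= s * s
        self.vxi1 *= math.exp(-self.vxi2 * dt8)
        g1 = (2.0 * k - self.ndof * self.kt) / self.q1
        self.vxi1 += g1 * dt4
        self.vxi1 *= math.exp(-self.vxi2 * dt8)
        g2 = (self.q1 * self.vxi1**2 - self.kt) / self.q2
        self.vxi2 += g2 * dt4
        return s


def thermostat_step(state: SystemState, topology: Topology, kind: str,
                    tau: float, T_target: float, dt: float,
                    rng: Optional[np.random.Generator] = None,
                    nhc: Optional[NoseHooverChain] = None):
    """Scale velocities toward canonical sampling at ``T_target``.

    ``stochastic_rescale`` is the canonical-sampling velocity rescaling
    of Bussi and co-workers (requires ``rng``); ``nose_hoover`` uses a
    two-link chain whose state persists in ``nhc``.  Returns the
    (possibly newly created) chain for reuse.
    """
    ndof = topology.n_dof()
    k = kinetic_energy(state.velocities, topology.masses)
    if ndof == 0 or k <= 0.0:
        return nhc
    if kind == "stochastic_rescale":
        if rng is None:
            raise ConfigError("stochastic_rescale thermostat requires an RNG")
        cfac = math.exp(-dt / tau)
        kbar_ratio = c.KB * T_target / (2.0 * k)
        r1 = rng.normal()
        s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
        a2 = (cfac + (1.0 - cfac) * kbar_ratio * (r1 * r1 + s)
              + 2.0 * r1 * math.sqrt(cfac * (1.0 - cfac) * kbar_ratio))
        scale = math.sqrt(max(a2, 0.0))
    elif kind == "nose_hoover":
        if nhc is None or nhc.ndof != ndof:
            nhc = NoseHooverChain(ndof, T_target, tau)
        scale = nhc.scale_factor(k, dt)
    else:
        raise ConfigError(f"unknown thermostat {kind!r}")
    mask = topology.massive & ~topology.frozen_sites
    state.velocities[mask] *= scale
    return nhc


def barostat_step(state: SystemState, topology: Topology,
                  report: EnergyReport, tau: float, P_target: float,
                  dt: float, mode: str = "isotropic",
                  compressibility: float = 4.5e-5) -> None:
    """Weak-coupling cell rescaling toward ``P_target`` (in place).

    Molecular centers of mass are scaled; intramolecular geometry is
    untouched, so constraints stay satisfied.  ``anisotropic_orthorhombic``
    scales each axis with its own diagonal pressure component.
    """
    p_diag = np.diag(report.pressure_tensor)
    if mode == "isotropic":
        p_use = np.full(3, p_diag.mean())
    elif mode == "anisotropic_orthorhombic":
        p_use = p_diag
    else:
        raise ConfigError(f"unknown barostat mode {mode!r}")
    mu = 1.0 - (dt * compressibility / (3.0 * tau)) * (P_target - p_use)
    mu = np.clip(mu, 0.98, 1.02)
    com = molecule_com(state.positions, topology)
    shift = np.repeat(com * (mu - 1.0), SITES_PER_MOL, axis=0)
    state.positions = state.positions + shift
    state.box = state.box * mu


def mc_volume_step(state: SystemState, topology: Topology, ff: "ForceField",
                   config: RunConfig, rng: np.random.Generator,
                   potential_current: float):
    """Metropolis volume move for exact isothermal-isobaric sampling.

    A symmetric step in ln V scales molecular centers of mass (internal
    geometry untouched); acceptance uses
    ΔU + P ΔV − (N + 1) k_B T Δln V.  Returns
    (state, forces, report, accepted); on rejection forces/report are
    None and the input state is returned unchanged.
    """
    V = state.volume
    lnv = math.log(V)
    lnv_new = lnv + rng.uniform(-config.mc_dlnv, config.mc_dlnv)
    scale = math.exp((lnv_new - lnv) / 3.0)
    com = molecule_com(state.positions, topology)
    shift = np.repeat(com * (scale - 1.0), SITES_PER_MOL, axis=0)
    trial = SystemState(state.positions + shift, state.velocities,
                        state.box * scale, state.time)
    forces, rep = ff.compute(trial)
    kt = c.KB * config.T_target
    p_int = config.P_target / c.KJMOL_PER_A3_TO_BAR
    v_new = math.exp(lnv_new)
    darg = (rep.potential - potential_current + p_int * (v_new - V)
            - (topology.n_molecules + 1) * kt * (lnv_new - lnv))
    if darg <= 0.0 or rng.random() < math.exp(-darg / kt):
        return trial, forces, rep, True
    return state, None, None, False


# ---------------------------------------------------------------------------
# run loop
# ---------------------------------------------------------------------------

def run(state: SystemState, topology: Topology, config: RunConfig,
        n_steps: int, meta: Optional[dict] = None) -> Trajectory:
    """Integrate ``n_steps`` and collect frames plus an energy log.

    NVE runs audit total-energy drift (reported in ``meta['drift_kj_mol']``
    and per-molecule in ``meta['drift_per_molecule']``); a change of the
    total energy beyond ``config.blowup_bound`` per molecule raises
    :class:`BlowUpError`.
    """
    state = state.copy()
    rebuild_msites(state.positions, topology)
    ff = ForceField(topology, config)
    rng = np.random.default_rng(config.seed)
    nhc = None
    forces, report = ff.compute(state)

    frames, boxes, times, erows = [], [], [], []

    def record(rep):
        frames.append(state.positions.copy())
        boxes.append(state.box.copy())
        times.append(state.time)
        row = {"time": state.time}
        row.update(rep.as_dict())
        erows.append(row)

    record(report)
    e0 = report.total
    n_mol = topology.n_molecules
    mobile_mask = topology.massive & ~topology.frozen_sites

    for step in range(1, n_steps + 1):
        state, forces, report = velocity_verlet_step(
            state, forces, topology, config, ff)
        if config.thermostat_active:
            nhc = thermostat_step(state, topology, config.thermostat,
                                  config.tau_t, config.T_target,
                                  config.timestep, rng=rng, nhc=nhc)
        if config.barostat_active:
            if config.barostat == "monte_carlo":
                if step % config.mc_volume_every == 0:
                    state, f_new, rep_new, accepted = mc_volume_step(
                        state, topology, ff, config, rng, report.potential)
                    if accepted:
                        forces, report = f_new, rep_new
            else:
                barostat_step(state, topology, report, config.tau_p,
                              config.P_target, config.timestep,
                              mode=config.barostat_mode,
                              compressibility=config.compressibility)
        if (config.remove_com_every and not topology.frozen.any()
                and step % config.remove_com_every == 0):
            m = topology.masses
            p = (m[:, None] * state.velocities).sum(axis=0)
            state.velocities[mobile_mask] -= (p / m[topology.massive].sum())

        if not np.isfinite(report.total) or \
                abs(report.total - e0) > config.blowup_bound * n_mol:
            raise BlowUpError(
                f"total energy moved from {e0:.3f} to {report.total:.3f} "
                f"kJ/mol at t = {state.time:.1f} fs")
        if step % config.output_every == 0 or step == n_steps:
            record(report)

    energies = pd.DataFrame(erows)
    out_meta = {"seed": config.seed, "ensemble": config.ensemble,
                "timestep_fs": config.timestep, "n_steps": n_steps}
    if config.ensemble == "NVE":
        drift = float(energies["total"].iloc[-1] - energies["total"].iloc[0])
        out_meta["drift_kj_mol"] = drift
        out_meta["drift_per_molecule"] = drift / n_mol
        mean_tot = float(energies["total"].mean())
        out_meta["drift_relative"] = drift / abs(mean_tot) if mean_tot else 0.0
    if meta:
        out_meta.update(meta)
    return Trajectory(np.array(frames), np.array(boxes), np.array(times),
                      energies=energies, topology=topology, meta=out_meta,
                      final_state=state)
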