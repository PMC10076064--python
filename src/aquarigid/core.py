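"""Shared containers: topology, system state, energy report, trajectory.

Site layout convention: molecule ``m`` owns the four consecutive sites
``4m .. 4m+3`` ordered O, H1, H2, M.  The M site is massless; its
position is rebuilt from the O/H positions every step and the force it
collects is redistributed to O and the hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import constants as c
from .errors import TopologyError
from .models import WaterModel

SITES_PER_MOL = 4
SITE_NAMES = ("O", "H1", "H2", "M")


@dataclass
class Topology:
    """Composition of a box of four-site water molecules.

    ``frozen`` marks molecules excluded from integration (their
    velocities are zero and they contribute no degrees of freedom); they
    still exert forces.  Rigid molecules carry the three distance
    constraints O-H1, O-H2, H1-H2.
    """

    model: WaterModel
    n_molecules: int
    frozen: Optional[np.ndarray] = None  # bool per molecule

    def __post_init__(self):
        if self.n_molecules < 1:
            raise TopologyError("need at least one molecule")
        if self.frozen is None:
            self.frozen = np.zeros(self.n_molecules, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
            if self.frozen.shape != (self.n_molecules,):
                raise TopologyError("frozen mask has wrong length")
        # cached site arrays (the topology is immutable once built)
        self._masses = np.tile(
            np.array([c.MASS_O, c.MASS_H, c.MASS_H, 0.0]), self.n_molecules)
        self._charges = np.tile(
            np.array([0.0, self.model.q_H, self.model.q_H, self.model.q_M]),
            self.n_molecules)
        self._massive = np.tile(
            np.array([True, True, True, False]), self.n_molecules)
        self._mol_of_site = np.repeat(
            np.arange(self.n_molecules), SITES_PER_MOL)
        self._frozen_sites = np.repeat(self.frozen, SITES_PER_MOL)

    # -- site-level arrays -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return SITES_PER_MOL * self.n_molecules

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def charges(self) -> np.ndarray:
        return self._charges

    @property
    def massive(self) -> np.ndarray:
        """Boolean mask of sites that carry mass (O, H1, H2)."""
        return self._massive

    @property
    def molecule_of_site(self) -> np.ndarray:
        return self._mol_of_site

    @property
    def frozen_sites(self) -> np.ndarray:
        return self._frozen_sites

    def lj_params(self):
        """Per-site (epsilon, sigma) arrays; zero-epsilon sites inert."""
        eps = np.zeros(SITES_PER_MOL)
        sig = np.ones(SITES_PER_MOL)
        for idx, name in enumerate(("O", "H1", "H2", "M")):
            key = {"H1": "H", "H2": "H"}.get(name, name)
            if key in self.model.lj_sites:
                eps[idx] = self.model.lj_sites[key].epsilon
                sig[idx] = self.model.lj_sites[key].sigma
        return np.tile(eps, self.n_molecules), np.tile(sig, self.n_molecules)

    # -- constraints and DOF ----------------------------------------------
    @property
    def constraint_targets(self) -> Optional[np.ndarray]:
        """Distance targets (d_OH, d_OH, d_HH) for rigid molecules, else None."""
        if not self.model.is_rigid:
            return None
        g = self.model.rigid_geometry
        return np.array([g.r_OH, g.r_OH, g.r_HH])

    # constraint pairs as local site indices within the molecule
    CONSTRAINT_PAIRS = np.array([[0, 1], [0, 2], [1, 2]])

    def n_dof(self, remove_com: bool = True) -> int:
        """Kinetic degrees of freedom of the mobile molecules.

        Rigid molecules have 6 (3 translation + 3 rotation), flexible
        9.  Three are subtracted for conserved total momentum when no
        molecule is frozen.
        """
        per_mol = 6 if self.model.is_rigid else 9
        n_mobile = int((~self.frozen).sum())
        dof = per_mol * n_mobile
        if remove_com and not self.frozen.any() and n_mobile > 0:
            dof -= 3
        return dof


@dataclass
class SystemState:
    """Instantaneous mechanical state of an orthorhombic periodic box."""

    positions: np.ndarray          # (n_sites, 3) Å
    velocities: np.ndarray         # (n_sites, 3) Å/fs; zero on M sites
    box: np.ndarray                # (3,) Å
    time: float = 0.0              # fs

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise TopologyError("positions/velocities shape mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite positions")

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box.copy(), self.time)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class EnergyReport:
    """Energy decomposition of one configuration (kJ/mol, K, bar)."""

    kinetic: float = 0.0
    lj: float = 0.0
    coul_real: float = 0.0
    coul_recip: float = 0.0
    coul_self_excl: float = 0.0
    intramolecular: float = 0.0
    tail: float = 0.0
    temperature: float = 0.0
    pressure_tensor: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    @property
    def potential(self) -> float:
        return (self.lj + self.coul_real + self.coul_recip
                + self.coul_self_excl + self.intramolecular + self.tail)

    @property
    def total(self) -> float:
        return self.kinetic + self.potential

    @property
    def pressure(self) -> float:
        return float(np.trace(self.pressure_tensor) / 3.0)

    def as_dict(self) -> dict:
        d = {
            "kinetic": self.kinetic, "lj": self.lj,
            "coul_real": self.coul_real, "coul_recip": self.coul_recip,
            "coul_self_excl": self.coul_self_excl,
            "intramolecular": self.intramolecular, "tail": self.tail,
            "potential": self.potential, "total": self.total,
            "temperature": self.temperature, "pressure": self.pressure,
        }
        for i, a in enumerate("xyz"):
            d[f"P{a}{a}"] = float(self.pressure_tensor[i, i])
        return d


@dataclass
class Trajectory:
    """Time-ordered frames with box data and an energy log.

    ``energies`` is a DataFrame with one row per stored frame (columns
    from :meth:`EnergyReport.as_dict` plus ``time``).  ``meta`` carries
    provenance (seed, config snapshot, fixture ground truth).
    """

    positions: np.ndarray            # (n_frames, n_sites, 3)
    boxes: np.ndarray                # (n_frames, 3)
    times: np.ndarray                # (n_frames,)
    energies: Optional[pd.DataFrame] = None
    topology: Optional[Topology] = None
    meta: dict = field(default_factory=dict)
    final_state: Optional[SystemState] = None  # with velocities, for chaining

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> SystemState:
        return SystemState(self.positions[i].copy(),
                           np.zeros_like(self.positions[i]),
                           self.boxes[i].copy(), float(self.times[i]))

    def temperature_series(self):
        """(times, T) arrays from the energy log."""
        if self.energies is None or "temperature" not in self.energies:
            raise ValueError("trajectory has no temperature log")
        return (self.energies["time"].to_numpy(),
                self.energies["temperature"].to_numpy())


def molecule_com(positions: np.ndarray, topology: Topology) -> np.ndarray:
    """Centers of mass (n_molecules, 3); assumes whole molecules."""
    pos = positions.reshape(topology.n_molecules, SITES_PER_MOL, 3)
    m = np.array([c.MASS_O, c.MASS_H, c.MASS_H, 0.0])
    return (pos * m[None, :, None]).sum(axis=1) / c.MASS_WATER


def make_whole(positions: np.ndarray, box: np.ndarray,
               topology: Topology) -> np.ndarray:
    """Unwrap each molecule around its oxygen (minimum image)."""
    pos = positions.reshape(topology.n_molecules, SITES_PER_MOL, 3).copy()
    ref = pos[:, :1, :]
    d = pos - ref
    d -= np.round(d / box) * box
    return (ref + d).reshape(-1, 3)
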