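"""Four-site water model definitions and rigid-variant construction.

A four-site water model places point charges on the two hydrogens and on
a massless M site that sits on the HOH bisector,

    r_M = r_O + a * ((r_H1 - r_O) + (r_H2 - r_O)),

with dimensionless parameter ``a``; the oxygen carries the Lennard-Jones
center.  A flexible (FL) model adds intramolecular stretch and bend
terms.  Two rigid variants are supported:

* **MG** (model geometry): the monomer is frozen at the flexible force
  field's own equilibrium bond length and angle.
* **EG** (ensemble geometry): the monomer is frozen at the ensemble-
  averaged geometry measured in liquid water at a reference state
  (298 K, 1 bar by default), which is a longer bond and a smaller angle
  than the model geometry and therefore a larger dipole.

Because bending the HOH angle changes the molecular dipole, a flexible
model carries an effective in-plane polarizability; the EG dipole
exceeds the MG dipole by this induction.  The polarization self-energy
(mu_m - mu_g)^2 / (2 alpha) quantifies the cost of maintaining the
enhanced condensed-phase dipole and enters the heat of vaporization.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from . import constants as c
from .errors import (
    IncompleteModelError,
    InvalidGeometryError,
    InvalidParameterError,
    ModeError,
)

__all__ = [
    "MonomerGeometry",
    "LJSite",
    "StretchTerm",
    "BendTerm",
    "SelfEnergyParams",
    "WaterModel",
    "msite_position",
    "om_distance_to_a",
    "a_to_om_distance",
    "monomer_positions",
    "monomer_dipole",
    "in_plane_polarizability",
    "self_energy_correction",
    "rigidify_mg",
    "rigidify_eg",
    "get_model",
    "register_model",
    "available_models",
    "load_model",
    "dump_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomerGeometry:
    """Rigid monomer geometry: OH bond length (Å) and HOH angle (deg)."""

    r_OH: float
    theta_HOH: float

    def __post_init__(self):
        if not (np.isfinite(self.r_OH) and np.isfinite(self.theta_HOH)):
            raise InvalidGeometryError("non-finite monomer geometry")
        if self.r_OH <= 0:
            raise InvalidGeometryError(f"r_OH must be positive, got {self.r_OH}")
        if not 0.0 < self.theta_HOH < 180.0:
            raise InvalidGeometryError(
                f"theta_HOH must lie in (0, 180) deg, got {self.theta_HOH}"
            )

    @property
    def theta_rad(self) -> float:
        return self.theta_HOH * c.DEG

    @property
    def r_HH(self) -> float:
        """H–H distance implied by the isoceles geometry."""
        return 2.0 * self.r_OH * math.sin(0.5 * self.theta_rad)


@dataclass(frozen=True)
class LJSite:
    """Lennard-Jones parameters of one site: epsilon kJ/mol, sigma Å."""

    epsilon: float
    sigma: float

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma < 0:
            raise InvalidParameterError("LJ parameters must be non-negative")


@dataclass(frozen=True)
class StretchTerm:
    """Intramolecular OH stretch.

    kinds:
      - ``harmonic``: V = 1/2 k_r (r - r0)^2            params: k_r kJ/mol/Å²
      - ``quartic``:  V = D [a² x² - a³ x³ + 7/12 a⁴ x⁴] with x = r - r0
                      (quartic expansion of a Morse well)  params: D kJ/mol, alpha 1/Å
      - ``morse``:    V = D (1 - exp(-a x))²
    """

    kind: str
    r0: float
    k_r: float = 0.0
    D: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.kind not in ("harmonic", "quartic", "morse"):
            raise InvalidParameterError(f"unknown stretch kind {self.kind!r}")

    def energy_forces(self, r: np.ndarray):
        """Energy (kJ/mol) and dV/dr (kJ/mol/Å) at bond lengths ``r``."""
        x = r - self.r0
        if self.kind == "harmonic":
            return 0.5 * self.k_r * x * x, self.k_r * x
        if self.kind == "quartic":
            a = self.alpha
            e = self.D * (a**2 * x**2 - a**3 * x**3 + (7.0 / 12.0) * a**4 * x**4)
            de = self.D * (2 * a**2 * x - 3 * a**3 * x**2 + (7.0 / 3.0) * a**4 * x**3)
            return e, de
        # morse
        ex = np.exp(-self.alpha * x)
        e = self.D * (1.0 - ex) ** 2
        de = 2.0 * self.D * self.alpha * ex * (1.0 - ex)
        return e, de

    @property
    def harmonic_k(self) -> float:
        """Effective harmonic force constant at the minimum, kJ/mol/Å²."""
        if self.kind == "harmonic":
            return self.k_r
        return 2.0 * self.D * self.alpha**2


@dataclass(frozen=True)
class BendTerm:
    """Harmonic HOH bend: V = 1/2 k_theta (theta - theta0)^2.

    k_theta in kJ/mol/rad², theta0 in degrees.
    """

    k_theta: float
    theta0: float

    def __post_init__(self):
        if self.k_theta <= 0:
            raise InvalidParameterError("k_theta must be positive")

    def energy_forces(self, theta: np.ndarray):
        """Energy and dV/dtheta (kJ/mol/rad) at angles ``theta`` (rad)."""
        x = theta - self.theta0 * c.DEG
        return 0.5 * self.k_theta * x * x, self.k_theta * x


@dataclass(frozen=True)
class SelfEnergyParams:
    """Inputs of the polarization self-energy: gas dipole (D), polarizability (Å³)."""

    mu_gas: float = c.MU_GAS_EXPT
    alpha_pol: float = c.ALPHA_EXPT

    def __post_init__(self):
        if self.alpha_pol <= 0:
            raise InvalidParameterError("polarizability must be positive")


@dataclass(frozen=True)
class WaterModel:
    """Complete four-site water force-field definition.

    The monomer is charge neutral: the M site carries -2 q_H.  ``mode``
    is one of ``FL`` (flexible), ``MG`` or ``EG`` (rigid); rigid modes
    require ``rigid_geometry`` and drop the intramolecular terms.
    """

    name: str
    q_H: float
    msite_a: float
    lj_sites: dict = field(default_factory=dict)  # site name -> LJSite
    stretch: Optional[StretchTerm] = None
    bend: Optional[BendTerm] = None
    mode: str = "FL"
    rigid_geometry: Optional[MonomerGeometry] = None
    apply_dispersion_tail: bool = True

    def __post_init__(self):
        if self.mode not in ("FL", "MG", "EG"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.msite_a < 0.5:
            raise InvalidParameterError(
                f"msite_a must lie in [0, 0.5), got {self.msite_a}"
            )
        if self.mode != "FL" and self.rigid_geometry is None:
            raise IncompleteModelError(f"{self.mode} model requires rigid_geometry")
        if self.mode == "FL" and (self.stretch is None or self.bend is None):
            raise IncompleteModelError("FL model requires stretch and bend terms")

    @property
    def q_M(self) -> float:
        return -2.0 * self.q_H

    @property
    def is_rigid(self) -> bool:
        return self.mode != "FL"

    @property
    def model_geometry(self) -> MonomerGeometry:
        """Equilibrium (gas-phase) geometry of the force field."""
        if self.is_rigid:
            return self.rigid_geometry
        return MonomerGeometry(self.stretch.r0, self.bend.theta0)

    def intermolecular_block(self):
        """Hashable snapshot of all intermolecular parameters."""
        lj = tuple(sorted((k, v.epsilon, v.sigma) for k, v in self.lj_sites.items()))
        return (self.q_H, self.msite_a, lj, self.apply_dispersion_tail)


# ---------------------------------------------------------------------------
# monomer-level operations
# ---------------------------------------------------------------------------

def msite_position(r_O, r_H1, r_H2, a: float) -> np.ndarray:
    """Position of the massless M site on the HOH bisector.

    r_M = r_O + a * ((r_H1 - r_O) + (r_H2 - r_O))
    """
    r_O = np.asarray(r_O, dtype=float)
    r_H1 = np.asarray(r_H1, dtype=float)
    r_H2 = np.asarray(r_H2, dtype=float)
    if not (np.all(np.isfinite(r_O)) and np.all(np.isfinite(r_H1))
            and np.all(np.isfinite(r_H2))):
        raise InvalidGeometryError("non-finite site position")
    if a < 0:
        raise InvalidParameterError(f"M-site parameter a must be >= 0, got {a}")
    return r_O + a * ((r_H1 - r_O) + (r_H2 - r_O))


def a_to_om_distance(a: float, geom: MonomerGeometry) -> float:
    """O–M distance (Å) implied by the M-site parameter for a symmetric monomer."""
    return a * 2.0 * geom.r_OH * math.cos(0.5 * geom.theta_rad)


def om_distance_to_a(d_OM: float, geom: MonomerGeometry) -> float:
    """Convert a tabulated O–M distance to the M-site parameter ``a``.

    Inverse of :func:`a_to_om_distance`; raises when the requested
    distance would place M on or beyond the H–H line (a >= 0.5).
    """
    span = 2.0 * geom.r_OH * math.cos(0.5 * geom.theta_rad)
    if d_OM < 0 or d_OM >= span:
        raise InvalidParameterError(
            f"d_OM = {d_OM} Å places M outside [0, {span:.4f}) Å for this geometry"
        )
    return d_OM / span


def monomer_positions(geom: MonomerGeometry, a: float) -> np.ndarray:
    """Canonical monomer coordinates (O, H1, H2, M), bisector along +z.

    O at the origin, hydrogens in the xz plane.
    """
    th2 = 0.5 * geom.theta_rad
    s, co = math.sin(th2), math.cos(th2)
    r_O = np.zeros(3)
    r_H1 = np.array([geom.r_OH * s, 0.0, geom.r_OH * co])
    r_H2 = np.array([-geom.r_OH * s, 0.0, geom.r_OH * co])
    r_M = msite_position(r_O, r_H1, r_H2, a)
    return np.array([r_O, r_H1, r_H2, r_M])


def monomer_dipole(model: WaterModel, geom: Optional[MonomerGeometry] = None) -> float:
    """Magnitude of the monomer dipole moment in Debye.

    Sums q_i r_i over the two H charges and the M charge at the given
    geometry (default: the model's own geometry).  Independent of rigid
    translation and rotation of the monomer.
    """
    if model.q_H is None:
        raise IncompleteModelError("model has no charges")
    if geom is None:
        geom = model.model_geometry
    pos = monomer_positions(geom, model.msite_a)
    q = np.array([0.0, model.q_H, model.q_H, model.q_M])
    mu = (q[:, None] * pos).sum(axis=0)
    return float(np.linalg.norm(mu)) * c.EA_TO_DEBYE


def in_plane_polarizability(model: WaterModel,
                            geom: Optional[MonomerGeometry] = None) -> float:
    """Effective in-plane polarizability (Å³) from HOH-angle bending.

    Bending the angle changes the monomer dipole; to first order the
    dipole response to a field conjugate to the bend coordinate is

        alpha = (dmu/dtheta)^2 / k_theta
              = q_H² r_OH² sin²(theta/2) (1 - 2a)² / k_theta,

    since mu(theta) = 2 q_H (1 - 2a) r_OH cos(theta/2).  The result is
    validated against a finite-field minimization of the bend energy in
    the test suite.
    """
    if model.bend is None:
        raise IncompleteModelError("in-plane polarizability requires a bend term")
    if model.bend.k_theta <= 0:
        raise InvalidParameterError("k_theta must be positive")
    if geom is None:
        geom = model.model_geometry
    dmu_dtheta = (model.q_H * geom.r_OH
                  * math.sin(0.5 * geom.theta_rad) * (1.0 - 2.0 * model.msite_a))
    return dmu_dtheta**2 / model.bend.k_theta * c.COULOMB


def self_energy_correction(mu_model: float,
                           params: SelfEnergyParams = SelfEnergyParams()) -> float:
    """Polarization self-energy (mu_m - mu_g)² / (2 alpha) in kJ/mol.

    ``mu_model`` in Debye.  The correction is the energetic cost of the
    enhanced condensed-phase dipole of a non-polarizable model and is
    subtracted in the heat of vaporization.
    """
    if mu_model < 0:
        raise InvalidParameterError("model dipole must be non-negative")
    dmu_ea = (mu_model - params.mu_gas) / c.EA_TO_DEBYE
    return dmu_ea**2 / (2.0 * params.alpha_pol) * c.COULOMB


# ---------------------------------------------------------------------------
# rigidification
# ---------------------------------------------------------------------------

def rigidify_mg(model: WaterModel) -> WaterModel:
    """Freeze a flexible model at its own equilibrium geometry (MG variant).

    All intermolecular parameters are carried over unchanged; the
    stretch and bend terms are removed.
    """
    if model.mode != "FL":
        raise ModeError(f"rigidify_mg requires a flexible model, got mode {model.mode}")
    geom = MonomerGeometry(model.stretch.r0, model.bend.theta0)
    return replace(model, name=f"{model.name}-MG", mode="MG",
                   rigid_geometry=geom, stretch=None, bend=None)


def rigidify_eg(model: WaterModel, geom: MonomerGeometry) -> WaterModel:
    """Freeze a flexible model at an ensemble-averaged geometry (EG variant).

    ``geom`` is normally extracted from a liquid NPT trajectory at the
    reference state (298 K, 1 bar); see
    :func:`aquarigid.geomstats.extract_ensemble_geometry`.
    """
    if model.mode != "FL":
        raise ModeError(f"rigidify_eg requires a flexible model, got mode {model.mode}")
    return replace(model, name=f"{model.name}-EG", mode="EG",
                   rigid_geometry=geom, stretch=None, bend=None)


# ---------------------------------------------------------------------------
# built-in registry
# ---------------------------------------------------------------------------

def _qtip4pf() -> WaterModel:
    # q-TIP4P/F (Habershon, Markland & Manolopoulos, 2009): quartic
    # expansion of a Morse OH stretch, harmonic bend, TIP4P charge layout.
    return WaterModel(
        name="q-TIP4P/F",
        q_H=0.5564,
        msite_a=(1.0 - 0.73612) / 2.0,  # gamma = 0.73612
        lj_sites={"O": LJSite(epsilon=0.1852 * c.KCAL_TO_KJ, sigma=3.1589)},
        stretch=StretchTerm(kind="quartic", r0=0.9419,
                            D=116.09 * c.KCAL_TO_KJ, alpha=2.287),
        bend=BendTerm(k_theta=87.85 * c.KCAL_TO_KJ, theta0=107.4),
        mode="FL",
        apply_dispersion_tail=True,
    )


def _tip4p_ice() -> WaterModel:
    # TIP4P/Ice (Abascal et al., 2005): rigid reference model used to
    # validate the NVE three-phase coexistence method.
    geom = MonomerGeometry(0.9572, 104.52)
    return WaterModel(
        name="TIP4P/Ice",
        q_H=0.5897,
        msite_a=om_distance_to_a(0.1577, geom),
        lj_sites={"O": LJSite(epsilon=0.21084 * c.KCAL_TO_KJ, sigma=3.1668)},
        mode="MG",
        rigid_geometry=geom,
        apply_dispersion_tail=True,
    )


_BUILTIN = {
    "q-TIP4P/F": _qtip4pf,
    "TIP4P/Ice": _tip4p_ice,
}

_REGISTRY: dict = {}


def register_model(model: WaterModel) -> None:
    """Add a model to the runtime registry (e.g. one loaded from file)."""
    _REGISTRY[model.name] = model


def available_models():
    return sorted(set(_BUILTIN) | set(_REGISTRY))


def get_model(name: str) -> WaterModel:
    """Fetch a built-in or registered model by name (fresh copy)."""
    if name in _REGISTRY:
        return copy.deepcopy(_REGISTRY[name])
    if name in _BUILTIN:
        return _BUILTIN[name]()
    raise KeyError(
        f"unknown model {name!r}; available: {', '.join(available_models())}"
    )


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

_SCHEMA_KEYS = {"name", "charges", "msite", "lj", "stretch", "bend", "flags",
                "geometry", "mode"}


def load_model(path) -> WaterModel:
    """Load a water model from a YAML parameter file.

    Schema (keys in parentheses optional)::

        name: BLYPSP-4F
        mode: FL | MG | EG            # default FL
        charges: {q_H: <e>}
        msite:   {a: <dimensionless>} # or {d_OM: <Å>} with a geometry block
        lj:
          O: {epsilon: <kJ/mol>, sigma: <Å>}
          (H): {...}
          (M): {...}
        (stretch): {kind: harmonic|quartic|morse, r0: <Å>,
                    (k_r): <kJ/mol/Å²>, (D): <kJ/mol>, (alpha): <1/Å>}
        (bend):    {k_theta: <kJ/mol/rad²>, theta0: <deg>}
        (geometry): {r_OH: <Å>, theta_HOH: <deg>}   # required for rigid modes
        (flags):   {dispersion_tail: true|false}

    Models whose dispersion term was fit jointly with repulsion (the
    WAIL schema) should set ``dispersion_tail: false``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"model file {path} is not a mapping")
    unknown = set(raw) - _SCHEMA_KEYS
    if unknown:
        raise InvalidParameterError(
            f"unknown keys in model file: {sorted(unknown)}; "
            f"expected a subset of {sorted(_SCHEMA_KEYS)}"
        )
    for req in ("name", "charges", "msite", "lj"):
        if req not in raw:
            raise IncompleteModelError(f"model file missing required block {req!r}")

    mode = raw.get("mode", "FL")
    geom = None
    if "geometry" in raw:
        geom = MonomerGeometry(float(raw["geometry"]["r_OH"]),
                               float(raw["geometry"]["theta_HOH"]))

    msite = raw["msite"]
    if "a" in msite:
        a = float(msite["a"])
    elif "d_OM" in msite:
        g = geom
        if g is None and "stretch" in raw and "bend" in raw:
            g = MonomerGeometry(float(raw["stretch"]["r0"]),
                                float(raw["bend"]["theta0"]))
        if g is None:
            raise IncompleteModelError("msite d_OM requires a geometry block")
        a = om_distance_to_a(float(msite["d_OM"]), g)
    else:
        raise IncompleteModelError("msite block needs 'a' or 'd_OM'")

    lj = {site: LJSite(float(p["epsilon"]), float(p["sigma"]))
          for site, p in raw["lj"].items()}

    stretch = bend = None
    if "stretch" in raw:
        s = dict(raw["stretch"])
        stretch = StretchTerm(kind=s.pop("kind"), r0=float(s.pop("r0")),
                              **{k: float(v) for k, v in s.items()})
    if "bend" in raw:
        bend = BendTerm(k_theta=float(raw["bend"]["k_theta"]),
                        theta0=float(raw["bend"]["theta0"]))

    flags = raw.get("flags", {})
    tail = bool(flags.get("dispersion_tail", True))

    return WaterModel(name=str(raw["name"]), q_H=float(raw["charges"]["q_H"]),
                      msite_a=a, lj_sites=lj, stretch=stretch, bend=bend,
                      mode=mode, rigid_geometry=geom, apply_dispersion_tail=tail)


def dump_model(model: WaterModel, path) -> None:
    """Write a model back to the YAML schema of :func:`load_model`."""
    doc: dict = {
        "name": model.name,
        "mode": model.mode,
        "charges": {"q_H": model.q_H},
        "msite": {"a": model.msite_a},
        "lj": {s: {"epsilon": p.epsilon, "sigma": p.sigma}
               for s, p in model.lj_sites.items()},
        "flags": {"dispersion_tail": model.apply_dispersion_tail},
    }
    if model.stretch is not None:
        s = {"kind": model.stretch.kind, "r0": model.stretch.r0}
        if model.stretch.kind == "harmonic":
            s["k_r"] = model.stretch.k_r
        else:
            s["D"] = model.stretch.D
            s["alpha"] = model.stretch.alpha
        doc["stretch"] = s
    if model.bend is not None:
        doc["bend"] = {"k_theta": model.bend.k_theta, "theta0": model.bend.theta0}
    if model.rigid_geometry is not None:
        doc["geometry"] = {"r_OH": model.rigid_geometry.r_OH,
                           "theta_HOH": model.rigid_geometry.theta_HOH}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
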