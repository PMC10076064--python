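"""Property estimators: RDF, dielectric constant, heat capacity, heat of
vaporization, diffusion constant, surface tension, density curve and the
temperature of maximum density.

Conventions shared by all estimators:

* uncertainties are block averages over frames (5 blocks by default);
* estimators operate on :class:`~aquarigid.core.Trajectory` objects and
  return :class:`ObservableReport` records carrying the settings needed
  to reproduce the number;
* the dielectric constant is orientational-only (the models carry no
  electronic polarizability); the reported ε multiplies ε_o by the
  high-frequency water factor 1.78.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import constants as c
from .core import SITES_PER_MOL, Topology, Trajectory, molecule_com
from .errors import IllConditionedError, InsufficientDataError
from .models import SelfEnergyParams, WaterModel, self_energy_correction

__all__ = ["ObservableReport", "rdf", "box_dipole", "dielectric",
           "heat_capacity_fd", "equipartition_cv", "heat_of_vaporization",
           "diffusion", "surface_tension", "density_curve", "tmd_fit"]


@dataclass
class ObservableReport:
    """A named estimate with uncertainty and reproduction settings."""

    name: str
    value: float
    uncertainty: float
    units: str
    settings: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def _block_sem(values: np.ndarray, n_blocks: int = 5) -> float:
    values = np.asarray(values, dtype=float)
    nb = min(n_blocks, len(values))
    if nb < 2:
        return 0.0
    means = np.array([b.mean() for b in np.array_split(values, nb)])
    return float(means.std(ddof=1) / math.sqrt(nb))


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

_PAIR_SITES = {"O-O": (0, 0), "O-H": (0, 1), "H-H": (1, 1)}


def rdf(traj: Trajectory, pair: str = "O-O", r_max: float = 8.0,
        bin_width: float = 0.05,
        topology: Optional[Topology] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between water site species.

    Intramolecular pairs are excluded.  Normalization is the standard
    ideal-gas shell count, so g → 1 at large r in a homogeneous fluid.
    Returns (bin centers, g).
    """
    topo = topology or traj.topology
    if pair not in _PAIR_SITES:
        raise ValueError(f"pair must be one of {sorted(_PAIR_SITES)}")
    s1, s2 = _PAIR_SITES[pair]
    nm = topo.n_molecules
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_ideal = 0.0
    mol = np.arange(nm)
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        pos = traj.positions[f].reshape(nm, SITES_PER_MOL, 3)
        groups1 = pos[:, [s1]] if s1 == 0 else pos[:, [1, 2]]
        groups2 = pos[:, [s2]] if s2 == 0 else pos[:, [1, 2]]
        a = groups1.reshape(-1, 3)
        b = groups2.reshape(-1, 3)
        mol_a = np.repeat(mol, groups1.shape[1])
        mol_b = np.repeat(mol, groups2.shape[1])
        d = a[:, None, :] - b[None, :, :]
        d -= np.round(d / box) * box
        r = np.sqrt((d**2).sum(axis=-1))
        mask = mol_a[:, None] != mol_b[None, :]
        if s1 == s2:
            mask &= np.triu(np.ones_like(mask, dtype=bool), k=1)
        rr = r[mask]
        hist += np.histogram(rr[rr < r_max], bins=edges)[0]
        # ideal count: n_pairs / V per unit volume
        n_pairs = int(mask.sum())
        n_ideal += n_pairs / float(np.prod(box))
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = 4.0 / 3.0 * math.pi * (edges[1:]**3 - edges[:-1]**3)
    g = hist / (n_ideal * shell)
    return centers, g


# ---------------------------------------------------------------------------
# dielectric constant
# ---------------------------------------------------------------------------

def box_dipole(positions: np.ndarray, box: np.ndarray,
               topology: Topology) -> np.ndarray:
    """Total dipole vector of one frame in Debye (charges on H and M)."""
    nm = topology.n_molecules
    pos = positions.reshape(nm, SITES_PER_MOL, 3)
    # molecule-local sum: translation-invariant because each monomer is
    # neutral; molecules are made whole around O first
    d = pos - pos[:, :1, :]
    d -= np.round(d / box) * box
    q = np.array([0.0, topology.model.q_H, topology.model.q_H,
                  topology.model.q_M])
    mu = (q[None, :, None] * d).sum(axis=(0, 1))
    return mu * c.EA_TO_DEBYE


def dielectric(traj: Trajectory, T: float,
               topology: Optional[Topology] = None,
               high_freq_factor: float = c.EPS_HIGH_FREQ_FACTOR,
               n_blocks: int = 5) -> Tuple[ObservableReport, ObservableReport]:
    """Orientational and scaled dielectric constants from dipole fluctuations.

    ε_o = 1 + 4π (⟨M²⟩ − ⟨M⟩²) / (3 V k_B T); ε = high_freq_factor · ε_o.
    Returns (ε_o report, ε report); fewer than 10 independent blocks of
    frames attaches an unreliable-estimate warning.
    """
    topo = topology or traj.topology
    M = np.array([box_dipole(traj.positions[f], traj.boxes[f], topo)
                  for f in range(traj.n_frames)]) / c.EA_TO_DEBYE  # e·Å
    V = float(np.prod(traj.boxes.mean(axis=0)))
    m2 = (M**2).sum(axis=1)
    fluct = float(m2.mean() - (M.mean(axis=0)**2).sum())
    pref = 4.0 * math.pi * c.COULOMB / (3.0 * V * c.KB * T)
    eps_o = 1.0 + pref * fluct

    # block error
    nb = min(n_blocks, traj.n_frames)
    eps_blocks = []
    for bm, bm2 in zip(np.array_split(M, nb), np.array_split(m2, nb)):
        fl = float(bm2.mean() - (bm.mean(axis=0)**2).sum())
        eps_blocks.append(1.0 + pref * fl)
    err = (float(np.std(eps_blocks, ddof=1) / math.sqrt(nb))
           if nb > 1 else 0.0)

    warnings = []
    if traj.n_frames < 10:
        warnings.append("unreliable-estimate: fewer than 10 frame blocks")
    settings = {"T": T, "n_frames": traj.n_frames,
                "high_freq_factor": high_freq_factor}
    rep_o = ObservableReport("eps_o", eps_o, err, "dimensionless",
                             settings=settings, warnings=list(warnings))
    rep = ObservableReport("eps", high_freq_factor * eps_o,
                           high_freq_factor * err, "dimensionless",
                           settings=settings, warnings=list(warnings))
    return rep_o, rep


# ---------------------------------------------------------------------------
# heat capacity
# ---------------------------------------------------------------------------

def equipartition_cv(topology: Topology,
                     n_potential_quadratic: Optional[int] = None) -> float:
    """Classical equipartition Cv in J/(mol·K) per mole of molecules.

    Each kinetic degree of freedom contributes R/2, each quadratic
    potential term another R/2.  A rigid four-site water has 6 kinetic
    DOF and no intramolecular potential (3R total); a flexible one has
    9 kinetic DOF plus 3 vibrational potential terms (6R) — hence the
    flexible-minus-rigid difference of 3R ≈ 25 J/(mol·K).
    """
    if topology.model.is_rigid:
        kin, pot = 6, 0
    else:
        kin, pot = 9, 3
    if n_potential_quadratic is not None:
        pot = n_potential_quadratic
    return 0.5 * (kin + pot) * c.R_GAS


def heat_capacity_fd(traj1: Trajectory, traj2: Trajectory,
                     n_molecules: int, n_blocks: int = 5,
                     noise_floor_sigma: float = 3.0) -> ObservableReport:
    """Finite-difference Cv from two NVE runs: Cv = ΔE / ΔT per mole.

    The runs must start from configurations sampled from a parent NVT
    trajectory so their mean temperatures straddle the state point.
    ΔE uses the total (kinetic + potential) energy.  Uncertainty is
    propagated from block variances of E and T; a |ΔT| below
    ``noise_floor_sigma`` times its own standard error raises
    :class:`IllConditionedError`.
    """
    means = []
    errs = []
    for tr in (traj1, traj2):
        e = tr.energies["total"].to_numpy()
        t = tr.energies["temperature"].to_numpy()
        means.append((e.mean(), t.mean()))
        errs.append((_block_sem(e, n_blocks), _block_sem(t, n_blocks)))
    dE = means[0][0] - means[1][0]
    dT = means[0][1] - means[1][1]
    se_dT = math.hypot(errs[0][1], errs[1][1])
    se_dE = math.hypot(errs[0][0], errs[1][0])
    if abs(dT) < noise_floor_sigma * se_dT:
        raise IllConditionedError(
            f"|ΔT| = {abs(dT):.3g} K is below {noise_floor_sigma}× its "
            f"standard error {se_dT:.3g} K; sample farther-apart configurations")
    cv = dE / dT / n_molecules * 1000.0  # kJ → J
    rel = math.sqrt((se_dE / dE) ** 2 + (se_dT / dT) ** 2) if dE else 0.0
    return ObservableReport(
        "Cv", cv, abs(cv) * rel, "J/(mol·K)",
        settings={"n_molecules": n_molecules, "dT": dT, "dE": dE})


# ---------------------------------------------------------------------------
# heat of vaporization
# ---------------------------------------------------------------------------

def heat_of_vaporization(liq_traj: Trajectory, model: WaterModel, T: float,
                         gas_traj: Optional[Trajectory] = None,
                         mu_model: Optional[float] = None,
                         params: SelfEnergyParams = SelfEnergyParams(),
                         n_molecules: Optional[int] = None) -> ObservableReport:
    """ΔH_vap = ⟨V_gas⟩ − ⟨V_liq⟩ − ΔE_self + RT, in kJ/mol.

    ⟨V_liq⟩ is the per-molecule potential energy of the liquid run.  For
    rigid models the gas-phase intramolecular energy is zero and no gas
    run is needed; flexible models require a single-molecule gas-phase
    trajectory.  ΔE_self = (μ_m − μ_g)²/(2α) removes the polarization
    self-energy of the enhanced condensed-phase dipole.
    """
    from .models import monomer_dipole
    nm = n_molecules or (liq_traj.topology.n_molecules
                         if liq_traj.topology else None)
    if nm is None:
        raise ValueError("n_molecules unknown")
    v_liq = liq_traj.energies["potential"].to_numpy() / nm
    se_liq = _block_sem(v_liq)
    if model.is_rigid or gas_traj is None:
        if not model.is_rigid and gas_traj is None:
            raise InsufficientDataError(
                "flexible models need a gas-phase single-molecule run")
        v_gas, se_gas = 0.0, 0.0
    else:
        vg = gas_traj.energies["potential"].to_numpy()
        v_gas, se_gas = float(vg.mean()), _block_sem(vg)
    mu = mu_model if mu_model is not None else monomer_dipole(model)
    de_self = self_energy_correction(mu, params)
    rt = c.KB * T
    value = v_gas - float(v_liq.mean()) - de_self + rt
    return ObservableReport(
        "dH_vap", value, math.hypot(se_liq, se_gas), "kJ/mol",
        settings={"T": T, "dE_self": de_self, "mu_model": mu,
                  "mu_gas": params.mu_gas, "alpha": params.alpha_pol})


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def diffusion(traj: Trajectory, fit_window: Tuple[float, float] = (5000.0, 15000.0),
              topology: Optional[Topology] = None,
              max_origins: int = 200) -> ObservableReport:
    """Diffusion constant from the Einstein relation, in 1e-5 cm²/s.

    D = slope/6 of the multi-origin center-of-mass mean-square
    displacement, fitted linearly over ``fit_window`` (fs; default
    5–15 ps).  Positions must be unwrapped.  A curvature diagnostic
    flags non-diffusive (e.g. ballistic) regimes.
    """
    topo = topology or traj.topology
    t1, t2 = fit_window
    times = traj.times
    if times[-1] - times[0] < t2:
        raise InsufficientDataError(
            f"trajectory span {times[-1] - times[0]:.0f} fs is shorter than "
            f"the fit window end {t2:.0f} fs")
    dt = float(np.median(np.diff(times)))
    com = np.array([molecule_com(traj.positions[f], topo)
                    for f in range(traj.n_frames)])

    lag_idx = np.unique(np.linspace(max(1, int(t1 / dt) // 2),
                                    int(round(t2 / dt)), 40).astype(int))
    msd = np.empty(len(lag_idx))
    for li, lag in enumerate(lag_idx):
        disp = com[lag:] - com[:-lag]
        stride = max(1, len(disp) // max_origins)
        d = disp[::stride]
        msd[li] = float((d**2).sum(axis=2).mean())
    lag_t = lag_idx * dt

    sel = (lag_t >= t1) & (lag_t <= t2)
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 MSD points in the window")
    coef, cov = np.polyfit(lag_t[sel], msd[sel], 1, cov=True)
    slope = coef[0]
    slope_err = math.sqrt(max(cov[0, 0], 0.0))
    # curvature diagnostic: quadratic term relative to linear over the window
    c2 = np.polyfit(lag_t[sel], msd[sel], 2)[0]
    curved = abs(c2) * (t2 - t1) > 0.5 * abs(slope)
    warnings = (["non-diffusive: MSD strongly curved over the fit window"]
                if curved else [])
    # Å²/fs → 1e-5 cm²/s:  1 Å²/fs = 1e-16 cm² / 1e-15 s = 1e-1 cm²/s
    conv = 1.0e-1 / 6.0 / 1.0e-5
    return ObservableReport(
        "D", slope * conv, slope_err * conv, "1e-5 cm^2/s",
        settings={"fit_window_fs": fit_window, "n_lags": int(sel.sum())},
        warnings=warnings)


# ---------------------------------------------------------------------------
# surface tension
# ---------------------------------------------------------------------------

def surface_tension(traj: Trajectory, n_blocks: int = 5) -> ObservableReport:
    """γ from the pressure-tensor (mechanical) route, in mN/m.

    γ = (L_z/2)[⟨P_zz⟩ − (⟨P_xx⟩ + ⟨P_yy⟩)/2]; the factor 1/2 accounts
    for the two interfaces of a slab normal to z.
    """
    e = traj.energies
    if e is None or any(col not in e for col in ("Pxx", "Pyy", "Pzz")):
        raise InsufficientDataError("trajectory lacks a pressure log")
    lz = traj.boxes[:, 2].mean()
    series = 0.5 * lz * (e["Pzz"].to_numpy()
                         - 0.5 * (e["Pxx"].to_numpy() + e["Pyy"].to_numpy()))
    gamma = float(series.mean()) * c.BAR_A_TO_MN_PER_M
    err = _block_sem(series, n_blocks) * c.BAR_A_TO_MN_PER_M
    return ObservableReport("gamma", gamma, err, "mN/m",
                            settings={"Lz": float(lz),
                                      "n_frames": traj.n_frames})


# ---------------------------------------------------------------------------
# density curve and TMD
# ---------------------------------------------------------------------------

def density_curve(runs: Sequence[Tuple[float, Trajectory]],
                  n_blocks: int = 5):
    """Mean density (kg/m³) with block errors at each temperature.

    ``runs`` is a sequence of (T, NPT trajectory).  Returns an array of
    (T, rho, rho_err) rows sorted by temperature.
    """
    rows = []
    for T, tr in runs:
        nm = tr.topology.n_molecules
        vol = tr.boxes.prod(axis=1)
        rho = nm * c.MASS_WATER / 6.02214076e23 / (vol * 1.0e-24) * 1000.0
        rows.append((T, float(rho.mean()), _block_sem(rho, n_blocks)))
    return np.array(sorted(rows))


def tmd_fit(curve: np.ndarray, window: float = 20.0) -> ObservableReport:
    """Temperature of maximum density from a quadratic fit near the peak.

    ``curve`` has rows (T, rho[, rho_err]).  Points within window/2 of
    the empirical maximum enter a quadratic fit whose vertex is the TMD.
    A maximum at the edge of the temperature grid yields a no-TMD
    verdict (value NaN) rather than an extrapolated number; a cubic-fit
    vertex is reported in the settings as a sensitivity check.
    """
    curve = np.asarray(curve, dtype=float)
    T, rho = curve[:, 0], curve[:, 1]
    order = np.argsort(T)
    T, rho = T[order], rho[order]
    imax = int(np.argmax(rho))
    if imax in (0, len(T) - 1):
        return ObservableReport(
            "TMD", float("nan"), 0.0, "K",
            settings={"verdict": "no-TMD", "window_K": window,
                      "reason": "density maximum at the grid edge"})
    sel = np.abs(T - T[imax]) <= window / 2.0
    if sel.sum() < 3:
        raise InsufficientDataError("fewer than 3 points in the fit window")
    coef, cov = np.polyfit(T[sel], rho[sel], 2, cov=(sel.sum() > 3))  \
        if sel.sum() > 3 else (np.polyfit(T[sel], rho[sel], 2), None)
    a, b = coef[0], coef[1]
    if a >= 0:
        return ObservableReport(
            "TMD", float("nan"), 0.0, "K",
            settings={"verdict": "no-TMD", "window_K": window,
                      "reason": "fit is not concave"})
    vertex = -b / (2.0 * a)
    err = 0.0
    if cov is not None:
        # d(vertex)/d(a,b) with covariance of the fit
        grad = np.array([b / (2.0 * a * a), -1.0 / (2.0 * a)])
        err = float(np.sqrt(max(grad @ cov[:2, :2] @ grad, 0.0)))
    sens = {}
    if sel.sum() >= 5:
        c3 = np.polyfit(T[sel], rho[sel], 3)
        roots = np.roots(np.polyder(c3))
        roots = roots[np.isreal(roots)].real
        if len(roots):
            sens["cubic_vertex"] = float(
                roots[np.argmin(np.abs(roots - vertex))])
    return ObservableReport(
        "TMD", float(vertex), err, "K",
        settings={"verdict": "ok", "window_K": window,
                  "n_points": int(sel.sum()), **sens})
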