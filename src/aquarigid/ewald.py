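"""Direct Ewald summation for point charges in orthorhombic periodic boxes.

The Coulomb energy is split into a short-ranged real-space sum
(erfc-screened, evaluated over a neighbor list), a reciprocal-space sum
over plane waves, the Gaussian self term, and corrections for excluded
intramolecular pairs (whose full interaction must not be counted but
whose screened image appears in the reciprocal sum).  Conducting
("tinfoil") boundary conditions: no surface dipole term.

All energies kJ/mol, forces kJ/mol/Å, positions Å, charges e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erf

from .constants import COULOMB

__all__ = ["EwaldParams", "choose_parameters", "real_space", "reciprocal",
           "self_energy", "excluded_correction"]


@dataclass(frozen=True)
class EwaldParams:
    alpha: float               # splitting parameter, 1/Å
    kmax: tuple                # max integer k index per axis
    cutoff: float              # real-space cutoff, Å


def choose_parameters(box, cutoff: float, accuracy: float = 1e-6) -> EwaldParams:
    """Pick alpha and k-space extents for a requested relative accuracy.

    alpha is set so the real-space term decays to ``accuracy`` at the
    cutoff; the reciprocal extent so the Gaussian weight decays to the
    same level at the largest included wavevector.
    """
    box = np.asarray(box, dtype=float)
    p = math.sqrt(max(-math.log(accuracy), 1.0))
    alpha = p / cutoff
    kcut = 2.0 * alpha * p
    kmax = tuple(int(math.ceil(kcut * L / (2.0 * math.pi))) for L in box)
    return EwaldParams(alpha=alpha, kmax=kmax, cutoff=cutoff)


def _pair_coef(rij, r, qprod, e_pair, alpha):
    """Force coefficient shared by the real-space and exclusion terms."""
    gauss = COULOMB * qprod * (2.0 * alpha / math.sqrt(math.pi)) \
        * np.exp(-(alpha * r) ** 2)
    return (e_pair + gauss) / (r * r)


def real_space(rij: np.ndarray, r: np.ndarray, qprod: np.ndarray,
               alpha: float):
    """Screened real-space term for a pair list.

    ``rij`` are minimum-image displacements r_i - r_j (n, 3), ``r``
    their norms, ``qprod`` the charge products q_i q_j.  Returns
    (energy, force_on_i_per_pair, virial_tensor).
    """
    if len(r) == 0:
        return 0.0, np.zeros((0, 3)), np.zeros((3, 3))
    e_pair = COULOMB * qprod * erfc(alpha * r) / r
    coef = _pair_coef(rij, r, qprod, e_pair, alpha)
    forces = coef[:, None] * rij
    return float(e_pair.sum()), forces, rij.T @ forces


def excluded_correction(rij: np.ndarray, r: np.ndarray, qprod: np.ndarray,
                        alpha: float):
    """Remove the screened interaction of excluded (intramolecular) pairs.

    The reciprocal sum contains erf(alpha r)/r for every pair including
    excluded ones; subtracting it here cancels that contribution.
    """
    if len(r) == 0:
        return 0.0, np.zeros((0, 3)), np.zeros((3, 3))
    e_pair = -COULOMB * qprod * erf(alpha * r) / r
    coef = _pair_coef(rij, r, qprod, e_pair, alpha)
    forces = coef[:, None] * rij
    return float(e_pair.sum()), forces, rij.T @ forces


def self_energy(charges: np.ndarray, alpha: float) -> float:
    """Gaussian self-interaction removed from the reciprocal sum."""
    return -COULOMB * alpha / math.sqrt(math.pi) * float((charges**2).sum())


def _kindices(box, kmax):
    """Half-space integer k triples (inversion symmetry gives factor 2)."""
    nx, ny, nz = kmax
    ns = []
    for ix in range(0, nx + 1):
        jlo = -ny if ix > 0 else 0
        for iy in range(jlo, ny + 1):
            klo = -nz if (ix > 0 or iy > 0) else 1
            for iz in range(klo, nz + 1):
                ns.append((ix, iy, iz))
    return np.array(ns, dtype=int)


class ReciprocalSum:
    """Cached reciprocal-space evaluator for a fixed box and splitting.

    Phases are built from per-axis tables exp(i 2π n x/L), so the cost
    per evaluation is dominated by complex multiplies rather than
    transcendental calls.  Wavevectors are truncated on a sphere
    commensurate with ``kmax`` so the result is insensitive to how the
    box factors into axes.
    """

    def __init__(self, box, alpha: float, kmax):
        self.box = np.asarray(box, dtype=float)
        self.alpha = alpha
        self.kmax = tuple(int(k) for k in kmax)
        n = _kindices(self.box, self.kmax)
        k = 2.0 * math.pi * n / self.box[None, :]
        k2 = (k**2).sum(axis=1)
        kcut2 = float(np.min(2.0 * math.pi * np.asarray(self.kmax)
                             / self.box)) ** 2
        keep = k2 <= kcut2 * (1.0 + 1e-12)
        self.n = n[keep]
        self.k = k[keep]
        self.k2 = k2[keep]
        V = float(np.prod(self.box))
        pref = COULOMB * 4.0 * math.pi / V  # ×2 half-space folded into 2·(2π/V)
        self.a_k = pref * np.exp(-self.k2 / (4.0 * alpha**2)) / self.k2
        self.fac = 2.0 * (1.0 / (4.0 * alpha**2) + 1.0 / self.k2)

    def _phases(self, positions):
        """exp(i k·r) for every site and wavevector, via axis tables."""
        out = None
        for axis in range(3):
            nmax = self.kmax[axis]
            tab = np.exp(1j * (2.0 * math.pi / self.box[axis])
                         * np.outer(positions[:, axis], np.arange(nmax + 1)))
            tab = np.concatenate([tab[:, :0:-1].conj(), tab], axis=1)
            term = np.take(tab, self.n[:, axis] + nmax, axis=1)
            if out is None:
                out = term
            else:
                out *= term
        return out

    def compute(self, positions: np.ndarray, charges: np.ndarray):
        """Energy, per-site forces, virial tensor."""
        ex = self._phases(positions)                  # (n_sites, K)
        S = charges @ ex
        s2 = S.real**2 + S.imag**2
        e_k = self.a_k * s2
        energy = float(e_k.sum())
        # Im[conj(ex) S] without forming the complex product
        im = ex.real * S.imag[None, :]
        im -= ex.imag * S.real[None, :]
        im *= self.a_k[None, :]
        im *= charges[:, None]
        forces = -2.0 * (im @ self.k)
        virial = np.eye(3) * energy
        virial -= (self.k.T * (e_k * self.fac)) @ self.k
        return energy, forces, virial


def reciprocal(positions: np.ndarray, charges: np.ndarray, box,
               alpha: float, kmax):
    """Reciprocal-space sum: energy, per-site forces, virial tensor."""
    return ReciprocalSum(box, alpha, kmax).compute(positions, charges)
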