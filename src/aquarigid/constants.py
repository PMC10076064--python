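"""Internal unit system and physical constants.

Internal units throughout the package: length Å, time fs, mass amu
(g/mol), charge e, energy kJ/mol, temperature K, pressure bar.  In this
system one amu·Å²/fs² equals exactly 1e4 kJ/mol, which fixes the kinetic
energy and force-to-acceleration conversion factors below.
"""

import math

# Coulomb constant, kJ·mol⁻¹·Å·e⁻²
COULOMB = 1389.35458

# Boltzmann constant, kJ·mol⁻¹·K⁻¹ (CODATA: R = 8.31446261815324 J/mol/K)
KB = 8.31446261815324e-3

# Gas constant, J·mol⁻¹·K⁻¹
R_GAS = 8.31446261815324

# Dipole conversion: 1 e·Å in Debye
EA_TO_DEBYE = 4.80321

# amu·Å²/fs² expressed in kJ/mol (exact in the g/mol convention)
KE_TO_KJMOL = 1.0e4

# Force (kJ/mol/Å) divided by mass (amu) to acceleration (Å/fs²)
FORCE_TO_ACC = 1.0e-4

# kJ·mol⁻¹·Å⁻³ expressed in bar
KJMOL_PER_A3_TO_BAR = 1.0e33 / 6.02214076e23 / 1.0e5  # ≈ 16605.39 bar

# bar·Å expressed in mN/m (1 bar·Å = 1e-5 N/m)
BAR_A_TO_MN_PER_M = 1.0e-2

# Site masses, amu
MASS_O = 15.999
MASS_H = 1.008
MASS_WATER = MASS_O + 2.0 * MASS_H

# Experimental gas-phase dipole moment of water, Debye
MU_GAS_EXPT = 1.8546

# Experimental water polarizability, Å³
ALPHA_EXPT = 1.44

# High-frequency (electronic) dielectric factor applied to the
# orientational dielectric constant of non-polarizable models
EPS_HIGH_FREQ_FACTOR = 1.78

KCAL_TO_KJ = 4.184

DEG = math.pi / 180.0
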