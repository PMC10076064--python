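# Methods

## The problem

Flexible water models resolve the OH stretch and HOH bend and therefore
need ~0.5 fs timesteps; constraining them rigid allows 2 fs and a
fourfold saving. But *which* geometry should the rigid body freeze? Two
choices bracket the practice:

* **MG (model geometry)** — the force field's own equilibrium bond
  length and angle, i.e. the shape of an isolated monomer.
* **EG (ensemble geometry)** — the average bond length and angle the
  flexible model actually adopts in liquid water at a reference state
  (298 K, 1 bar here).

The two differ because every flexible model is effectively polarizable:
bending the HOH angle changes the monomer dipole, so the condensed phase
pulls the average geometry toward a longer bond and a smaller angle, and
hence a larger dipole. The package quantifies this with the in-plane
polarizability

    α = q_H² r_OH² sin²(θ/2) (1 − 2a)² / k_θ,

the exact first-order dipole response of a harmonic bend to a field
conjugate to the angle (the test suite validates it against a numerical
finite-field relaxation to <1%). The polarization self-energy
ΔE_self = (μ_m − μ_g)²/2α (μ_g = 1.8546 D, α = 1.44 Å³ by default)
prices the enhanced condensed-phase dipole and is subtracted in the heat
of vaporization, ΔH_vap = ⟨V_gas⟩ − ⟨V_liq⟩ − ΔE_self + RT.

## Engine

A compact MD engine for four-site water only:

* **Units.** Å, fs, amu (g/mol), e, kJ/mol; Coulomb constant
  1389.35458 kJ·mol⁻¹·Å·e⁻²; 1 e·Å = 4.80321 D. One amu·Å²/fs² is
  exactly 10⁴ kJ/mol, which fixes all kinetic conversions.
* **Electrostatics.** Direct Ewald summation (erfc real space over a
  Verlet pair list, spherically truncated half-space reciprocal sum with
  cached per-axis phase tables, Gaussian self term, erf-corrections for
  the excluded intramolecular pairs), tinfoil boundary. The splitting
  parameter and k-space extent follow a single accuracy target
  (default 10⁻⁶); energy is invariant to the split within ~10⁻⁹
  relative, and the summation reproduces the NaCl Madelung constant to
  10⁻¹¹. Slabs use plain 3D Ewald (no slab correction), matching the
  usual practice for these systems.
* **Dispersion.** Site-site Lennard-Jones (Lorentz–Berthelot),
  potential-shifted to zero at the cutoff by default so that pair-list
  crossings do not pump energy in microcanonical runs; analytic tail
  corrections to energy and pressure for homogeneous systems, disabled
  for models whose fitted C6 is unreliable (the WAIL-schema flag) and
  for slabs.
* **M site.** Massless, rebuilt from r_M = r_O + a(r_OH1 + r_OH2) every
  evaluation; its force is redistributed by the chain rule — O receives
  (1−2a)F_M, each H receives aF_M — making forces the exact gradient of
  the reported potential (verified by central differences to 10⁻⁶).
* **Constraints.** The rigid triangle (two OH, one HH distance) is
  solved by a Newton iteration on the three Lagrange multipliers
  (batched 3×3 solves across molecules; corrections along reference
  bond directions preserve each center of mass), followed by an exact
  linear solve that removes velocity components along the constraints.
  Default tolerance 10⁻⁸ relative on the distances.
* **Integration.** Velocity Verlet. Rigid water at 0.5 fs holds total
  energy to <10⁻⁴ relative over 10 ps at desk scale; at 2 fs the
  *secular* drift slope stays within an order of magnitude of the
  0.5 fs slope, but the reversible O(dt²) energy fluctuation is ~16×
  larger — the reason all coexistence (NVE) runs use 0.5 fs regardless
  of rigidity.
* **Thermostats.** Stochastic velocity rescaling (canonical-sampling
  rescaling with the exact noise term; default relaxation 0.5 ps) and a
  two-link Nosé–Hoover chain. Both reproduce the canonical mean and
  kinetic-energy variance on an ideal gas within a few percent.
* **Barostats.** (i) Weak-coupling rescaling of molecular centers of
  mass, isotropic or per-axis (the per-axis mode is what ice-cell
  equilibration needs); compressibility gain 4.5×10⁻⁵/bar. With
  physical gains its density bias is negligible, but a large gain makes
  the cell chase pressure noise — so (ii) a Metropolis volume move
  (ΔU + PΔV − (N+1)k_BT Δln V acceptance) provides exact NPT sampling
  and serves as the barostat's oracle in the tests.
* **Pressure.** Molecular (group-based) virial: pair virials plus the
  analytic reciprocal-space tensor, referred to molecular centers, plus
  the center-of-mass kinetic tensor. Constraint forces and the virtual
  site then need no explicit terms. Verified against numerical
  volume derivatives to 7 digits.
* **Temperature.** Kinetic, over the true degrees of freedom: 6 per
  rigid molecule, 9 per flexible, 0 for frozen molecules, minus 3 when
  total momentum is conserved.

## Ice and slabs

Oxygens sit on a lonsdaleite lattice in an orthorhombic cell of 8
molecules, (a, √3a, c) with a = 4.518 Å, c = 7.356 Å (≈0.92 g/cm³);
supercells hold 8·n1·n2·n3 molecules. No periodic orthorhombic ice Ih
supercell holds exactly 300 molecules, so reduced-scale boxes of 24–96
molecules (stacked in z as needed) stand in for the full-scale boxes.

Hydrogens are assigned by orienting the 4-regular hydrogen-bond graph
along an Eulerian circuit — which yields exactly two donated bonds per
oxygen, i.e. a Bernal–Fowler-valid state, by construction — then
decorrelated and de-polarized by reversing random directed loops, a move
that preserves the ice rules exactly. Replicas from different seeds
differ in their bond orientations and end with a net dipole below
0.01 D per molecule. Edges carry explicit periodic-image shifts, so
even a single 8-molecule cell (where one oxygen pair can be bonded
through two images) is handled correctly and stacking preserves the
network across the seam.

The liquid–ice–liquid (LIL) slab follows the staged protocol: add a
vacuum gap (default 10 Å) along z, freeze the central half of the
molecules, melt the two ends at T_melt under the stochastic-rescaling
thermostat, then cool to the target temperature in two equal stages
(core frozen, then everything mobile). Frozen means excluded from
integration with zero velocity, not restrained. Melting is verified
with the Errington–Debenedetti tetrahedral order parameter; molecules
with fewer than four neighbors within 3.5 Å (slab surfaces, strays in
the vacuum) are excluded from the verdict, and the default threshold of
0.8 separates pristine ice (q ≈ 1) from disordered packings (q ≲ 0.6).

## Melting temperature: NVE three-phase coexistence

Each proton-disorder replica's slab is run microcanonically from two
bracketing initial temperatures T_L < T_M < T_H. Above T_M ice melts
and cools the slab; below, freezing heats it — both trajectories relax
toward coexistence without thermostats or barostats, whose coordinate
rescaling is exactly what the method avoids. Equilibrium is declared
when the trailing rolling averages of the two temperature traces agree
within a tolerance *and stay within it to the end of the traces* (a
single crossing of two diverging traces does not count); the
temperature is then averaged over a fixed span, the two runs of a pair
averaged, and replicas pooled with the standard error of the mean. A
pair that never agrees signals complete melt or freeze and is excluded
and reported.

Full-scale settings (1 ns window, 0.1 K tolerance, 10 ns average, six
replicas, 1200-molecule slabs) ship in the `paper` preset together with
the per-model bracketing temperatures and the rigid reference model the
method is validated on. The `desk` preset divides the window and the
averaging span by 500; the tolerance is instead *widened* to 2 K, since
the rolling-average noise of a few-hundred-molecule slab grows as the
window shrinks — a 0.1 K criterion is resolvable only at full scale.

## Property estimators

RDF (ideal-gas-normalized, intramolecular pairs excluded), dielectric
constant from box-dipole fluctuations (ε_o = 1 + 4π(⟨M²⟩−⟨M⟩²)/3Vk_BT;
the reported ε multiplies by the high-frequency factor 1.78 since the
models carry no electronic polarizability), finite-difference heat
capacity from paired NVE runs (total energy over mean-temperature
difference, with an ill-conditioning guard), heat of vaporization as
above, diffusion from a multi-origin MSD fit over 5–15 ps with a
curvature diagnostic that flags ballistic data (no finite-size
correction, matching common practice for these comparisons), surface
tension by the mechanical route γ = (L_z/2)[⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2],
and the temperature of maximum density from a quadratic fit within a
20 K window of the empirical maximum — refusing to extrapolate when the
maximum sits on the grid edge (the "no TMD in this range" verdict), and
reporting a cubic-fit vertex alongside as a sensitivity check. All
uncertainties are 5-block averages unless configured otherwise.

The classical equipartition bookkeeping behind the heat-capacity story:
a rigid water has 6 kinetic DOF (3R total), a flexible one 9 kinetic
plus 3 quadratic potential DOF (6R), so constraining the intramolecular
motion removes exactly 3R ≈ 25 J mol⁻¹ K⁻¹ for harmonic interactions.
The simulated gap uses non-interacting harmonic water with monomer
geometries drawn from the exact canonical Gaussian — necessary because
a global rescaling thermostat only scales the total energy of
non-interacting molecules and can never repartition it between modes.

## What the synthetic fixtures do and do not show

The fixture generators (independent uniformly-oriented dipoles,
Brownian walkers, mean-reverting plateau pairs, noisy parabolic density
curves, pristine lattices) each embed their ground truth in the output
metadata. They validate the *estimators and protocol logic* —
normalization, unit chains, window/onset logic, pooling and error
propagation — at known answers. They do not emulate water
thermodynamics: passing them says the machinery measures correctly, not
that any particular force field is accurate. Conversely, the full-scale
melting-point and Table-of-properties numbers require cluster-scale
trajectories (hundreds of ns, thousand-molecule slabs) and are not
reproduced at desk scale; the package ships the exact configuration to
launch them.

## Numerical choices and limitations

* Orthorhombic boxes only; molecules are kept whole internally and
  wrapped on output.
* Boxes must exceed twice the cutoff; the Verlet skin shrinks
  automatically near that limit.
* Default desk problem sizes: 8–96 molecules for engine checks, 27–64
  for liquid-state runs, 24–96 (×2–4 stacking) for slabs; chosen so the
  full suite runs in minutes on one core while every oracle stays
  statistically meaningful.
* Constraint solver tolerance 10⁻⁸ (relative); Ewald accuracy 10⁻⁶;
  blow-up guard at 100 kJ/mol per molecule of total-energy change.
* The engine handles four-site water exclusively — "LJ fluid" test
  systems are zero-charge water molecules. No PME, no GPU, no
  polymorphs beyond ice Ih, no nuclear quantum effects.
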