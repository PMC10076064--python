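# aquarigid

Rigid-body versions of flexible four-site water models, a compact
molecular-dynamics engine to simulate them, and the **NVE three-phase
coexistence method** for measuring the melting temperature of ice —
plus the standard liquid-water property suite (dielectric constant,
heat capacity, heat of vaporization, diffusion, surface tension,
density curve / temperature of maximum density, RDFs).

## Who this is for

Force-field developers and simulators who want to run a flexible water
model (explicit OH stretch and HOH bend, 0.5 fs timesteps) as a rigid
body (2 fs timesteps, 4× cheaper) without silently changing its
physics. The catch: a flexible model's *average* geometry in liquid
water is not its equilibrium geometry. Bending the angle changes the
molecular dipole — an effective in-plane polarizability

    α = q_H² r_OH² sin²(θ/2) (1 − 2a)² / k_θ

— so the condensed phase stretches the bond, closes the angle, and
raises the dipole. Freezing the monomer at the force field's own
geometry (**MG**) therefore under-polarizes it; freezing it at the
ensemble-averaged liquid geometry (**EG**, measured at 298 K and 1 bar)
preserves the condensed-phase dipole and tracks the flexible model far
more closely. The package builds both variants, simulates them, and
measures the properties where the difference shows.

The melting temperature uses a liquid–ice–liquid slab with a vacuum gap
run *microcanonically* from two bracketing temperatures: above T_M ice
melts and the slab cools, below it ice grows and the latent heat warms
the slab, so both trajectories relax to coexistence with no thermostat
or barostat to perturb the interface. Equilibrium is declared when the
1 ns rolling averages of the two temperature traces agree within 0.1 K
(at full scale) and stay together; the following 10 ns average, pooled
over six proton-disordered replicas, is T_M ± SEM.

## Worked example

```python
from aquarigid import (get_model, rigidify_mg, rigidify_eg,
                       monomer_dipole, MonomerGeometry)
from aquarigid.models import self_energy_correction

fl = get_model("q-TIP4P/F")            # flexible, built in
mg = rigidify_mg(fl)                   # frozen at the model geometry
eg = rigidify_eg(fl, MonomerGeometry(0.9635, 104.670))

print(f"MG: {mg.rigid_geometry.r_OH} Å, {mg.rigid_geometry.theta_HOH} deg, "
      f"mu = {monomer_dipole(mg):.3f} D")
print(f"EG: mu = {monomer_dipole(eg):.3f} D, "
      f"dE_self = {self_energy_correction(monomer_dipole(eg)):.2f} kJ/mol")
```

prints

```
MG: 0.9419 Å, 107.4 deg, mu = 2.194 D
EG: mu = 2.316 D, dE_self = 4.46 kJ/mol
```

— the MG monomer keeps the gas-phase dipole of the model while the EG
monomer carries the ~0.12 D condensed-phase enhancement; the 4.5 kJ/mol
polarization self-energy of that enhancement is what the heat of
vaporization must give back.

A miniature melting-point run (desk scale — the numbers are
protocol demonstrations, not converged melting points):

```bash
aquarigid tm --model TIP4P/Ice --t-low 265 --t-high 275 \
             --replicas 1 --seed 1 --out tm.json   # a few minutes
```

builds a proton-disordered ice Ih replica, melts and re-freezes its
ends into a liquid–ice–liquid slab, launches the paired NVE runs and
pools the rolling-average equilibrium temperatures, ending with

```
T_M = 281.75 ± 0.00 K (1/1 replicas converged)
```

(the upward drift of this miniature slab reflects partial freezing —
a 48-molecule, 3 ps demonstration of the machinery, nowhere near a
converged melting point, whose bracketing tolerance is set by the
~7 K rolling-average noise at this size). Converged
full-scale settings (1200-molecule slabs, 1 ns windows, 10 ns
averaging, six replicas, the per-model bracketing temperatures) ship in
the `paper` preset (`aquarigid ... --config $(python -c
"from aquarigid.io import load_preset; print(load_preset('paper'))")`).

Other entry points: `aquarigid rigidify`, `build-ice`, `build-slab`,
`geometry`, `run`, `observables`, `fixtures` — every command writes a
manifest JSON that reproduces the run bit-identically from its seed.

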