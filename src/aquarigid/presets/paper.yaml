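# Full-scale production settings.  Flexible models integrate at 0.5 fs,
# rigid models at 2 fs (see the models section); NVE coexistence legs
# always use 0.5 fs regardless of rigidity.  Cluster-scale: the
# trajectory lengths implied here (100+ ns property runs, 10 ns T_M
# averaging windows over six proton-disorder replicas) are far beyond a
# desktop session.
engine:
  timestep: 0.5            # fs (flexible default; rigid models use 2.0)
  ensemble: NPT
  thermostat: nose_hoover
  tau_t: 2000.0            # fs
  T_target: 298.0
  barostat: weak_coupling
  tau_p: 5000.0            # fs
  P_target: 1.0            # bar
  cutoff: 10.0             # Å van der Waals cutoff
  ewald_accuracy: 1.0e-6
  output_every: 200

coexistence:
  window: 1.0e+6           # fs  (1 ns rolling average)
  tol: 0.1                 # K
  avg_span: 1.0e+7         # fs  (10 ns averaging window)
  replicas: 6
  gap: 10.0                # Å vacuum
  melt_time: 2.0e+5        # fs  (200 ps melt stage)
  cool_time: 2.0e+5        # fs  (200 ps two-stage cool)
  n_steps: 60000000        # 30 ns NVE legs at 0.5 fs

builder:
  n_molecules: 96          # per proton-disorder replica before stacking
  stack_z: 4
  t_equil: 1.0e+6          # fs NPT cell equilibration
  t_avg: 9.0e+5            # fs trailing average for cell lengths

observables:
  rdf_rmax: 9.0
  rdf_bin: 0.02
  fit_window: [5000.0, 15000.0]   # fs, MSD fit 5-15 ps
  n_blocks: 5
  temperature: 298.0

models:
  # melt / bracketing temperatures (K) for the T_M protocol
  q-TIP4P/F:    {timestep: 0.5, t_melt: 300.0, t_low: 245.0, t_high: 265.0}
  q-TIP4P/F-MG: {timestep: 2.0, t_melt: 300.0, t_low: 225.0, t_high: 245.0}
  q-TIP4P/F-EG: {timestep: 2.0, t_melt: 300.0, t_low: 245.0, t_high: 265.0}
  BLYPSP-4F:    {timestep: 0.5, t_melt: 300.0, t_low: 245.0, t_high: 265.0}
  BLYPSP-4F-MG: {timestep: 2.0, t_melt: 300.0, t_low: 230.0, t_high: 250.0}
  BLYPSP-4F-EG: {timestep: 2.0, t_melt: 320.0, t_low: 245.0, t_high: 265.0}
  WAIL:         {timestep: 0.5, t_melt: 320.0, t_low: 260.0, t_high: 280.0}
  WAIL-MG:      {timestep: 2.0, t_melt: 320.0, t_low: 240.0, t_high: 260.0}
  WAIL-EG:      {timestep: 2.0, t_melt: 340.0, t_low: 260.0, t_high: 280.0}
  TIP4P/Ice:    {timestep: 2.0, t_melt: 320.0, t_low: 265.0, t_high: 285.0}
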