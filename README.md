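# ribostate

Implicit-solvent binding energetics and conformational-state analysis
for riboswitch aptamer–ligand complexes.

Purine riboswitches are bacterial mRNA elements whose aptamer domain —
a three-way-junction RNA fold — binds a small nucleobase-like ligand
and thereby switches downstream gene expression. Two questions drive
their computational analysis: *how strongly* does each candidate ligand
bind (and does the ranking track experimental dissociation constants),
and *how does binding reshape the junction*, which interconverts
between an open and a closed conformation. `ribostate` implements the
standard end-point post-processing used to answer both from molecular
dynamics snapshots, for people who study RNA–ligand recognition but
want a desk-testable, dependency-light toolchain:

* **MM-GB/SA binding free energies.** For snapshots of a complex,

  ΔG_bind = ΔH_gas + ΔG_solv − TΔS,
  ΔH_gas = ΔE_int + ΔE_vdW + ΔE_ele,
  ΔG_solv = ΔG_pol + ΔG_nonpol,  ΔG_nonpol = γ·SASA + β,

  with the polar solvation term from a generalized-Born model (OBC
  effective radii) and the nonpolar term from Shrake–Rupley
  solvent-accessible surface area. Replicas are aggregated with
  standard errors σ = sd(replica means)/√N.
* **Per-nucleotide decomposition** of the binding enthalpy into
  electrostatic, van der Waals, polar and nonpolar shares (pairwise
  terms split half to each partner), so the hot-spot nucleotides of the
  pocket (the A21/U22/U51/A52/U74/U75 tier of the purine aptamer) can
  be identified.
* **Normal-mode vibrational entropy** for the −TΔS term: minimize,
  mass-weighted Hessian, harmonic-oscillator entropy over the 3N−6
  genuine modes.
* **Trajectory geometry**: Kabsch-superposed RMSD series, per-residue
  RMSF about the mean structure, RMSF = √(3B/8π²) conversion of
  crystallographic B-factors, hydrogen-bond occupancies
  (distance + angle criteria), and mass-center distance series between
  nucleotide groups.
* **Open/middle/closed state analysis**: strict-threshold
  classification of a junction distance (D1), state percentages, and
  the statistics linking geometry, energetics and experiment
  (Pearson r, r², ΔG_exp = RT ln K_d).
* **Synthetic generators with planted truth** — random parameterized
  bead complexes, Markov-switching two-state distance series, Gaussian
  energy-component tables, jittered trajectories — so every stage is
  testable without downloading structures or force fields.

## Worked example

```python
import numpy as np
from ribostate.mmgbsa import snapshot_binding_components, aggregate_replicas
from ribostate.synthetic_data import (ToySystemSpec, TwoStateSpec,
    make_toy_system, make_two_state_series, receptor_ligand_split)
from ribostate.state_analysis import StateThresholds, classify_states

system, frame = make_toy_system(ToySystemSpec(n_atoms=12, n_ligand_atoms=3, seed=7))
receptor, ligand = receptor_ligand_split(system)
comp = snapshot_binding_components(system, frame, receptor, ligand)
result = aggregate_replicas({0: [comp]}, t_delta_s=-2.0)
print(result.summary()[["mean", "sigma"]].round(3))

series, _ = make_two_state_series(TwoStateSpec(n_frames=10_000, seed=7))
states = classify_states(series, StateThresholds(closed_max=20.59, open_min=22.98))
print(f"open {states.pct_open:.1f}%  middle {states.pct_middle:.1f}%  closed {states.pct_closed:.1f}%")
```

prints

```
                 mean  sigma
term
dE_ele         28.456    0.0
dE_vdw         -0.232    0.0
dE_int          0.000    0.0
dG_pol        -27.116    0.0
dG_nonpol      -1.600    0.0
dG_ele_pol      1.340    0.0
dG_vdw_nonpol  -1.831    0.0
dH             -0.491    0.0
TdS            -2.000    0.0
dG_bind         1.509    0.0
open 26.0%  middle 49.4%  closed 24.6%
```

The energy rows are one snapshot's Δ-terms for the random bead complex:
the unfavourable inter-group electrostatics (ΔE_ele) are almost
cancelled by the polar solvation change (ΔG_pol) — the familiar
ele/pol compensation — while ΔE_int is identically zero under the
single-trajectory convention. σ is zero because there is a single
replica. The state percentages recover the two-state generator's
planted stationary distribution (here P(open) = 0.5, with the
middle band absorbing frames whose emission noise lands between the
thresholds 20.59 and 22.98 Å).

A YAML-driven CLI wraps the same stages
(`simulate`, `energy`, `decompose`, `entropy`, `geometry`, `states`,
`report`, `all`):

```bash
ribostate states --config run.yaml --seed 7 --out out/
```

Every emitted TSV carries the package version, the config hash and the
explicit overrides in its header; identical reruns are byte-identical.

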