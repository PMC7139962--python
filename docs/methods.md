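# Methods

This note records the models implemented in `ribostate`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and conventions

The package post-processes solute-only snapshots of an RNA
aptamer–ligand complex in implicit solvent. Coordinates are Å, masses
amu, charges elementary units, energies kcal/mol, temperatures K —
no unit switching anywhere. Internal residue indices are 0-based;
author (PDB) residue numbers are preserved verbatim and used in every
report, so output labels match the crystallographic U51/C74 style that
the riboswitch literature uses. Molecular dynamics itself, charge
derivation, explicit solvent, PME and numerical Poisson–Boltzmann
solvers are out of scope: a synthetic generator stands in for the
simulation engine.

## Energy model

**Gas phase.** Coulomb (k = 332.0637 kcal·Å/(mol·e²)) and 12-6
Lennard-Jones with Lorentz–Berthelot combining (Rmin_ij = rmin_half_i +
rmin_half_j, ε_ij = √(ε_i ε_j)). No distance cutoff: snapshots are a
few thousand atoms at most and exact pair sums avoid cutoff artifacts.
Intramolecular sums remove 1-2/1-3 pairs and scale 1-4 pairs (ele 1/1.2,
vdW 1/2, the AMBER-style convention). Bonds are harmonic with
E = (k/2)(r−r₀)²; note the ½ convention — the Hessian of a bond with
force constant k has the [[k,−k],[−k,k]] block.

**Polar solvation.** Generalized Born with OBC-rescaled effective
radii: per-atom HCT descreening integrals I_i (pairwise closed form,
verified in the tests against direct quadrature of the 1/r⁴ shell
integral), Ψ = I_i·ρ̃_i with ρ̃ = ρ − 0.09 Å, and

    1/R_i = 1/ρ̃_i − tanh(αΨ − βΨ² + γΨ³)/ρ_i,   α=1.0, β=0.8, γ=4.85.

Energy: E = −(k/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB with
f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j}), self terms included; ε_in = 1,
ε_out = 80. An isolated atom reduces exactly to the Born expression.
The source study used a Poisson–Boltzmann solver for its totals and GB
only for decomposition; this package deliberately uses the single GB
model for **both**, so totals and per-residue decompositions are
mutually consistent and every number is desk-checkable against a
brute-force double sum.

**Nonpolar solvation.** ΔG_nonpol = γ·SASA + β with γ = 0.00542
kcal/(mol·Å²) and β = 0.92 kcal/mol; SASA by Shrake–Rupley sphere-point
counting (golden-spiral points, default 960 per atom, probe 1.4 Å,
atom radii = LJ rmin_half). An isolated atom is exact at any point
count; a two-sphere system matches the spherical-cap closed form to
within the point-sampling error (~2% at 960 points). Because the point
grid is atom-centered, SASA is exactly translation-invariant but only
approximately rotation-invariant; the residual falls roughly linearly
with the point count (measured: ~1.2 Å² at 960 points, ~0.14 Å² at
3840 on a 12-bead complex). All other terms are rigid-motion invariant
to 1e−9.

**Binding components.** Under the single-trajectory convention the
receptor and ligand coordinates are taken from the complex snapshot, so
ΔE_int cancels identically and ΔE_ele/ΔE_vdW reduce to inter-group
sums, which are evaluated directly (the equality with the explicit
complex-minus-species route is asserted in the tests). A
three-trajectory mode accepts independently relaxed species frames and
produces nonzero ΔE_int; the published ~1.4 kcal/mol internal terms
imply some such separate treatment, but since the original reference
state is not described, neither mode is claimed to be the authors'.

**Replica aggregation.** Per-replica means are averaged to a grand
mean; the standard error of every term is σ = sd(replica means)/√N
(sample sd, ddof = 1), following the convention used for the published
tables where N = 10. With a single replica σ is reported as 0. Derived
rows satisfy exact identities: ΔH = ΔE_ele+ΔE_vdW+ΔE_int+ΔG_pol+ΔG_nonpol,
ΔG_bind = ΔH − TΔS, ΔG_ele+pol = ΔE_ele+ΔG_pol, ΔG_vdW+nonpol =
ΔE_vdW+ΔG_nonpol; report writers re-audit them at 0.01 kcal/mol.

**Per-residue decomposition.** Pairwise ele/vdW/GB-cross terms are
split half to each partner's residue; GB self-energy changes stay with
their own residue; per-atom SASA differences are scaled by γ and
assigned to their residue; the β constant (which contributes −β to the
delta, appearing once per species) is booked on a pseudo-residue named
`offset`. Column sums reproduce the system deltas exactly for ele/vdW
and to 1e−6 for pol/nonpol.

## Normal-mode entropy

The harmonic surface is bonds + intramolecular Coulomb/LJ + GB polar.
The sphere-point SASA term is piecewise-constant in coordinates — it
adds no curvature and its step discontinuities defeat line searches —
so it is deliberately omitted from this surface. Gradients are
analytic for the gas-phase terms; the GB term is differentiated by
central differences (step 1e−5 Å). Minimization is quasi-Newton
(L-BFGS) to an RMS-gradient tolerance of 1e−4 kcal/(mol·Å);
non-convergence is flagged, not raised. The Hessian is built by
central differences of the gradient (step 1e−4 Å) and symmetrized;
frequencies come from the mass-weighted eigenvalues. Modes with
|ν| < 1 cm⁻¹ are treated as rigid-body (numerical Hessians on the toy
systems place true rigid modes far below this); eigenvalues that map
beyond −1 cm⁻¹ count as imaginary, and any snapshot whose species
carry imaginary modes is dropped and logged rather than silently
included. The vibrational entropy is the harmonic-oscillator sum
S = R Σ [x/(eˣ−1) − ln(1−e^{−x})], x = hcν/kT, R = 0.0019872
kcal/(mol·K). TΔS = T(S_complex − S_receptor − S_ligand) averaged over
a thinned snapshot subset (minimization dominates cost; default every
10th analysis snapshot), with σ = sd/√N over used snapshots.

Translational/rotational gas-phase entropy and symmetry corrections
are intentionally excluded — ligand rankings rest on ΔS differences.
A consequence worth stating: on a toy where binding merely stiffens
two fragments into one molecule, the complex *gains* vibrational modes
and vibrational-only TΔS is positive; the negative TΔS of real binding
data is dominated by the excluded translational/rotational loss.

## Trajectory geometry

RMSD uses Kabsch superposition (SVD with determinant sign correction;
collinear or <3-point inputs have no unique rotation and fall back,
flagged, to a translation-only fit). RMSF superposes all frames onto
the mean structure with one refinement pass — the standard fluctuation
definition — then averages atomic √⟨|r−⟨r⟩|²⟩ within each residue.
Note that superposition absorbs the 6 rigid degrees of freedom
(≈ 2/N of the variance), which is why planted-jitter recovery tests
run on a 60-atom scaffold. Crystallographic B-factors convert via
RMSF = √(3B/8π²).

Hydrogen-bond criteria are not stated in the source study; the package
defaults to the common trajectory-analysis convention — donor-heavy to
acceptor distance ≤ 3.5 Å AND donor–H–acceptor angle ≥ 135° — both
config-overridable and echoed in output headers. Occupancy is the
satisfied-frame fraction; mean distance/angle are over satisfying
frames only. Distance series are Euclidean distances between group
mass centers; the shipped default set uses the nucleotide backbone
atoms (P, O3′, O5′, C3′, C4′, C5′) and includes the pocket distance
between the U51+A52 and C74+C75 mass centers alongside the junction
distance D1. Which atoms define the figure-only distances (D4–D7) was
never printed, so those stay config-only with no default asserted.

## State analysis

Thresholds: closed_max = 20.59 Å and open_min = 22.98 Å by default
(the trailing-window mean D1 of a ligand-bound and an apo trajectory
respectively; `derive_thresholds` recomputes them from series).
Classification is strict on both sides — "greater than"/"less than" —
so a frame exactly at a threshold is labelled middle; percentages are
exact count ratios and sum to 100. ΔG_exp = RT ln K_d (equivalently
−RT ln K_a): the widely reprinted "−RT ln K_d" form gives the wrong
sign for sub-molar K_d and is not used. Cross-ligand correlations are
computed on per-ligand summary values (n = 5), matching how the
published state table is constructed; recomputing the GR(C74U)
correlations from the *rounded* printed entries gives ≈0.65/−0.55
versus the published 0.66/−0.56, a pure rounding sensitivity that the
acceptance tests band accordingly. The published state table also
carries an anomalous duplicate row (identical ADE entries for both
aptamers); it is taken at face value for all arithmetic.

## Synthetic data

The generators define the study conditions for every test:

* **Bead complexes** — uniform random coordinates packed sequentially
  with a 2.8 Å minimum separation, charges in ±0.8 e shifted exactly
  onto the requested net charge, LJ rmin_half 1.2–2.0 Å, ε 0.05–0.3,
  GB radii 1.2–1.8 Å, screen 0.8, masses 12–16 amu. The last k atoms
  form the ligand residue.
* **Two-state series** — first-order Markov chain on {open, closed}
  started from its stationary distribution, Gaussian emission about
  the state means (defaults: means 22.98/20.59 Å matching the default
  thresholds, sd 0.5 Å, stay probabilities 0.98). Gaussian emission is
  a modelling choice; the real distance histograms show two peaks but
  no stated distributional form.
* **Energy tables** — iid Gaussian per-term per-frame draws, with an
  optional between-replica mean spread for standard-error checks.
* **Jittered trajectories** — isotropic per-atom Gaussian displacement
  (planted RMSF = √3·sd), optionally wrapped in random global rigid
  motions to exercise superposition.

All generators draw from substreams spawned off one root seed with
fixed per-generator spawn keys, so adding a generator never perturbs
another's draws, and everything is bit-reproducible for a fixed seed.

What these fixtures do **not** emulate: real RNA geometry, force-field
quality parameters, correlated collective motions, or trajectory
autocorrelation beyond the two-state chain. Passing tests therefore
demonstrate the correctness of the estimators and energy algebra, not
the physical accuracy of MM-GB/SA for any particular riboswitch;
trajectory-dependent published quantities (absolute energy means, RMSD
tables, apo-state percentages) require the original multi-microsecond
trajectories and are never asserted.

## Problem sizes

The test and acceptance runs use deliberately small problems — bead
systems of 4–20 atoms (60 for the RMSF scaffold), 10³–10⁵-frame
synthetic series, single-digit snapshot counts for normal-mode
entropy — chosen so the full suite re-verifies every oracle in
seconds while leaving the algorithms identical to what larger inputs
would exercise.

## Known limitations

* One GB model serves both totals and decomposition; absolute polar
  energies will differ from Poisson–Boltzmann post-processing.
* SASA rotational covariance is approximate at finite point counts
  (see above); raise `sasa_points` where this matters.
* The entropy term covers vibrations only; no quasi-harmonic or
  interaction-entropy alternatives are provided.
* The selection grammar covers resid/name/resname with boolean
  operators — sufficient for backbone and nucleotide-group selections,
  not a general query language.
* No mmCIF, AMBER prmtop, explicit solvent or periodic boxes.
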