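# Methods

## Model

One protein, three reference conformations: open (O), apo/partially closed
(A), holo/fully closed (H). The coarse-graining is mixed two-bead: a CA bead
per residue at the Cα position, and for every non-glycine residue a
side-chain (SC) bead at the geometric centroid of the side-chain heavy
atoms. The two-bead set defaults to *all* non-glycine residues; narrower
schemes are selectable. Charges are ±1e on the SC beads of Lys/Arg and
Asp/Glu; histidine is neutral at the modelled pH (configurable). All
coordinates are in Å; energies, temperatures and times are in reduced units.

### Backbone terms

Harmonic bonds (consecutive CA-CA and SC-CA, k = 100 ε/Å²), harmonic
pseudo-angles over the CA trace plus one SC-orientation angle per SC bead
(k = 20 ε/rad²), and cosine dihedrals over CA quadruples plus one chirality
dihedral per SC bead, `k1(1−cos Δφ) + k3(1−cos 3Δφ)` with k1 = 1.0,
k3 = 0.5 ε. Equilibrium values are measured on the open structure (the
`theta_O` convention). The force constants are this package's reduced-unit
convention, chosen so that at the working temperature T = 0.5 the backbone
is stiff relative to the contact energy scale (ε = 1) but not rigid.

Hinge residues are those whose CA pseudo-angle differs by more than 15° or
whose flanking pseudo-dihedrals differ by more than 30° between any pair of
reference states ("and/or" rule configurable). Every angle/dihedral touching
a hinge residue is hinge-flagged. Two knobs act on flagged terms:

* γ ∈ (0,1] multiplies their force constants (γ < 1 = softer hinge);
* the `theta_OAH` angle-model variant reduces each flagged term's constant
  so that all three states' native values lie within 1 k_BT of the open
  minimum at T = 0.5 (harmonic terms: k ≤ 2T/Δθ²_max; dihedrals scaled so
  the largest inter-state deviation costs ≤ T). This keeps each term
  single-welled and stable while removing the pure open-state bias from the
  hinge, which is the intent of a hinge treatment admitting all states.

### Contacts

A native contact is a residue pair with any heavy-atom pair within 4.5 Å
and |Δres| ≥ 4 (the common structure-based-model convention; the synthetic
fixture uses 6.0 Å because its residues carry far fewer atoms than real side
chains). The bead pair is SC-SC when side-chain atoms drive the contact and
both residues carry SC beads, else CA-CA; r0 is the bead-bead distance in
the native state.

Classification over the three per-state maps: in all three → CORE
(ε_shared = 1.0, r0 averaged); in exactly one → that state's specific class
(ε_spec = 0.4, state's own r0); in exactly two → PAIR_SHARED at ε_shared
with r0 averaged over the two (kept as its own class so nothing is silently
discarded and users can audit it). The ratio ε_spec/ε_shared is validated
for [0.4, 0.6]; outside it a warning is raised. Ligand-mediated contacts are
inter-domain (NTD×CTD) residue pairs whose members both have a heavy atom
within the cutoff of any ligand atom in the holo structure; their strength
is ε_L·ε_shared with ε_L ∈ [0, 1.5] acting as an implicit ligand
concentration. Ligand entries duplicating a native pair are dropped (classes
stay a partition; the native well already covers the pair), and at ε_L = 0
the whole ligand list is dropped, making the energy exactly independent of
it.

Each contact is a single-minimum 6-12 well `ε[(r0/r)¹² − 2(r0/r)⁶]`
(a Gaussian well of width 0.6 Å is config-selectable). The triple-basin
character of the landscape comes from the union of class-labelled wells,
not from multi-welled pair potentials.

### Non-bonded and electrostatics

Excluded volume `ε_rep(σ/r)¹²` between all pairs that are neither bonded
(1-2/1-3/1-4) nor contacts, with σ = 4.0 Å for CA-CA and 2.0 Å for pairs
involving SC beads (configurable; the literature is silent here, these
radii prevent chain crossing without perturbing native wells).

Electrostatics are Debye-Hückel: `U = B q₁q₂ exp(−r/λ_D)/(ε_r r)` over
charged, non-excluded pairs. The reduced-unit Coulomb prefactor maps the
working temperature T = 0.5 to 300 K, i.e. one reduced energy unit is
2 k_B·300 K ≈ 1.192 kcal/mol, giving B = 332.064/1.192 ≈ 278.5 ε·Å·e⁻²;
λ_D = 3.04·sqrt(ε_r/80)/sqrt(I[M]) Å, infinite at I = 0 (the unscreened
Coulomb limit, verified in tests). Supported ranges ε_r ∈ [40, 160],
I ∈ [0, 0.20] M; defaults 80 and 0.10 M. An optional finite-ion-size factor
exp(κa)/(1+κa) is provided (default off, a = 0) since the literature uses
both forms. Electrostatics are cut off at 3 λ_D with a shift to zero; the
contact list has no cutoff.

## Dynamics

BAOAB-split Langevin dynamics, friction = 1/coupling-time, defaults
dt = 0.0005, coupling time 1.0, T = 0.5, unit masses, Maxwell-Boltzmann
initial velocities. BAOAB was chosen for its configurational accuracy at
finite dt. Runs are bit-reproducible for a fixed seed: the integration loop
is compiled, but each chunk's Gaussian noise is pre-drawn from a numpy
PCG64 stream, so chunking does not affect the trajectory and a checkpoint
(coordinates, velocities, generator state) continues bit-identically. A
frictionless velocity-Verlet mode exists purely for conservation tests.
Replica protocols initialize round-robin across the three native states.

## Analysis

* **State-specific Q**: fraction of one state's specific contacts with
  r < 1.2 r0 (the standard formation criterion; configurable). Traditional
  all-contact Q cannot separate the native basins because core contacts
  never break during functional motion.
* **Basins**: rectangular regions in Q space, calibrated per system from
  the free-energy-surface minima (defaults Q_X > 0.7 with ceilings on the
  others; the bundled toy calibration uses (Q_A, Q_H) boxes). Frames outside
  every region are unassigned and attributed to the preceding visit (a
  "discard" alternative exists); visits shorter than the dwell filter
  (default 50 output frames) are merged away to suppress recrossing noise.
* **Kinetics**: direct counts N_XY over the visit sequence, sequential
  O→A→H path counts, F_IF = N_OH/(N_OH+N_OAH), rates
  k_XY = N_XY/(P_X·T_total). Replica statistics are pooled by summing
  counts and residence before forming ratios.
* **FES**: F = −T ln(counts/total) on a 2-D histogram, min-shifted, empty
  bins masked. Minima are strict 8-neighbourhood minima; the saddle between
  two minima is the merge point of their basins in a union-find sweep of
  bins by increasing F — exactly the highest bin of the minimax path, with
  row-major tie-breaking.
* **TS ensembles**: frames within ±0.05 (per axis) of a saddle; the window
  doubles (twice at most, with a warning) if fewer than 200 frames qualify.
* **φ-values**: per residue, thermal mean formed-native-contact numbers
  ⟨n⟩ in the start/end/TS ensembles; φ = (⟨n⟩_TS−⟨n⟩_start)/(⟨n⟩_end−⟨n⟩_start),
  residues with |Δn| < 0.5 contacts excluded as insensitive, φ outside [0,1]
  flagged as backtracking. Forcing TS := end (start) gives exactly 1 (0).
* **Cracking**: per residue, mean local bonded energy (angle+dihedral terms
  centred on it, shared equally among their residues) in the TS ensemble
  minus the larger of the two end-basin values; above 1 k_BT flags a
  cracking site. This local-strain definition is this package's own,
  documented stand-in for strain-relief-by-local-unfolding scores.
* **Heat capacity**: direct fluctuation formula per run, or standard
  iterative WHAM over energy histograms (tolerance 1e-7 on the free-energy
  shifts) onto a fine T grid; melting temperature = argmax Cv. WHAM refuses
  non-overlapping histograms, naming the gap.

## Synthetic fixture

The generator builds a 40-residue miniature of a two-domain binding
protein: two compact helical coils (radius 4.5 Å, rise 0.7 Å/res, turn
50°/res) joined by a 4-glycine hinge, four charged residues (K5, E9, E27,
K31), sparse heavy-atom decoration (backbone N/C/O plus short side chains).
The three conformers are rigid motions of the block C-terminal of the
mid-hinge pivot (residue 21): closure angles (0°, 36°, 68°) about the hinge
x-axis with twists (−30°, 20°, −70°) about the domain-2 axis; an optional
azimuth of the closure axis emulates a mixed closure/twist hinge mode.
These values were chosen once so that, after classification, every contact
class is populated and the closed conformers are clash-free; a pseudo-ligand
(4 atoms) sits between the domain surfaces in the H conformer. Conformers
share all bond lengths exactly, so only hinge-driven geometry differs.

What the toy reproduces: a ligand-controllable triple-basin landscape —
holo-basin occupancy rises monotonically with ε_L and the open/apo basins
empty at saturation — with the apo-closed state a genuinely minor species.
What it does not: the toy's open state has almost no inter-domain interface,
so its specific-contact class is minimal (Q_O is nearly binary and the open
basin is identified by low Q_A/Q_H); the apo-closed basin is shallow enough
that, at the default hinge rigidity, activation flux is essentially all
induced-fit (F_IF ≈ 1) — the machinery for population-shift statistics is
therefore exercised against exact Gillespie fixtures rather than the toy's
thermal noise. Melting thermodynamics of the toy are too slow/hysteretic to
resolve the ligand-stabilization shift at desk scale; the WHAM/Cv machinery
is validated against closed-form oracles (Gamma-distributed harmonic
energies, two-level Schottky peak) instead. Passing toy tests demonstrates
the correctness of the machinery, not quantitative agreement with any real
protein.

Basin calibration for the toy (from long-run FES minima): O = {Q_A < 0.30,
Q_H < 0.30}, A = {Q_A ≥ 0.55, Q_H < 0.50}, H = {Q_H ≥ 0.60}; dwell filter 5
frames at stride 500 for the sweep protocol (visits shorter than 2500 steps
are treated as recrossing noise).

## Validation experiment sizes

The bundled experiments are sized for minutes on one CPU: 100 random
configurations for the force check (central differences, h = 2×10⁻⁶ Å);
10⁵ NVE steps; 2×10⁶ Langevin steps for the dimer statistics (KS test on
~9000 decorrelated bond lengths); 1000 random visit sequences and a
~1.5×10⁴-event Gillespie run for the kinetics oracles; 200 overdamped
walkers × 3×10⁴ steps for the double-well FES; and 3 replicas × 1.2×10⁶
steps per ε_L ∈ {0, 0.5, 1.0, 1.5} for the ligand sweep, each replica's
first third discarded as burn-in.

## Known limitations

* No explicit ligand particle: binding is a contact-strength proxy, so
  ligands that engage only one domain are outside the model's scope.
* Absolute time scales are not physical; only rate ratios are meaningful.
* The PAIR_SHARED treatment (shared strength, averaged r0) and the
  `theta_OAH` flattening rule are documented package choices where the
  field's conventions genuinely vary.
* Single chain only; no disulfides, no nucleic acids, no solvent.
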