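# Methods

## The model

The package implements a dual-basin, all-atom structure-based (Gō) model.
A reference structure defines every bonded equilibrium value (bond lengths,
angles, improper/planar dihedral values, proper dihedral phases) and the
native-contact list, so the reference is the exact minimum of the bonded
terms: at the reference coordinates every bonded component evaluates to zero
and its gradient vanishes, which the tests assert to machine precision.

Two contact flavors are supported.

* **6–12 flavor** (`v1_6-12`): each native pair contributes
  ε_C w [(σ/r)¹² − 2(σ/r)⁶], minimum −ε_C w at r = σ.
* **Gaussian flavor** (`v2_gaussian`): each contact term is replaced by a
  single excluded-volume-plus-Gaussian well,
  ε_C w [(σ_NC/r)¹² − (1 + (σ_NC/σ)¹²) exp(−(r−σ)²/2g²)].
  The amplitude is chosen so the energy at r = σ equals exactly −ε_C w,
  matching the 6–12 depth; the width g defaults to 0.5 Å and is
  configurable per contact.  The published description of this flavor names
  only "a single Gaussian term", so this standard Gaussian-contact
  construction is a design choice of the package.

Term strengths follow the published constants: ε_r = 50, ε_θ = 40,
ε_χi = 10, ε_χp = 40, ε_NC = 0.1 ε₀, σ_NC = 2.5 Å.  The proper-dihedral
strengths ε_BB and ε_SC are not given numerically in the main text of the
source protocol; the package defaults to ε_BB = 1.0 and ε_SC = 0.5 ε₀
(backbone-dominant stiffness), both configurable per call.  Native contacts
are heavy-atom pairs within 4.5 Å, excluding pairs that share a bonded term
and pairs within one residue; no shadow/occlusion filter is applied beyond
the distance cutoff, since the protocol states only the cutoff.

**Dual-basin merge rule.** Pairs native only in the starting (A/T) map keep
weight 1; pairs native only in the target (A/A) map receive the titration
weight (0.13 for the 6–12 flavor, 0.4 for the Gaussian flavor in the
accommodation study); pairs native in both keep the A/T geometry at weight 1.
The rationale for the conflict rule is that the simulation starts in A/T
and only the A/A contacts are meant to be down-weighted.

## Dynamics

Reduced units throughout: ε₀ = k_B = m = 1, lengths in Å, time in τ_ru
(≈ 1 ns).  The thermostat is Langevin with BAOAB splitting; velocity
initialization is Maxwell–Boltzmann from the run's seed, and the friction
default is 1 τ_ru⁻¹ (the original GROMACS coupling is unspecified;
Langevin is the standard choice for structure-based models).  The NVE
integrator is plain velocity Verlet and serves as the correctness harness:
second-order energy drift (measured to scale as dt²) below
1e-4 ε₀ per degree of freedom over 1e5 steps at dt = 0.002.  All pairwise
terms are evaluated over explicit pair lists without cutoffs — exact at the
toy scale this package is tested at.  Runs are bitwise reproducible for a
fixed seed.

Event rules: an accommodation event opens when the probe distance
(R_elbow) first drops below 32.5 Å and closes above a release threshold of
35 Å — the hysteresis avoids double-counting boundary jitter, which the
bare threshold rule leaves ambiguous.  Dissociation is flagged when the
probe stays above 60 Å (beyond the ~57 Å A/T value) for 10 consecutive
recorded frames before any accommodation; the source protocol never
quantifies its dissociation criterion, so these defaults are package
choices, both configurable.

## The synthetic two-state system

The toy emulates the geometry of the accommodation corridor at ~30 atoms:

* a rigid scaffold (braced by a bond network; ≥ 12 beads) carrying an
  8-bead zig-zag arm on a free hinge;
* state A (arm raised) and state B (arm rotated 90° into a 10-bead
  pocket), with a probe pair whose distance is 57 Å in A and 32 Å in B,
  mirroring the endpoint values of the accommodation coordinate;
* one cradle contact holds state A (a shallow starting basin), the pocket
  contacts define state B, so the two endpoint contact maps are distinct;
* an optional 3-bead gate column sits on the rotation path: the
  straight-line interpolation between the endpoints clashes with it
  (< 2.5 Å), and in-plane crossing is sterically blocked;
* a permanent 3-bead wall closes the backward rotation path in *both*
  variants, so the corridor between the endpoints is the only route and
  the gate/no-gate comparison isolates the gate;
* weak "planarizer" angle terms tie every arm bead to two beads on the
  hinge's y-axis at 90°.  These are invariant under in-plane rotation of
  the arm — they bias neither basin — but confine the transition path to
  the plane where the gate sits.  Junction terms in which the anchor
  appears only as an end atom (e.g. the anchor–a1–a2 angle) are likewise
  rotation-invariant and are kept to make the arm a semi-rigid rod; terms
  coupling the arm direction to the scaffold frame are omitted, so the
  hinge itself is free.

Beads are single-atom residues (element C) at 4 Å spacing.  The seed
jitters scaffold bead positions by ±0.15 Å per axis, which breaks exact
collinearity in the braced frame and makes distinct fixtures for distinct
seeds; generators are pure functions of their parameters and seed.

What the toy does *not* emulate: sequence-realistic tRNA geometry, solvent,
ions, electrostatics, the factor's conformational change, or the
~150 000-atom scale of a real 80S complex.  Passing tests on the toy
demonstrate that the potential, integrators, event logic and statistics are
implemented correctly and that the dual-basin construction behaves as
designed; they do not validate biological conclusions about ribosomes.

## Measurement protocols on the toy

**Basin-B occupancy titration.**  Occupancy of the seated basin is the mean
formed fraction of A/A-basin contacts (a contact counts as formed below
1.3 σ — the standard native-contact Q statistic).  The ensemble is sampled
at the titration balance point (weight 0.13) with four replicas of 4×10⁶
steps started alternately from the two endpoints, so the estimate does not
hinge on rare spontaneous crossings; occupancies at the other weights
follow by exponential (free-energy-perturbation) reweighting, which is
exact here because the A/A contact energy is strictly linear in the weight.
Replica friction is 0.2 τ_ru⁻¹: equilibrium averages are
friction-independent, and the lower drag decorrelates the slow
rigid-rotation mode of the arm.  Run lengths and replica counts were chosen
to resolve the titration on a single CPU in minutes.

**Gate kinetics.**  Mean first-passage time from state A to the first
crossing of the 32.5 Å accommodation rule, 20 replicas with paired seeds,
gate versus no-gate, at the Gaussian-flavor seating weight 0.4.  Runs are
capped at 1.2×10⁶ steps; a capped run is counted at the cap, which is a
lower bound on its true first passage and therefore only makes the
gate-slows-passage comparison conservative (with the gate most replicas
exceed the cap; without it most arrive well before).

## Statistics

* **Landscapes.**  ΔG* = −k_BT ln(P/P_max)² on a 2-D histogram, reported in
  k_BT (the 300 K temperature only matters for conversion to absolute
  units); the squared ratio is implemented exactly as printed in the source
  protocol, with a `exponent=1` switch since the square may be
  typographic.  Empty bins are masked; the occupied minimum is exactly 0;
  the surface is invariant to rescaling counts.
* **Conv(t).**  Pointwise RMSD between the landscape at time t and at the
  first checkpoint, over bins occupied at both checkpoints (empty bins
  carry no estimate and are excluded rather than generating infinities).
  All checkpoints share one grid spanning the full data range.
* **Gaussian fits.**  Nonlinear least squares of
  A exp(−(x−x̄)²/2s²) on binned counts, with parameter covariance and an
  R² diagnostic; R² < 0.9 flags non-Gaussian (e.g. bimodal) input instead
  of silently returning a single-Gaussian summary.
* **Barrier estimates.**  ΔG‡ = k_BT ln(MFPT/τ_attempt) with the attempt
  time fixed at 1 τ_ru; barrier *differences* between systems therefore
  equal the log of their MFPT ratio, independent of any external input.
  An experimentally determined reference rate (always user-supplied) is
  used only to report the implied real-seconds-per-τ_ru calibration.
  Uncertainty is a seeded bootstrap over events (2.5/97.5 percentiles),
  degenerate (and flagged) for a single event.
* **Conservation.**  Percent identity per reference-numbered alignment
  column; gaps count as mismatches but are not listed among alternative
  residues; positions index the non-gap residues of the reference sequence,
  matching the residue-number convention of published conservation tables.

## Numerical choices and degenerate inputs

Angle forces guard sin θ ≥ 1e-8; dihedrals with collinear triples in the
reference are skipped with a warning (they carry no defined phase) and
contribute no force when a triple degenerates during a run.  Overlapping
atoms (r = 0) raise a singularity error before any 1/r evaluation.  The
integrator aborts with the offending step number if |V| exceeds a
configurable bound (default 1e8 ε₀).  PDB altloc handling keeps the
highest-occupancy conformer (ties: first encountered).  GRO files store no
chain identifiers, so on reading a chain break is opened wherever residue
numbering restarts.  Å↔nm conversion is exactly ×10/÷10.

## Limitations

The desk-scale tests cannot reproduce the production-scale observables of
real ribosome simulations (event counts over thousands of accommodation
events, landscape positions of intermediate states, SASA magnitudes of a
full tRNA); those require the deposited endpoint models and cluster-length
runs, which this package supports as configuration through the same
`build-topology` → `simulate` → `analyze` path but does not test.  The
Gaussian contact form and the barrier-rate mapping are standard
constructions chosen where the published description is incomplete; both
are isolated behind single functions (`gaussianize_contacts`,
`estimate_barrier`) and configurable.
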