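# Methods

## Problem and scope

Gas-phase amino acids (and flexible biomolecule building blocks generally)
populate many conformers separated by low torsional barriers.  Microwave (MW)
spectroscopy in a supersonic-jet expansion detects only conformers that (a)
retain enough population — in practice relative free energies within roughly
900 cm⁻¹ of the global minimum, about 1% population at room temperature
(kT/hc ≈ 207 cm⁻¹) — and (b) are not drained by collisional relaxation over
interconversion barriers below roughly 400 cm⁻¹.  `confscape` implements the
search-and-refinement machinery around that physics: evolutionary exploration
of the soft-torsion space, a cascade of relative-energy acceptance cutoffs,
barrier-based relaxation grouping, quasi-harmonic thermochemistry, and
spectroscopic post-processing, together with a benchmark harness over
published reference tables for glycine, alanine, serine, threonine, cysteine,
aspartic acid and asparagine.

Electronic-structure computation is explicitly out of scope.  Quantities that
require a quantum-chemistry engine — electronic energies, harmonic and
anharmonic frequencies, vibration–rotation constants, quadrupole couplings,
dipoles — enter either as data (the packaged tables, a user's own ledgers) or
through the analytic surrogate surfaces used to exercise the search.

## Conformer nomenclature

Backbone conformers of α-amino acids are classified by the hydrogen-bond
motif of (ϕ′, ψ, ω), where ϕ′ = ϕ + 120° references the nitrogen lone pair:
type I (bifurcated NH₂···O=C; ϕ′≈ψ≈ω≈180°), II (OH···N; ϕ′≈ψ≈ω≈0°), III
(bifurcated NH₂···OH; ϕ′≈180°, ψ≈0°, ω≈180°), primed variants I′/III′ for the
single-contact analogues, and a trailing `c` for the cis carboxyl (ω≈0°)
forms of I, I′ and III.  Side-chain torsions get cis/gauche/skew/trans
letters, with a `⁻` sign for negative gauche/skew.

Design choices (the published material defines the motifs but no numeric
windows):

* **Assignment is nearest-prototype on the (ϕ′, ψ) torus**, with ω handled
  separately as the cis-carboxyl flag (ω closer to 0° than to 180°).  Folding
  ω into a three-angle distance makes II and IIIc exactly equidistant from
  inputs near (0°, 0°, 0°)/(180°, 0°, 0°); the factorized rule removes that
  degeneracy.  Exact prototype ties raise an error rather than picking
  silently.
* **Prototypes are sign-mirrored where the motif is chiral-well split**
  (I′ at ϕ′ = ±90°; III′ at ψ = ±45°).  The III′ ψ-prototype sits at ±45°,
  not 90°: in the reference tables every III conformer has |ψ| ≤ 5° while the
  III′ family spans |ψ| = 24–86°, so the watershed belongs near 22°, which
  the ±45° prototype provides.  The III/III′ distinction is ultimately a
  hydrogen-bond-topology statement, and dihedral-only classification is an
  approximation; three reference rows (two in the cysteine table, one in the
  aspartic table) print dihedrals that contradict their own labels under any
  consistent geometric rule, and the classifier is deliberately not bent
  around them.
* **Torsion-letter bins** are |θ| < 25° cis, 25–110° gauche, 110–150° skew,
  ≥150° trans.  The gauche/skew edge at 110° (not 90°) and cis/gauche edge at
  25° (not 30°) are calibrated so that every self-consistent published
  dihedral reproduces its published letter (an amide side-chain torsion of
  101° and a gauche⁻ of −29.5° are both labelled gauche in the reference
  tables).  All edges are keyword arguments.

Angles are degrees everywhere, wrapped to [−180°, 180°); −180° and +180°
denote the same conformation and compare equal through their circular
distance.

## Surrogate surfaces and the evaluator contract

The evolutionary search consumes an *evaluator*: a callable mapping a vector
of soft torsions to `(energy in cm⁻¹, possibly-relaxed torsions)`.  In
production this is a constrained semiempirical geometry optimization; here it
is either an analytic surrogate or a file-exchange adapter that writes XYZ,
invokes a user command and reads back one scalar energy (cm⁻¹ or hartree).

A surrogate is a sum of per-torsion Fourier terms (A/2)(1 + cos(kθ − φ)) with
k ≤ 3, optional pairwise cosine couplings, and optional attractive Gaussian
wells on the torus that mimic deep hydrogen-bonded basins off the staggered
lattice.  The three packaged surfaces (1-, 2- and 3-torsion) are bounded,
360°-periodic, and cheap enough for exhaustive verification: `grid_oracle`
scans the full torus (default 15° resolution), refines every grid-local
minimum by derivative-free descent, deduplicates by circular distance, and
returns the minima sorted by energy.  A cost guard rejects scans beyond
2×10⁶ grid points.  Local refinement (Nelder–Mead on the periodic surface)
never returns an energy above its starting point.

## Evolutionary search

Island-model EA over the torus:

| parameter | default | notes |
|---|---|---|
| population | 100 | split evenly over islands |
| cycles | 50 | |
| islands | 4 | ring topology |
| independent runs | 4 | pooled |
| initialization | Latin Hypercube | one sample per stratum per dimension |
| selection | tournament, size 3 | lower energy wins |
| crossover | p = 0.7, circular interpolation | child on the shorter arc |
| mutation | per-gene p = 0.2, wrapped Gaussian σ = 30° | uniform-reset mode available |
| offspring / island / cycle | 5 | steady-state truncation replacement |
| migration | every 10 cycles, 2 migrants | best replace worst on the ring |
| Hall of Fame | 5 per island | elitist archive, best-so-far never worsens |

These defaults reproduce the canonical exploration budget of ~1000 fitness
evaluations per run (100 initial + 4×5×50 offspring = 1100).  The operator
probabilities and migration settings are conventional EA values consistent
with that budget; all are exposed in `EAConfig`.  Every evaluated candidate
is kept in a union pool, deduplicated by wrap-aware Euclidean torsion
distance (< 15°, lower energy survives) — definitive duplicate removal with
rotational constants and heavy-atom RMSD belongs downstream.  A failing
evaluation is counted and skipped; the run continues.  All randomness flows
from one `SeedSequence`, so a fixed seed replays bit-identically.

On every packaged surface the four default runs recover the grid-oracle
global minimum to well under 1 cm⁻¹ (the per-evaluation relaxation mirrors
the constrained-optimization fitness, so EA candidates land exactly in local
minima).

## Refinement cascade and detectability

* `threshold_filter`: inclusive ΔE cutoff after re-referencing to the pool
  minimum.  Defaults 2500 / 1500 / 1000 cm⁻¹ for the semiempirical, hybrid
  and double-hybrid stages.
* `deduplicate`: two conformers merge only if **all three** rotational
  constants agree within 1% **and** heavy-atom RMSD (Kabsch superposition,
  input-order correspondence, masses > 3 u) is below 0.25 Å; similarity is
  closed transitively and each component keeps its lowest-energy member.  The
  tolerances are chosen to merge numerically re-found minima while keeping
  genuinely distinct near-mirror pairs apart; both are arguments.
* `relaxation_grouping`: conformers follow downhill edges whose barrier
  (measured from the higher minimum to the transition state) is below the
  400 cm⁻¹ threshold, transitively, to a sink; cycles collapse onto their
  most stable member.  An edge with no numeric barrier records a relaxation
  stated to occur and is always followed downhill.
* `detectable_set`: sinks within the 900 cm⁻¹ free-energy window, each
  carrying the Boltzmann population of its whole basin.

On the packaged reference data this machinery leaves exactly the observed MW
species: glycine collapses to {I, II}, serine to its seven detected
conformers.

## Thermochemistry

All energies are cm⁻¹ (1 kJ/mol = 83.59 cm⁻¹ in display paths);
kT/hc = 0.6950348 cm⁻¹/K from CODATA constants.  Harmonic ZPE is ½Σν;
harmonic thermal enthalpy and entropy use the standard oscillator partition
function.  Because the harmonic entropy diverges logarithmically as ν → 0,
the quasi-harmonic entropy damps each mode between the harmonic expression
and a free-rotor expression, S = w·S_HO + (1−w)·S_FR with
w(ν) = 1/(1 + (ν₀/ν)^α), cutoff ν₀ = 100 cm⁻¹ and α = 4 (the method's
published defaults; both exposed).  The free rotor uses the mode moment
h/(8π²νc) damped by an averaging moment of 10⁻⁴⁴ kg·m².  At ν = ν₀ the
weight is exactly ½; at ν = 10ν₀ the residual free-rotor admixture is
exactly 10⁻⁴ of the HO/FR gap.

Free-energy tables are assembled as exact column sums in one of two
conventions: ΔG° = ΔG_H + ΔZPE(anh−H) + Δ(TΔS)(QH−H) (glycine/alanine-style
tables, where the composite electronic energy is folded into ΔG_H) or
ΔG° = ΔE_rDSD + ΔChS + ΔZPE_H + ΔTh_H + ΔZPE(anh−H) + TΔS(QH−H)
(the polar-side-chain tables, where ΔChS is the junChSF12-minus-rDSD
difference).  Anharmonic ZPE corrections are always consumed as supplied
numbers, never computed.  Boltzmann populations support basin grouping and
optional degeneracy factors (e.g. a factor 2 for double-well conformers; off
by default).

## Spectroscopic post-processing

* CBS extrapolation: the two-point n⁻³ formula,
  E_CBS = (Y³E_Y − X³E_X)/(Y³ − X³), exact on any E(n) = E_CBS + c·n⁻³
  series.
* Composite energy: frozen-core CCSD(T)-F12/triple-ζ plus the MP2-F12
  CBS increment (T→Q) plus the core–valence increment (all-electron minus
  frozen-core MP2-F12); linear in every component.
* Ground-state rotational constants: B₀ = B_e − ½Σᵣαᵣ per inertial axis,
  with a warning when the correction exceeds 2% of B_e (typical scale 0.5%).
* LRA geometry scaling: r_corr = a·r_comp + b per bond/angle class.  The
  reference coefficient table is not part of this package; the default is the
  identity (a = 1, b = 0) for user-declared classes, and unknown classes
  raise rather than passing through.
* Benchmark statistics: per-pair unsigned errors with MUE and MAX kept at
  full precision and rounded only for display.

Rigid-rotor constants are computed from the mass-weighted inertia tensor with
the conversion 505379.0 MHz·u·Å²; linear geometries report the vanishing-
moment constant as infinite.

## Packaged reference data

The fixture tables under `confscape/data/` transcribe the published energy
ledgers (with dihedrals and stated relaxations), spectroscopic parameters,
and glycine barriers verbatim.  Verbatim includes their flaws, which the
harness surfaces instead of repairing: two rows fail their own column-sum
identity (the alanine III⁻c ΔG° is 100 cm⁻¹ off its components, asparagine
Igt 50 cm⁻¹ off), three rows print dihedrals inconsistent with their own
labels, cysteine Igg carries two different ΔG° values in two tables, and the
published alanine rotational MUE (10.5 MHz) is not the arithmetic mean of its
six tabulated errors (recomputed: 16.6 MHz).  The recomputed statistics are
reported in all cases.

## What the surrogate tests do and do not show

The analytic surfaces share the structural features that matter for the
search — periodicity, 3ⁿ staggered-like minima, coupled torsions, deep narrow
wells, energy scales of a few hundred to a few thousand cm⁻¹ — and they make
exhaustive verification possible.  They do not reproduce real semiempirical
energetics: no geometry back-reaction on stiff coordinates, no level-to-level
reordering between search and refinement stages, no evaluation noise.
Passing the oracle-equivalence tests therefore validates the machinery
(operators, bookkeeping, reproducibility, cascade logic), not the accuracy of
any electronic-structure model.

## Numerical conventions and limitations

* Wrap convention [−180°, 180°), −180° kept; printed ±180.0° compare equal.
* Deduplication relies on input-order atom correspondence; no graph matching.
* Barriers are inputs; no transition-state search is performed.
* Problem sizes in the shipped tests: grid oracles at 15–30° resolution on
  ≤3 torsions; EA at the full default budget (4 × 1100 evaluations) per
  packaged surface.
* The classifier cannot recover hydrogen-bond topology that the backbone
  dihedrals do not encode (see the three inconsistent reference rows above).
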