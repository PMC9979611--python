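# confscape

Conformational landscapes of flexible molecules in the gas phase: an
island-model evolutionary search over soft torsions, a threshold-cascade
refinement pipeline, quasi-harmonic thermochemistry, and rotational-
spectroscopy post-processing — validated against published benchmark tables
for seven natural α-amino acids (glycine, alanine, serine, threonine,
cysteine, aspartic acid, asparagine).

## Who this is for

Rotational spectroscopists and computational chemists who need to predict
*which* conformers of a flexible molecule survive a supersonic-jet expansion
and are detectable by microwave spectroscopy, and to post-process
quantum-chemistry output (relative energies, frequencies, vibration–rotation
constants) into free energies, populations and ground-state rotational
constants.  The expensive electronic-structure steps live outside the
package; `confscape` supplies everything around them, plus analytic
surrogate surfaces so the whole machinery is testable without a
quantum-chemistry engine.

## The science in brief

* **Search.** Conformers of a molecule with *n* soft torsions live on an
  *n*-torus.  A knowledge-based pass enumerates the 3ⁿ staggered guesses; an
  island-model evolutionary algorithm (Latin-Hypercube initialization,
  tournament selection, circular-arc crossover, wrapped-Gaussian mutation,
  ring migration, elitist Hall of Fame; ~1000 energy evaluations per run,
  4 runs) finds the rest.  A brute-force torus-grid oracle verifies that the
  search recovers every low-lying minimum of the packaged test surfaces.
* **Refinement.** Candidates pass cutoffs of 2500 / 1500 / 1000 cm⁻¹ on
  successively more accurate relative energies, duplicates merge only when
  all three rotational constants (within 1%) *and* heavy-atom RMSD
  (< 0.25 Å) agree, and conformers behind interconversion barriers below
  ~400 cm⁻¹ relax onto their more stable neighbours.  Sinks within
  ~900 cm⁻¹ of the global minimum (≈1% population at room temperature,
  where kT/hc ≈ 207 cm⁻¹) are the detectable set.
* **Thermochemistry.** ΔG° is assembled as the exact column sum of a
  composite electronic energy, harmonic ZPE and thermal terms, a VPT2
  anharmonic-ZPE correction, and a quasi-harmonic entropy correction
  (free-rotor damping below a 100 cm⁻¹ cutoff, S = w·S_HO + (1−w)·S_FR with
  w = 1/(1+(ν₀/ν)⁴)).
* **Spectroscopy.** Ground-state rotational constants B₀ = B_e − ½Σαᵣ,
  two-point n⁻³ CBS extrapolation, composite CCSD(T)-F12 + CBS + CV energy
  assembly, linear-regression (a·r + b) geometry corrections, and MUE/MAX
  benchmark statistics against experiment.
* **Nomenclature.** Backbone types I/II/III (primed and cis-carboxyl
  variants) assigned by nearest prototype on the (ϕ′, ψ) torus, plus
  c/g/s/t letters for side-chain torsions — round-tripping the published
  conformer labels from their printed dihedrals.

See `docs/methods.md` for the full model description, parameter tables and
design rationale.

## Worked example

Benchmark the packaged glycine tables (experiment vs computation, and
method-vs-method relative energies):

```
$ confscape benchmark --molecule glycine
exp-vs-calc rotational: n=6 MUE=13.65 MHz MAX=30.18 MHz
exp-vs-calc quadrupole: n=6 MUE=0.13 MHz MAX=0.23 MHz
exp-vs-calc dipole: n=6 MUE=0.05 D MAX=0.10 D
method junChSF12_vs_best: junChSF12 vs best: n=7 MUE=6.24 cm-1 MAX=12.70 cm-1
method rDSD_vs_best: rDSD vs best: n=7 MUE=15.14 cm-1 MAX=28.80 cm-1
```

The computed rotational constants of the two detected glycine conformers
agree with experiment to 13.65 MHz on average (worst case 30.18 MHz), and
the composite relative energies sit within 6.24 cm⁻¹ of the best available
reference values.

Free energies, relaxation and detectability for the same molecule:

```
$ confscape thermo --molecule glycine
conformer  dG_cm1  sink  population
I           0.0    I     0.7172
II*       400.9    II*   0.1036
I'*       419.9    I     0.0945
III       461.6    I     0.0773
III'*     962.0    III'* 0.0069
Ic       1641.1    Ic    0.0003
IIIc     2001.3    IIIc  0.0000
I'c*     2021.3    Ic    0.0000
detectable: I (88.9%), II* (10.4%)
```

Conformers III and I′ drain into I over barriers of ~250 and ~70 cm⁻¹, III′
falls outside the 900 cm⁻¹ detectability window, and the jet-cooled spectrum
is predicted to show exactly the two species (I and II) that experiments
observe, with I carrying ~89% of the population.

Library use follows the same shape:

```python
from confscape import EAConfig, SurrogateEvaluator, packaged_surrogates, run_imea

spec = packaged_surrogates()["amino_3d"]
result = run_imea(EAConfig(rng_seed=1), SurrogateEvaluator(spec, relax=True), 3)
print(result.pool[0].torsions, result.pool[0].fitness)  # global minimum
```

## Layout

```
src/confscape/
  geom.py       internal coordinates, dihedral arithmetic, nomenclature,
                rigid-rotor constants, Kabsch RMSD, Z-matrix/XYZ I/O
  surrogate.py  analytic torsional surfaces, grid oracle, engine adapter
  explorer.py   island-model evolutionary algorithm
  refine.py     threshold cascade, deduplication, relaxation, detectability
  thermo.py     HO/QH thermochemistry, ΔG assembly, Boltzmann populations
  spectro.py    CBS/composite energies, B0 corrections, LRA, error stats
  hbond.py      additive hydrogen-bond strength model
  fixtures.py   packaged reference tables + benchmark harness
  pipeline.py   end-to-end orchestration with provenance
  cli.py        `confscape` command-line interface
  data/         reference tables (TSV, transcribed verbatim)
```
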