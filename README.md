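# mixjdp4

NMR-based stereochemical assignment for small organic molecules: DP4,
J-DP4 (dJ, iJ and iJ/dJ variants) and the consensus **mix-J-DP4** method,
computed from molecular-mechanics conformer ensembles.

## The problem

Assigning the relative configuration of a natural product with *n*
stereocenters means choosing among 2^(n−1) diastereomers using NMR data
alone. The DP4 family of methods does this probabilistically: predicted
chemical shifts (and coupling constants) for every candidate are compared
with experiment, and the errors are scored under a Student-t model.
With a uniform prior, the probability of candidate *k* is

    P(k) = Π_j f((e_jk − μ)/σ; ν)  /  Σ_m Π_j f((e_jm − μ)/σ; ν)

where e_jk are the errors of scaled calculated vs experimental observables
and f is the t density of the channel (¹H δ, ¹³C δ, ³J_HH). The coupling
information can be used **directly** (dJ: an extra probability channel) or
**indirectly** (iJ: conformers whose dihedral angles are inconsistent with
the experimental ³J_HH via a Karplus curve are removed before Boltzmann
averaging), or both (iJ/dJ).

Predicted observables are assembled per candidate from a curated conformer
ensemble: isotropic shieldings are Boltzmann-averaged at 298 K
(σ_x = Σ_i σ_i^x e^(−E_i/RT) / Σ_i e^(−E_i/RT)), referenced against TMS
(δ_u = σ_0 − σ_x) and linearly rescaled against experiment
(δ_s = (δ_u − b)/m with m, b from the OLS fit of δ_u on δ_exp).

Because these probabilities are sensitive to the force field used for the
conformational search — different force fields populate the conformational
landscape differently and perturb the computed shieldings — **mix-J-DP4**
runs the iJ/dJ-DP4 pipeline on three independent force-field ensembles
(AMBER, MM3, MMFF by default) and averages the resulting probabilities into
a single consensus. The package also covers the supporting machinery:
energy-window filtering, MAD/RMSD redundancy elimination after Kabsch
superposition, diagnostics (CMAE, MaxErr, MaxΔσ, Boltzmann-weight R²
correlations between force fields), and a fully ground-truthed synthetic
fixture generator.

The package consumes force-field geometries/energies and computed
shieldings/couplings as files (multi-XYZ/SDF/CSV); it does not run
quantum-chemistry or conformational-search engines.

## Worked example

Generate a ground-truthed synthetic bundle and assign it:

```bash
mixjdp4 fixture spec.yaml --out demo      # spec.yaml: "seed: 31"
cd demo && mixjdp4 assign config.yaml --out assignment
```

With a two-candidate bundle (seed 31, wrong candidate inflated by 3σ) the
run prints:

```
INFO mixjdp4: cand1: curation 8 -> 3 conformers
INFO mixjdp4: cand1: iJ filter (dihedral_window) 3 -> 1 conformers
                  H             C         J      combined
candidate
cand1      0.999992  1.000000e+00  0.985025  1.000000e+00
cand2      0.000008  5.932556e-12  0.014975  6.779724e-19
top candidate: cand1
```

Reading: curation trimmed the 8 raw conformers to 3 within the 12 kJ/mol
window after MAD-0.5 Å deduplication; the iJ filter kept the single rotamer
consistent with the experimental ³J_HH; each channel column is the
per-candidate probability from that data type, and `combined` is their
product renormalized — candidate 1 (the generator's true isomer) is
selected at essentially 100%.

Mixing three force fields from the library API:

```python
from mixjdp4 import AssignmentConfig, run_assignment, mix_jdp4, format_report
from mixjdp4.fixtures import FixtureSpec, make_mix_fixture

ffs = make_mix_fixture(FixtureSpec(seed=5))
results = [
    run_assignment(f.ensembles, f.shieldings, f.exp,
                   AssignmentConfig(reference=f.reference), couplings=f.couplings)
    for f in ffs.values()
]
print(format_report(mix_jdp4(results)))
```

```
candidate  AMBER     MM3       MMFF      mix
cand1      >99.9     >99.9     >99.9     >99.9
cand2      <0.1      <0.1      <0.1      <0.1
```

When the force fields disagree — e.g. per-force-field probabilities of
about 0, 1 and 1 for the right isomer — the mix column reports their mean
(66.7%), retaining the two votes in favour instead of letting a single
force field veto the assignment.

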