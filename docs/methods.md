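# Methods

This note records the models implemented in `mixjdp4`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic fixtures
do and do not establish.

## Ensemble curation

A candidate's input is an ordered conformer ensemble from a
molecular-mechanics conformational search, with relative energies in
kJ/mol (hartree accepted only when declared; units are never guessed from
magnitude, because a silent unit error is the worst failure mode of this
kind of plumbing). Energies are re-referenced so the global minimum is 0.

Curation applies an **energy window** then **redundancy elimination**:

* The window is inclusive (rel. energy ≤ cutoff): a conformer exactly at
  the line is kept, since the known failure mode of aggressive trimming is
  losing genuinely populated structures. Default cutoff 12 kJ/mol, with
  21 kJ/mol as the conservative alternative.
* Deduplication is greedy in ascending energy order (ties broken by input
  order for determinism): a conformer is discarded iff its distance to an
  already-retained conformer is below the threshold. The distance is MAD
  (maximum atom deviation, default, threshold 0.5 Å) or RMSD, computed
  after least-squares Kabsch superposition. Since RMSD ≤ MAD for any pair,
  the MAD criterion declares duplicates less often and preserves more
  structural diversity at the same threshold — the reason it is the
  default. The greedy keep-first rule guarantees the global minimum always
  survives and makes the operation idempotent.
* Superposition and the deviation measures use heavy atoms by default
  (configurable to all atoms). Whether the upstream modelling packages
  align structures or include hydrogens in their MAD/RMSD tests is not
  documented anywhere authoritative; best-fit heavy-atom alignment is the
  de facto convention and avoids methyl-rotor false distinctions. Atom
  correspondence is by input ordering only — no symmetry/automorphism
  matching — so topologically symmetric molecules can over-count distinct
  conformers (known limitation).

Boltzmann populations use w_i = e^(−E_i/RT)/Σ_j e^(−E_j/RT) with
R = 8.3145 J/(K·mol) and T = 298 K by default, evaluated with the
max-shift trick so arbitrarily large gaps cannot overflow.

## Shift and coupling assembly

Per candidate: shieldings are population-averaged per nucleus, referenced
(δ_u = σ_0 − σ_x) and rescaled against experiment. The σ_0 values are
level-of-theory dependent and must always be supplied; there is no
default. The regression is OLS of δ_u on δ_exp (experimental shifts on the
abscissa — the opposite orientation gives different scaled values and is
deliberately not offered), run per element channel and per candidate.
Scaled shifts are invariant to any affine distortion of the raw
predictions; this is what makes the resulting errors comparable across
force fields and levels. With fewer than 3 signals the rescale is refused
and the unscaled values pass through with a flag. Computed shifts of
equivalent nuclei (declared as groups in the experimental table) are
averaged before regression: experimental signals, not nuclei, are the unit
of comparison. Optionally, declared diastereotopic signal pairs may be
swapped per candidate to the error-minimizing pairing; this is off unless
requested, since it is a deviation risk.

Couplings enter as Fermi-contact-only computed values, Boltzmann-averaged
and passed through a named linear rescale profile (`jdp4-2019`,
multiplicative 1.0709, marked approximate in its provenance; `identity`
also ships). The constants live in a profile, not in logic, and are
overridable.

Diagnostics: CMAE (mean |δ_s − δ_exp|) and MaxErr per channel; MaxΔσ /
MaxΔδ (max − min across force-field tables per nucleus) quantifies the
geometry sensitivity of the predictions; pairwise R² between force-field
Boltzmann-weight vectors quantifies how differently the force fields
populate a shared conformer set.

## Probability model

Errors are modelled per channel as Student-t with parameters (μ, σ, ν)
shipped as named, cited, overridable profiles — `dp4-2010` carries the
published DP4 shift statistics (¹H: σ = 0.185 ppm, ν = 14.18; ¹³C:
σ = 2.306 ppm, ν = 11.38; μ = 0); `jdp4-2019` adds an approximate coupling
channel (σ = 0.80 Hz, ν = 6). No statistical constant is hardcoded in the
engine. The prior over candidates is uniform (configurable only by an
explicit prior). All likelihood products run in log space with
log-sum-exp normalization, so 200 signals at 10σ neither overflow nor
collapse the vector to all-zero.

The **iJ filter** defaults to dihedral-window mode: each filtering-grade
experimental ³J_HH is inverted through the configured Karplus curve
(`classic`: J(θ) = 7.76 cos²θ − 1.10 cosθ + 1.40 Hz) by bracketed root
finding on a 0.5° grid; a conformer survives iff each filtering dihedral is
within the tolerance of an admissible angle. The tolerance defaults to
±30° — a package decision, echoed loudly in result metadata, because no
authoritative value exists. An experimental J outside the curve's range
falls back to the nearest-approach angle, so slightly-too-large couplings
still define a usable window. A J-match mode (|J_calc − J_exp| ≤ tol per
conformer) is available. If the filter would empty an ensemble it is
released with a warning instead: an empty ensemble indicates filter
misconfiguration, not impossible stereochemistry.

Methods are channel subsets of one pipeline: DP4 = {H, C} without the
filter; dJ-DP4 = {H, C, J}; iJ-DP4 = {H, C} with the filter; iJ/dJ-DP4 =
{H, C, J} with the filter. **mix-J-DP4** is the plain arithmetic mean of
the per-force-field combined probabilities (not a geometric mean and not a
re-normalized likelihood product — averaging is the operation that lets
two succeeding force fields outvote one failing one). Per-channel means
are emitted as supplementary columns only. Saturated values are exact
internally; only the report formatter clamps display to `<0.1`/`>99.9`.

Diastereomer enumeration pins the first-listed stereocenter by default
(2^(n−1) candidates), since chemical-shift data cannot distinguish
enantiomers; a guard (default 20 centers) prevents accidental combinatorial
explosions.

## Synthetic fixtures

The generator fabricates complete inputs with recorded ground truth:

* **Geometry**: a self-avoiding chain (1.5 Å bonds, tetrahedral angles)
  whose reporter dihedral is set to rotamer states (true state 180°, decoys
  at ±60°, ±5° jitter) with Cartesian noise at 0.02 Å — the scale of
  typical inter-force-field geometry differences. Energies are uniform on
  [0, 12] kJ/mol, matching the recommended window.
* **Shieldings** encode true shifts affinely (σ = σ_0 − (mδ + b)) plus
  optional per-conformer offsets, so Boltzmann averaging and rescaling are
  both exercised; decoy conformers can carry extra offsets so that the iJ
  filter has something real to repair.
* **Experimental values** are the true candidate's (consistent-rotamer)
  observables plus Student-t noise from the configured error model; wrong
  candidates' predictions are perturbed by a per-signal random-sign
  location shift in channel-σ units (default 2σ) and/or a scale
  inflation. The random signs matter: a same-sign shift would be absorbed
  by the scaling regression.
* Noise is injected into experimental values by default, which makes the
  true candidate's scaled-error distribution exactly the configured t (the
  property the goodness-of-fit test checks); a switch injects it into
  shieldings instead for geometry-sensitivity studies.

All randomness flows through `numpy.random.default_rng` (PCG64) from a
mandatory integer seed; outputs are bitwise reproducible per seed.

What passing on fixtures shows: the statistical engine is calibrated, the
kernels match independent oracles, and the method ordering
DP4 ≤ dJ ≤ iJ/dJ holds under controlled error injection. What it does not
show: performance on real molecules, where force-field energetics, real
Karplus chemistry, assignment ambiguities and solvent effects dominate.
The fixtures are statistical stand-ins, not physical models, and the
parameter-recovery success rates reported by `scripts/acceptance.py`
(computed at 20 signals per system, 200 replicates, 2σ inflation — sizes
chosen to give stable rates at interactive runtimes) are properties of
those synthetic conditions only.

## Numerical choices

* Probability vectors are normalized exactly after log-sum-exp; every
  emitted vector sums to 1 within 1e-9 (validated at construction).
* Karplus inversion: sign-change bracketing on a 0.5° grid refined by
  Brent's method; angular distances on the circle (period 360°).
* Dihedrals follow the IUPAC sign convention, range (−180°, 180°], with
  collinear triples rejected.
* Greedy dedup ties in energy break by input order; superposition requires
  ≥ 3 non-collinear subset atoms.
* 1 hartree = 2625.499 kJ/mol.

## Known limitations

* No symmetry-aware atom matching in superposition/dedup.
* Only ¹H/¹³C shift channels; other nuclei are rejected.
* The J rescale and J-channel t parameters ship as approximate profiles;
  exact refit values from the original coupling-statistics source should be
  supplied by the user where they matter.
* The quantum-chemistry log reader is a tolerant text scan for GIAO
  isotropic lines; anything unusual should be exported to the CSV
  interchange format instead.
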