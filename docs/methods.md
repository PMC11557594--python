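# Methods

## Scope and data model

qcpost operates strictly downstream of an electronic-structure program: its
substrate is the `QCRecord` summary (orbital energies in eV with explicit
per-orbital occupancies, total energy in hartree, dipole in Debye, harmonic
frequencies in cm⁻¹, optional per-orbital population fractions over named
atom groups). Occupancy is stored, not inferred from an electron count,
because records are often truncated frontier-region summaries. Unit
conventions are fixed per field and conversions are explicit calls —
`hartree_to_ev` uses 27.2114 eV/hartree by default (the precision at which
tabulated literature conversions reproduce; the full CODATA constant can be
passed instead). Records serialize to canonical JSON (fixed key order,
shortest round-trip floats), so `parse ∘ write` is the identity and golden
files are stable. Imaginary modes are encoded as negative wavenumbers and
carried with a warning, never silently dropped — except by `apply_scale`,
which excludes them (with a warning) because scaling an imaginary frequency
is meaningless. Raw log-file parsing is delegated to existing parser
ecosystems; `qcpost.convert.record_from_parsed` documents the attribute
mapping.

## Reactivity descriptors

The cascade is the standard Koopmans-type set: I = −E_HOMO, A = −E_LUMO,
χ = (I+A)/2, µ = −χ, η = (I−A)/2, σ = 1/η, ω = µ²/(2η), ΔE = E_LUMO −
E_HOMO. Identities µ = −χ, ΔE = 2η and σ·η = 1 hold exactly (to 1e-12 for
the division) and are asserted property-style over synthetic records.

ΔN, the fraction of electrons transferred to a metal surface, defaults to
the parameterization used in the corrosion-inhibition literature this
package accompanies: χ_ref = 0, η_ref = 7 eV with a *difference*
denominator, ΔN = (χ_ref − χ)/(2(η_ref − η)). The textbook convention
(χ_ref = 7 eV, η_ref = 0, sum denominator) is available as
`ReferenceMetal.conventional()`; the two conflict in the literature and no
tabulated ΔN values exist in the bundled study to adjudicate, so the choice
is an explicit flag rather than a silent default swap.

### Reproducing 3-dp published tables

Published descriptor tables are printed at 3 decimals and are *internally*
generated from rounded intermediates. Reverse-engineering the bundled
table's half-way cells (µ = −3.2775 printed as −3.277 while η = 3.3325
prints as 3.333, and the analogous CH3/CN cells) shows its convention is
**ties toward +infinity** — not the more common ties-away-from-zero — and
that σ and ω were computed from the already-rounded µ and η (ω for the CHO
variant is 1.611 from rounded inputs but 1.612 at full precision).
`rounded_cascade` implements exactly this: the linear steps run in exact
decimal arithmetic (IEEE floats perturb the ties: the double nearest
−3.2775 is −3.2775000000000003, which any nearest rule rounds to −3.278),
ties round toward +∞, then σ and ω derive from the rounded µ, η. Full
precision is always retained alongside (`descriptor_table` vs
`rounded_descriptor_table`; the CLI writes both files).

`compare_tables` reports every cell where a recomputed table differs from a
reference at the printed scale, with an `exceeds_tol` flag at 0.0015
(half-ulp-ish differences are listed but not flagged). The bundled
reference table has fourteen such cells, enumerated with their recomputed
values in `EXPECTED_DESCRIPTOR_DISCREPANCIES`; eleven are final-digit
rounding slips in the source, three (one structure's ΔE, and the GO σ/ω
pair, whose printed σ = 11.855 implies η ≈ 0.0844 rather than the printed
0.084) are genuine internal inconsistencies. They are documented and
asserted as *non-matching*; nothing auto-passes them.

## Binding energies

`binding_energy` reports the raw difference TE(complex) − Σ TE(fragments),
negative favorable, with no counterpoise correction (none is applicable to
the bundled single-point energies). The bundled study's printed binding
energies carry the opposite sign and a ~0.004 hartree offset relative to
the arithmetic on its own printed total energies; the package reports the
raw difference, bundles the published values separately, and uses the
latter as-is where the analysis (site ranking) is about their order.
Ranking is ascending in BE with a lexicographic site-tag tiebreak so the
ordering is total and reproducible.

## DOS / PDOS

Each orbital contributes a unit-area Gaussian; defaults are fwhm 0.3 eV,
grid step 0.01 eV and padding of 4 fwhm beyond the extreme orbitals —
conventional visual-broadening choices for molecular DOS post-processing
(the broadening used for published DOS figures is generally unstated, and
no numeric DOS values exist to fit, so only property-level verification is
possible: integral = orbital count within 1% at this padding, pointwise
partition of unity of the group projections within 1e-9, translation
invariance). The Fermi reference of a molecular "band structure" is a
convention; the default places 0 eV at midgap, matching plots that show
occupied states below and virtual states above zero, with `mode="homo"` as
the alternative. Group projections are taken from the record's population
rows (a Mulliken-style partition aggregated over atom groups); qcpost does
not compute populations from wavefunctions.

## Vibrational analysis

Band matching is monotone (order-preserving) one-to-one between the two
wavenumber-sorted lists, computed by Needleman–Wunsch-style dynamic
programming with the skip penalty equal to the tolerance; surviving pairs
with residual above the tolerance are dissolved. Monotonicity reflects the
physics (mode order is meaningful) and removes greedy-matching tie
ambiguity; ties in the DP traceback prefer the match for determinism. The
residual between interval bands is 0 on overlap, else nearest-endpoint
distance; interval pairs join the matching but are excluded from MAD/RMSD
by default because endpoint distance is not a like-for-like deviation.
Default tolerances: 100 cm⁻¹ for model-vs-experiment assignment, 50 cm⁻¹
for experiment-vs-experiment differencing (tight enough that a 1640↔1620
C-O shift matches while a genuinely new 1710 cm⁻¹ carboxyl band stays
isolated). Model ranking for the bundled eleven method/basis IR tables is
computed over the seven single-valued bands all columns share, with an
infinite matching tolerance so every model scores the same n = 7; the
tabulated "absent" calculated band (C-O, unreproduced by every harmonic
column) is simply omitted from model lists.

`estimate_scale` is the least-squares slope through the origin,
Σ(calc·exp)/Σ(calc²) — the standard effective-scale-factor estimator when
the applied factor is unreported. It is scale-equivariant and exact on
noiseless data.

## Synthetic generator

`SyntheticSpec` defaults are the study-like conditions the tests exercise:
30 occupied + 30 virtual orbitals in normal clusters (spread 3 eV) centred
one spread outside ±gap/2 and clipped to preserve the requested gap
(clipping was chosen over truncated sampling for verifiability; with these
spreads the extreme orbitals clip to the gap edges with overwhelming
probability, so requested gaps survive the full descriptor pipeline),
symmetric-Dirichlet population rows over three groups renormalized to sum
exactly to 1, a 3-component normal dipole (sd 2 Debye), and 30 frequencies
uniform on 400–3800 cm⁻¹ with exp = 0.9614·calc + N(0, 5 cm⁻¹). What it
does **not** emulate: realistic quantum-chemistry level spacings, mode
degeneracies, intensity information, or correlated (non-additive,
mode-dependent) anharmonic error — so passing tests demonstrate the
estimators' and spectral constructions' correctness under their stated
models, not robustness to systematic structure in real harmonic errors.

## Problem sizes and determinism

The property suites use 100 seeded 16-orbital records for DOS/PDOS checks
and 50 seeds × 30 bands for scale recovery — sizes at which the checked
bounds are already tight (the observed integral error is ~1e-14, partition
error ~1e-15, mean-recovery error ~5e-5). All randomness flows through
explicit `numpy.random.default_rng(seed)` instances; re-running any
pipeline or script with the same seed and inputs is byte-identical.

## Known limitations

- Koopmans-type descriptors inherit all limitations of frontier-orbital
  estimates; the package computes, it does not endorse.
- The published-table reproduction convention (rounded cascade, ties to
  +∞) is inferred from the bundled table's own half-way cells; other
  sources may round differently, which `compare_tables` will surface
  rather than hide.
- Band matching assumes both lists are fundamentals in a common spectral
  window; no peak-picking from raw absorbance traces, no anharmonic
  corrections, no intensity weighting.
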