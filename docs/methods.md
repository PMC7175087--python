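# Methods

## Scope and data model

The package operates on a multiple sequence alignment of the rRNAs to be
depleted, one row per species, in the RNA alphabet (`T` accepted on input and
stored as `U`; IUPAC ambiguity codes are rejected with an error rather than
silently scored as mismatches). All internal coordinates are 0-based,
half-open; exported probe tables use 1-based inclusive coordinates, the
convention of oligo vendors. Columns at which any species has a gap are
inadmissible for probe placement; the admissible columns are kept as maximal
half-open runs ("windows") which partition the admissible set exactly.

Per-column conservation is reported as information content
`ic = 2 − H` bits with `H` the base-2 Shannon entropy of per-species base
frequencies (zero-frequency terms contribute nothing; a fully conserved
column scores exactly 2 bits). Species are counted individually, without
deduplication of identical rows or phylogenetic weighting. The smoothed
track is a centered moving mean over the subsequence of admissible columns
(default window 20 columns; the width is a display choice and is exposed as
a parameter).

## Thermodynamic model

Tm of a probe against one species' rRNA is a nearest-neighbor sum for the
DNA:RNA heteroduplex formed by the antisense DNA oligo and the rRNA:

    Tm(K) = 1000·ΔH / (ΔS + ΔS_salt + R·ln C_eff)

- ΔH, ΔS: duplex initiation (+1.9 kcal/mol, −3.9 cal/mol/K) plus one term
  per dinucleotide stack. Perfect-match stacks come from the Sugimoto (1995)
  RNA/DNA hybrid set; a stack with exactly one mismatched pairing falls back
  to the Allawi–SantaLucia DNA internal-mismatch set, the standard
  approximation when hybrid mismatch parameters are unavailable.
- A stack with **two** mismatched pairings is never parameterized: the Tm of
  any duplex containing sequential mismatches is *undefined* (NaN). The
  three tandem G·T-wobble entries present in some DNA mismatch tables are
  deliberately excluded so this rule is absolute. Terminal mismatches are
  likewise only scored when the internal-mismatch set covers them;
  otherwise undefined (conservative — their thermodynamics are poorly
  approximated by internal parameters). Dangling ends and divalent-cation
  corrections are out of scope.
- Conditions (all configurable; defaults follow the documented defaults of
  the standard nearest-neighbor implementations): probe and target at 25 nM
  (`C_eff = [probe] − [target]/2` = 12.5 nM), 50 mM monovalent salt with the
  SantaLucia-1998 entropic correction `ΔS_salt = 0.368·(N−1)·ln[Na+]`. Tm is
  computed in double precision and reported to 0.01 °C.

Parameter tables are shipped as TSV data files with per-entry provenance
labels. The vectorized engine encodes each (target base, sense base)
pairing as one of 16 states and looks stacks up in a 256-entry array, so a
candidate's full 8-species profile costs a few numpy operations; tests
verify exact (1e-6 °C) agreement with both an independently written
position-by-position summation and the Biopython `MeltingTemp` routine on
perfect-match duplexes.

A probe's score is the **minimum Tm across species**; if any species is
undefined the whole profile is undefined (an oligo is only useful if it
binds *every* target).

## Optimization

- Initialization: `n_init` candidates (500 default; 1000 for the longer,
  more divergent 23S target), lengths uniform on 15–24 nt, placement
  uniform over all feasible (window, start) pairs, sequence drawn per
  column uniformly from the distinct bases present among species.
- Mutation: one operator per mutant, chosen uniformly — move the window
  1–4 columns, shrink 1–4 columns off one end, extend 1–4 columns on one
  end (new columns sequenced by the initialization rule), or swap one
  position to a different species' base. Infeasible proposals (masked
  columns, length outside [12, 45] nt, swap at a fully conserved column)
  are resampled up to 50 times, after which the incumbent is duplicated so
  the pool size stays fixed.
- Selection: each cycle every candidate generates 25 mutants and the
  successor is drawn from mutants **plus the incumbent** — inclusion of the
  parent prevents forced regressions when all mutants are worse. If any
  pool member has a defined profile, only defined members are eligible,
  with probability ∝ N(62.5 °C, 2 °C²) evaluated at their min-Tm (computed
  in log space and normalized); if the entire pool is undefined the parent
  carries over.
- The trajectory records, per cycle, the mean min-Tm over defined
  candidates and the undefined count; record 0 is the initialized
  population so the decline of the undefined count is visible. One seeded
  `numpy` generator drives the whole run; identical (alignment, config,
  seed) gives byte-identical exports, and the seed is written into the
  export header.
- Group-specific designs (e.g. Gram-negative-only 23S ends) and per-species
  5S designs reuse the identical code path on a row subset or a single-row
  alignment.

## Final probe selection and export

The published workflow hand-selected probes; here that step is automated as
a deterministic greedy rule: drop undefined candidates and those whose Tm
does not exceed 50 °C for strictly more than half the species (the
depletion protocol includes a 50 °C incubation); rank the rest by
|min-Tm − 62.5| ascending, breaking ties toward shorter oligos (cost,
off-target risk) and then lower start; accept in rank order subject to
nonoverlap and an optional minimum spacing (default 0 — the only published
constraint is that probes be spread out, which nonoverlap plus
closeness-ranking already encourages). Default set sizes are 8 (16S) and 9
(23S), matching the published common set. Probes are exported as the
reverse-complement DNA of the sense window with a `5Biotin` annotation, as
TSV plus FASTA, and round-trip losslessly through the provided reader.

A vendored catalog file with the published structure (17 common oligos with
mean length 30 nt, 2 Gram-group 23S oligos per group, 2 species-specific 5S
oligos per organism — 21 per organism) supports the accounting functions;
its sequences are synthetic stand-ins (random DNA, fixed seed), as labelled
in the file, so only structural properties are meaningful.

## Stoichiometry

moles(ribosome) = µg input × 10⁻⁶ × rRNA mass fraction / rRNA molar mass.
Defaults: fraction 0.9; molar mass from an E. coli-like rRNA complement
(1542 + 2904 + 120 nt at 321 g/mol per residue ≈ 1.47 × 10⁶ g/mol), or
computed from user-supplied rRNA lengths. Each 16S/23S oligo is dosed at
2.25 × ribosome moles; 5S oligos at 4.5 × (twice the concentration, as 5S
depletion needs the larger excess). The minimum bead volume is
excess × total oligo moles / capacity with capacity 5 × 10⁻¹² mol/µl; the
bead excess default is 2.0 — the need for a significant excess is
established, the exact multiplier is a protocol tuning knob and is exposed
prominently.

## Sequencing QC

- Counting: one count at `floor((start+end)/2)` per read, summed per region
  containing that midpoint (half-open). Strand is ignored. Region sets may
  overlap; a read midpoint can then count toward several regions.
- RPKM = count / (region kb × total mapped / 10⁶).
- Coverage profiles add one count at every position a read covers
  (both ends inclusive); depth is corrected by median-of-ratios size
  factors: per-region geometric mean across samples forms the reference,
  the factor is the median ratio to it (regions with any zero excluded).
- rRNA fraction = Σ rRNA-region counts / total mapped reads.
- Outliers between two samples: least-squares line on (log₁₀x, log₁₀y);
  points whose **perpendicular** distance from the line deviates from the
  mean distance by more than 2 SD are flagged, with the side recording
  which sample depleted them more. The vertical-residual reading of
  "distance from the fit" is available behind a flag; flagging is
  insensitive to the log base. With a degenerate (collinear) input the SD
  is 0 and nothing is flagged.
- Fold-change comparison: regions passing an RPKM floor in both untreated
  samples (default 64; count- or RPKM-floors on all four samples also
  supported) get log₂(treated/untreated) per method; agreement is the
  squared Pearson correlation.

## Synthetic fixtures

The alignment generator draws an ancestral sequence, copies it unchanged
inside configured conserved blocks, and outside them substitutes each
species' base with probability `divergence` (uniform over the three
alternatives) and gaps it with probability `gap_probability`
(single-column gaps only — enough to exercise masking, with no indel length
model or phylogenetic correlation between species). Defaults emulate the
conservation structure the designer faces on real 16S alignments: 8
species, 1500 columns, ten conserved 40-nt blocks, 30% divergence, 5% gaps.
The read generator picks a region class by weight, a region uniformly
within the class, and a start uniformly such that the read fits; it
emulates the composition of depleted/undepleted samples (e.g. 95% rRNA
weight), not fragment-length, GC, or positional biases of real libraries.
Consequently, passing tests demonstrate correctness of the computations and
recovery of planted truth, not performance on real sequencing data.

## Problem sizes and numerical notes

The shipped acceptance computation runs the full default problem (500
candidates × 100 cycles × 25 mutants on a 1500-column, 8-species alignment)
for three replicate seeds — about 10⁷ profile evaluations in a few minutes
on one CPU. Unit and property tests use scaled-down populations (20–100
candidates, 3–15 cycles), which exercise every code path identically.
Selection weights are computed in log space before normalization to avoid
underflow far from the target; Tm arithmetic propagates NaN to mark
undefined profiles. Ties in probe ranking are broken deterministically
(length, then start) so runs are reproducible bit-for-bit.

## Known limitations

- Mismatch thermodynamics borrow DNA-duplex parameters for hybrid stacks;
  single-mismatch Tm values are approximations.
- No secondary-structure screening (hairpins, probe dimers) and no
  off-target screening against mRNA; short probe length is the only
  mitigation.
- The information content and the optimizer treat species as independent
  samples; closely related species effectively double-weight their clade.
- The published probe sequences themselves are not reproducible
  sequence-by-sequence (stochastic search plus hand selection); only
  structural properties of the catalog are checked.
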