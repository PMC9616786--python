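# Methods

## Secondary chemical shifts and helix populations

Observed Hα and Cα shifts are compared with random-coil reference values for
the same residue type; the deviations Δδ_Hα and Δδ_Cα report secondary
structure (helix: Δδ_Hα negative, Δδ_Cα positive).  The bundled reference
table carries the Wishart random-coil Hα/Cα values for the 20 standard amino
acids; any other table can be supplied as a TSV, since random-coil
conventions differ between laboratories.

Classification uses a coil band of ±0.04 ppm (Hα) and ±0.4 ppm (Cα) around
zero.  A residue is scored helical when **either** indicator leaves the band
on the helical side (Δδ_Hα ≤ −0.04 ppm **or** Δδ_Cα ≥ +0.4 ppm, boundary
inclusive).  The OR rule was chosen because natural-abundance ¹³C data are
often sparse: either indicator alone should be able to carry a residue.
Maximal helical runs become segments; up to `max_gap` (default 1) interior
non-helical residues are bridged, so a single missing or noisy assignment
does not split a helix, and runs shorter than `min_segment_length`
(default 3) are discarded — the shorter of the two INF2 helices spans seven
residues, so 3 is a permissive floor.

Helix population is Hα-only, over an explicit inclusive residue range
(default: the called segment's span):

    % helix = 100 × ⟨Δδ_Hα⟩ / (−0.39 ppm)

where −0.39 ppm is the Δδ_Hα of a fully formed helix.  The estimate is
clamped to [0, 100] for reporting, with the raw value retained for
diagnostics, because strong coil or β propensity can push the raw number out
of range.  Measurement error propagates linearly, without √N reduction —
the per-residue errors in a nascent helix are not independent draws to
average away, so the conservative single-shift propagation
`100 × σ_shift / 0.39` is used; ±0.01 ppm maps to ±2.56 %, i.e. ±3 % at the
integer precision the estimate warrants.

Numbering is full-length throughout: a peptide covering residues 2–19 of the
parent protein numbers its residues 2..19, carried by a first-residue offset
on each record.  The NMR-STAR reader deliberately consumes only the assigned
chemical-shift loop and takes each file as self-describing; it never assumes
which deposition holds which peptide or condition.

## CSP mapping

Per-residue perturbations between the free-protein reference spectrum
(ratio 0) and an endpoint ratio (default: the highest present, 1:8 in the
reference design) are

    CSP = sqrt(((Δδ_1H)² + (Δδ_15N/5)²) / 2)

The 1/5 scaling compensates the wider ¹⁵N ppm dispersion, and the 1/2
averages the two squared contributions — the standard pooled convention.
Because compact renderings of this formula are ambiguous about what the 1/2
multiplies, the alternative reading (1/2 on the nitrogen term only) is
selectable via `convention="n_only"` for sensitivity checks; it only rescales
the ¹H contribution by √2 and does not change the residue ranking for pure
¹⁵N shifts.

Significance is inclusive (CSP ≥ threshold, default 0.25 ppm) for
deterministic boundary behaviour.  Residues missing at either endpoint
(prolines, exchange-broadened amides) are omitted with a warning, never
imputed.  The default lobe map — N-lobe 1–77, linker 78–81, C-lobe 82–148 —
follows the canonical calmodulin EF-hand organisation and is overridable,
since lobe boundaries are a convention, not a measurement.

## Steady-state SPR

Double referencing subtracts the reference flow cell and then the buffer
blank (itself reference-subtracted) from each sample sensorgram, with the
reference and blank interpolated onto the sample time grid.  The equilibrium
response is the mean over a window late in the association phase — default
the final 10 s of a 60 s injection, appropriate for interactions that
equilibrate within seconds — with the within-window slope reported as a
plateau diagnostic.

The one-site Langmuir isotherm R_eq = C·R_max/(C + K_D) is fitted by
unweighted nonlinear least squares (`scipy.optimize.curve_fit`), replicates
entering as separate points.  Initialisation is R_max⁰ = 1.2 × max(R_eq) and
K_D⁰ = the concentration whose response is nearest half-maximum, with both
parameters bounded positive; this is robust for both saturating and
non-saturating ladders.  The K_D standard error comes from the fit
covariance.  Kinetic (k_a/k_d) fitting is out of scope: the regime of
interest equilibrates faster than the instrument resolves.  Concentrations
are stored in molar and K_D is reported in µM.

The reference concentration series spans 13.2 nM to 9.6 µM.  Since the
intermediate concentrations are a design choice, the package uses a two-fold
dilution ladder from 13.2 nM with the 9.6 µM endpoint appended (11
concentrations, duplicated), which spans both stated endpoints exactly.

## Motif scanning and conservation

Ca²⁺-dependent CaM-binding motifs are classified by the relative positions
of bulky hydrophobic anchors (W, F, I, L, V).  The scanner implements the
1-4-8 spacing — anchor offsets (0, +3, +7) — as a parameter tuple, so other
spacings are one argument away, but only 1-4-8 is exercised here.
Intermediate positions are unconstrained, because the mutational evidence
for this site constrains only the three anchors; every window is reported,
overlapping hits included.  `X` never matches the anchor class; gapped
records must be degapped before scanning.

Conservation across a pre-aligned ortholog set reports, per anchor column,
the fraction of records carrying exactly the reference residue and the
fraction carrying any anchor-class residue; a gap counts as neither.  Anchor
positions are mapped to alignment columns by ungapped counting from the
reference's first-residue offset, so reference gaps shift columns, never
numbering.  Variant tables are consumed as local files (no database
queries, for reproducibility offline); the same alternate allele reported by
several source databases is de-duplicated keeping the maximum frequency.

## Synthetic data

The generators emulate the statistical structure each stage assumes, not the
physics of the measurements:

- **Shift tables**: observed shift = random coil + population × full-helix
  offset + independent Gaussian ppm noise (default σ = 0.01 ppm, the stated
  measurement error).  The Cα full-helix offset (+2.8 ppm) is a conventional
  value used only for simulation; population estimation is Hα-only.
- **Titrations**: fast-exchange 1:1 binding; the bound fraction is the exact
  quadratic root fb = ((P+L+K)−√((P+L+K)²−4PL))/(2P) and each peak moves
  free → free + fb·Δδ_max, plus noise.  Free peak positions are drawn once
  per seed from typical amide ranges (¹H 7.5–9.5, ¹⁵N 105–130 ppm).
- **SPR**: Langmuir responses plus Gaussian RU noise, replicated; an
  exponential-rise sensorgram generator exists solely for window-extraction
  and referencing tests.
- **Ortholog sets**: independent per-position substitution; at anchor-class
  positions a substitution stays within the class with probability
  `class_preserving_fraction`, mimicking the observed pattern of identity
  loss with class retention.

All generators are pure functions of their spec including the seed, with a
documented draw order, so seed-regeneration tests are stable.  What passing
tests on these inputs shows is that the analysis recovers the generating
parameters under the assumed noise model; they do not probe peak overlap,
correlated shift errors, exchange-regime intermediates, mass transport, or
phylogenetic correlation between species — real data can violate all of
these.

## Problem sizes and fixed choices

Stochastic checks use 100 seeded replicates (Langmuir recovery at σ = 1 RU
on the duplicated reference ladder; segment recovery at populations drawn
uniformly from 10–90 % with σ = 0.01 ppm noise).  The helix-population
checks use the ranges stated for the system: 23 % over residues 3–17 in
water, 43–47 % in 30 % TFE, and two helices (3–17, 25–31) for the longer
2–36 peptide; the second helix's population is not stated and the synthetic
fixture uses 30 %, a mid-range nascent-helix value — only its span is
asserted.  At populations below ~14 % the Hα deviation (−0.055 ppm and
smaller) approaches the ±0.04 ppm coil band, so segment boundaries are
intrinsically unstable there; the recovery criterion (≥ 90 % of replicates
within ±1 residue per boundary) accounts for this.

## Known limitations

- The helix caller has no β-strand or PPII logic; it answers only the
  helix/coil question the population formula needs.
- Population estimation assumes the random-coil reference matches the
  experimental conditions; co-solvents like TFE shift reference values
  slightly, which is not corrected.
- The CSP module does not extract affinities from titration curves; K_D
  comes from the SPR module.
- The Langmuir fit is unweighted; heteroscedastic RU noise would call for
  weights the reference design does not provide.
- The motif scanner scores anchor identity only; helicity, charge and
  context that discriminate real CaM targets are out of scope.
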