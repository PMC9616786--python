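# camsite

Analysis toolkit for characterising a calmodulin (CaM)-binding site from
solution data, built around the N-terminal extension of the formin INF2 as
the worked system.  It is aimed at structural biologists and biophysicists
who have peptide chemical shifts, HSQC titrations, SPR sensorgrams and
ortholog alignments on disk and want the downstream numbers — helix
populations, perturbed residues, affinities, motif assignments — computed
reproducibly instead of by spreadsheet.

## What it computes

**Secondary chemical shifts and helix populations** (`camsite.chemshift`).
From observed Hα/Cα shifts and random-coil references (the bundled Wishart
table by default):

    Δδ_Hα = δ_Hα^obs − δ_Hα^RC,    Δδ_Cα = δ_Cα^obs − δ_Cα^RC

Residues with Δδ_Hα ≤ −0.04 ppm or Δδ_Cα ≥ +0.4 ppm are scored helical;
maximal runs (≥ 3 residues, bridging single-residue dropouts) become helix
segments.  The fractional helix population of a segment is

    % helix = 100 × ⟨Δδ_Hα⟩ / (−0.39 ppm)

with the per-shift measurement error propagated linearly (±0.01 ppm → ±2.6 %,
i.e. ±3 % at integer precision).

**Chemical-shift perturbation mapping** (`camsite.titration`).  Per-residue
CSPs across an ¹H-¹⁵N HSQC titration,

    CSP = sqrt(((Δδ_1H)² + (Δδ_15N/5)²) / 2)

with an inclusive significance threshold (0.25 ppm default) and a per-lobe
summary over the CaM anatomy (N-lobe 1–77, linker 78–81, C-lobe 82–148).

**Steady-state SPR affinity** (`camsite.spr`).  Double referencing of
sensorgrams, equilibrium-response extraction with a plateau diagnostic, and
an unweighted least-squares fit of the one-site Langmuir isotherm
R_eq = C·R_max/(C + K_D).

**1-4-8 motif scanning and conservation** (`camsite.motifs`).  Reports every
sequence window whose relative positions 1, 4 and 8 all carry a bulky
hydrophobic anchor (W/F/I/L/V), plus anchor conservation across ortholog
alignments and allelic-variant tallies.

**Synthetic data** (`camsite.simulate`).  Seeded generators with the
statistical structure each stage assumes (fractional-helix shift tables,
fast-exchange 1:1 titrations, Langmuir equilibrium responses, ortholog sets),
so the whole pipeline is testable without downloads.

## Worked example

```python
from camsite import (RandomCoilTable, compute_delta, call_segments,
                     helix_population, scan_148, fit_langmuir)
from camsite.sequences import INF2_2_19
from camsite.simulate import (ShiftSimSpec, SPRSimSpec,
                              gen_shift_table, gen_equilibrium)
from camsite.spr import reference_concentration_ladder

rc = RandomCoilTable.wishart()

# Hα/Cα shifts of the 2-19 peptide with a 23 %-formed helix over 3-17
spec = ShiftSimSpec(INF2_2_19, [((3, 17), 0.23)], noise_sd=0.01, seed=7)
profile = compute_delta(gen_shift_table(spec, rc), rc)
for s in call_segments(profile):
    print(f"helix {s.start}-{s.end}: "
          f"{s.population_percent:.1f} +/- {s.population_error_percent:.1f} % helix")

hit = scan_148(INF2_2_19)[0]
print("1-4-8 motif anchors:", hit.anchor_positions, hit.anchor_residues)

data = gen_equilibrium(SPRSimSpec(
    kd=1.40e-6, rmax=50.0,
    concentrations=tuple(reference_concentration_ladder()),
    noise_sd=1.0, replicates=2, seed=7))
fit = fit_langmuir(data)
print(f"K_D = {fit.kd_uM:.2f} uM, Rmax = {fit.rmax:.1f} RU")
```

prints

```
helix 3-17: 24.9 +/- 2.6 % helix
1-4-8 motif anchors: (11, 14, 18) ('W', 'L', 'L')
K_D = 1.32 uM, Rmax = 48.1 RU
```

The called segment spans residues 3–17 and its population lands within the
propagated ±2.6 % of the generating 23 %.  The motif scan places the three
hydrophobic anchors at W11, L14 and L18 — the 1-4-8 CaM-binding motif of
INF2.  The Langmuir fit recovers the generating affinity (1.40 µM) within
the scatter expected at 1 RU noise on a two-fold ladder from 13.2 nM to
9.6 µM in duplicate.

A command-line interface mirrors the library (`camsite shifts`, `camsite
csp`, `camsite spr fit|reduce`, `camsite scan`, `camsite conserve`,
`camsite variants`, `camsite simulate`); run `camsite --help` for details.

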