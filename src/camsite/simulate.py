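"""Seeded generators of synthetic inputs for every analysis stage.

Each generator is a pure function of its spec (seed included): the same spec
always yields byte-identical output.  Random draws use one
``numpy.random.default_rng(seed)`` stream per call, consumed in a documented
order so regeneration-based tests stay stable:

- shift tables: residues in sequence order, Hα noise then Cα noise;
- titrations: free peak positions first (¹H then ¹⁵N per residue, residues
  sorted), then per ratio in order, per residue sorted, ¹H noise then ¹⁵N;
- equilibrium sets: concentrations in the given order, replicates innermost;
- ortholog sets: species in order, positions left to right, the
  substitute-or-not draw before any residue-choice draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemshift import FULL_HELIX_HALPHA, RandomCoilTable, ShiftEntry, ShiftTable
from .errors import ValidationError
from .motifs import ANCHOR_CLASS, SequenceRecord
from .spr import EquilibriumBindingSet, Sensorgram, langmuir
from .titration import Peak, TitrationPoint, TitrationSeries

#: Cα secondary shift of a 100 % helix, ppm — a conventional value used only
#: for simulation, never for population estimation (which is Hα-only).
FULL_HELIX_CALPHA = 2.8

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ShiftSimSpec:
    """Synthetic Hα/Cα shifts for a peptide with fractional helical spans.

    Each span (inclusive residue range, population in [0,1]) displaces the
    random-coil shift by population × full-helix offset; independent
    Gaussian ppm noise is added per shift.
    """

    sequence: SequenceRecord
    helix_spans: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    noise_sd: float = 0.01
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        first = self.sequence.first_residue_number
        last = first + len(self.sequence.sequence) - 1
        for (lo, hi), pop in self.helix_spans:
            if lo < first or hi > last or lo > hi:
                raise ValidationError(f"span {lo}-{hi} outside sequence {first}-{last}")
            if not 0.0 <= pop <= 1.0:
                raise ValidationError("populations must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def gen_shift_table(spec: ShiftSimSpec, rc: RandomCoilTable) -> ShiftTable:
    """Observed shifts = random coil + population × full-helix offset + noise."""
    rng = np.random.default_rng(spec.seed)
    pop_of: dict[int, float] = {}
    for (lo, hi), pop in spec.helix_spans:
        for res in range(lo, hi + 1):
            pop_of[res] = pop
    entries = []
    first = spec.sequence.first_residue_number
    for i, aa in enumerate(spec.sequence.sequence):
        res = first + i
        pop = pop_of.get(res, 0.0)
        ha = rc.halpha(aa) + pop * FULL_HELIX_HALPHA + rng.normal(0.0, spec.noise_sd)
        ca = rc.calpha(aa) + pop * FULL_HELIX_CALPHA + rng.normal(0.0, spec.noise_sd)
        entries.append(ShiftEntry(residue=res, aa=aa, atom="HA", shift=ha))
        entries.append(ShiftEntry(residue=res, aa=aa, atom="CA", shift=ca))
    return ShiftTable(
        molecule_id=spec.sequence.id, condition=spec.condition, entries=entries
    )


@dataclass(frozen=True)
class TitrationSimSpec:
    """Fast-exchange 1:1 binding titration of an HSQC-observed protein.

    ``dmax`` maps residue number -> (ΔδH_max, ΔδN_max), the bound-minus-free
    peak displacement at saturation.
    """

    kd: float
    protein_conc: float
    ratios: tuple[float, ...]
    dmax: dict[int, tuple[float, float]]
    noise_sd: float = 0.0
    seed: int = 0
    protein_id: str = "synthetic_protein"

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.protein_conc <= 0:
            raise ValidationError("kd and protein_conc must be positive")
        if any(r < 0 for r in self.ratios) or list(self.ratios) != sorted(set(self.ratios)):
            raise ValidationError("ratios must be non-negative and strictly ascending")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def bound_fraction(protein: float, ligand: float, kd: float) -> float:
    """Fraction of protein bound in a 1:1 equilibrium (exact quadratic root).

    fb = ((P + L + K_D) − sqrt((P + L + K_D)² − 4·P·L)) / (2P)
    """
    s = protein + ligand + kd
    disc = s * s - 4.0 * protein * ligand
    return (s - math.sqrt(max(disc, 0.0))) / (2.0 * protein)


def gen_titration(spec: TitrationSimSpec) -> TitrationSeries:
    """Peak positions that move from free toward free + dmax with saturation."""
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.dmax)
    free = {
        res: Peak(
            h_shift=float(rng.uniform(7.5, 9.5)),
            n_shift=float(rng.uniform(105.0, 130.0)),
        )
        for res in residues
    }
    points = []
    for ratio in spec.ratios:
        ligand = ratio * spec.protein_conc
        fb = bound_fraction(spec.protein_conc, ligand, spec.kd) if ligand > 0 else 0.0
        peaks = {}
        for res in residues:
            dh, dn = spec.dmax[res]
            peaks[res] = Peak(
                h_shift=free[res].h_shift + fb * dh + float(rng.normal(0, spec.noise_sd)),
                n_shift=free[res].n_shift + fb * dn + float(rng.normal(0, spec.noise_sd)),
            )
        points.append(TitrationPoint(ratio=ratio, peaks=peaks))
    return TitrationSeries(protein_id=spec.protein_id, points=points)


@dataclass(frozen=True)
class SPRSimSpec:
    """Langmuir equilibrium responses with Gaussian RU noise, replicated."""

    kd: float
    rmax: float
    concentrations: tuple[float, ...]
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    ligand_id: str = "synthetic_ligand"

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.rmax <= 0:
            raise ValidationError("kd and rmax must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations must be positive")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def gen_equilibrium(spec: SPRSimSpec) -> EquilibriumBindingSet:
    """R_eq = C·Rmax/(C + K_D) + Gaussian RU noise, replicates as points."""
    rng = np.random.default_rng(spec.seed)
    concs, reqs = [], []
    for c in spec.concentrations:
        model = float(langmuir(np.asarray(c), spec.kd, spec.rmax))
        for _ in range(spec.replicates):
            concs.append(c)
            reqs.append(model + float(rng.normal(0.0, spec.noise_sd)))
    return EquilibriumBindingSet(
        concentrations=np.asarray(concs),
        responses=np.asarray(reqs),
        ligand_id=spec.ligand_id,
    )


def gen_sensorgram(
    conc: float,
    kd: float,
    rmax: float,
    k_obs: float = 1.0,
    t_assoc: float = 60.0,
    t_dissoc: float = 60.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell: str = "sample",
) -> Sensorgram:
    """Exponential rise to the Langmuir plateau, then exponential decay.

    A minimal trace for equilibrium-window extraction and double-referencing
    tests; no mass transport or drift.
    """
    rng = np.random.default_rng(seed)
    req = float(langmuir(np.asarray(conc), kd, rmax))
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = np.where(
        t <= t_assoc,
        req * (1.0 - np.exp(-k_obs * t)),
        req * (1.0 - np.exp(-k_obs * t_assoc)) * np.exp(-k_obs * (t - t_assoc)),
    )
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(analyte_conc=conc, times=t, response=r, cell=cell)


@dataclass(frozen=True)
class OrthologSimSpec:
    """Ortholog set with per-position substitution rates.

    At positions whose reference residue is a bulky hydrophobic anchor
    (W/F/I/L/V), a substitution stays within that class with probability
    ``class_preserving_fraction`` (drawn from the class minus the reference),
    otherwise it leaves the class; elsewhere a substitution draws uniformly
    from the other 19 residues.
    """

    base: SequenceRecord
    per_position_sub_rate: dict[int, float] = field(default_factory=dict)
    class_preserving_fraction: float = 1.0
    n_species: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= r <= 1.0 for r in self.per_position_sub_rate.values()):
            raise ValidationError("substitution rates must be in [0, 1]")
        if not 0.0 <= self.class_preserving_fraction <= 1.0:
            raise ValidationError("class_preserving_fraction must be in [0, 1]")
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")


def gen_ortholog_set(spec: OrthologSimSpec) -> list[SequenceRecord]:
    """Mutate the base sequence independently per species and position."""
    rng = np.random.default_rng(spec.seed)
    base = spec.base
    records = []
    in_class = sorted(ANCHOR_CLASS)
    for k in range(spec.n_species):
        chars = []
        for i, ref in enumerate(base.sequence):
            res = base.first_residue_number + i
            rate = spec.per_position_sub_rate.get(res, 0.0)
            if rate > 0 and rng.random() < rate:
                if ref in ANCHOR_CLASS and rng.random() < spec.class_preserving_fraction:
                    choices = [a for a in in_class if a != ref]
                elif ref in ANCHOR_CLASS:
                    choices = [a for a in _ALPHABET if a not in ANCHOR_CLASS]
                else:
                    choices = [a for a in _ALPHABET if a != ref]
                chars.append(choices[int(rng.integers(len(choices)))])
            else:
                chars.append(ref)
        records.append(
            SequenceRecord(
                id=f"species_{k:03d}",
                sequence="".join(chars),
                first_residue_number=base.first_residue_number,
            )
        )
    return records
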