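"""Secondary chemical shifts, helix calling and helix-population estimation.

Secondary chemical shifts are the deviations of observed Hα/Cα shifts from
random-coil reference values for the same residue type:

    Δδ_Hα = δ_Hα(observed) − δ_Hα(random coil)
    Δδ_Cα = δ_Cα(observed) − δ_Cα(random coil)

Stretches of negative Δδ_Hα and/or positive Δδ_Cα mark α-helix; values inside
a narrow band around zero (±0.04 ppm for Hα, ±0.4 ppm for Cα) are treated as
random coil.  The fractional helix population of a segment is estimated from
the mean Hα secondary shift relative to the value expected for a fully formed
helix (−0.39 ppm):

    % helix = 100 × ⟨Δδ_Hα⟩ / (−0.39)

The per-residue shift measurement error propagates linearly into the
population estimate (no √N reduction), so a ±0.01 ppm shift error maps to
roughly ±3 % helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .errors import ValidationError

VALID_ATOMS = frozenset({"HA", "CA", "N", "H"})
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Hα secondary shift of a 100 % formed α-helix, ppm.
FULL_HELIX_HALPHA = -0.39


@dataclass(frozen=True)
class ShiftEntry:
    """One assigned chemical shift: (residue, residue type, atom, ppm)."""

    residue: int
    aa: str
    atom: str
    shift: float


@dataclass
class ShiftTable:
    """Assigned chemical shifts for one molecule under one condition.

    Residue numbers follow full-length protein numbering: a peptide covering
    residues 2–19 of the parent protein numbers its residues 2..19.
    """

    molecule_id: str
    condition: str = ""
    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            if e.residue <= 0:
                raise ValidationError(f"residue number must be positive, got {e.residue}")
            if e.atom not in VALID_ATOMS:
                raise ValidationError(f"unknown atom {e.atom!r} for residue {e.residue}")
            if not math.isfinite(e.shift):
                raise ValidationError(f"non-finite shift for residue {e.residue} atom {e.atom}")
            key = (e.residue, e.atom)
            if key in seen:
                raise ValidationError(f"duplicate entry for residue {e.residue} atom {e.atom}")
            seen.add(key)

    def shifts_for(self, atom: str) -> dict[int, float]:
        """Map residue number -> shift for one atom type."""
        return {e.residue: e.shift for e in self.entries if e.atom == atom}

    def residue_types(self) -> dict[int, str]:
        types: dict[int, str] = {}
        for e in self.entries:
            prev = types.setdefault(e.residue, e.aa)
            if prev != e.aa:
                raise ValidationError(
                    f"residue {e.residue} typed as both {prev} and {e.aa}"
                )
        return types

    @property
    def residues(self) -> list[int]:
        return sorted({e.residue for e in self.entries})


class RandomCoilTable:
    """Per-residue-type random-coil Hα/Cα reference shifts (ppm).

    The bundled default table carries the Wishart random-coil values for the
    20 standard amino acids; alternative tables can be loaded from a TSV file
    with columns ``aa``, ``halpha_rc``, ``calpha_rc``.
    """

    def __init__(self, values: dict[str, tuple[float, float]]):
        for aa, (ha, ca) in values.items():
            if not (ha > 0 and ca > 0 and math.isfinite(ha) and math.isfinite(ca)):
                raise ValidationError(f"random-coil values for {aa} must be positive finite")
        self._values = dict(values)

    @classmethod
    def wishart(cls) -> "RandomCoilTable":
        """The bundled Wishart random-coil reference table."""
        text = resources.files("camsite.data").joinpath("wishart_rc.tsv").read_text()
        return cls._parse(text.splitlines())

    @classmethod
    def from_file(cls, path) -> "RandomCoilTable":
        with open(path) as fh:
            return cls._parse(fh.read().splitlines())

    @classmethod
    def _parse(cls, lines: Iterable[str]) -> "RandomCoilTable":
        values: dict[str, tuple[float, float]] = {}
        for i, line in enumerate(lines):
            if i == 0 or not line.strip():
                continue
            aa, ha, ca = line.split("\t")
            values[aa.strip().upper()] = (float(ha), float(ca))
        missing = STANDARD_AA - values.keys()
        if missing:
            raise ValidationError(f"random-coil table missing amino acids: {sorted(missing)}")
        return cls(values)

    def halpha(self, aa: str) -> float:
        return self._lookup(aa)[0]

    def calpha(self, aa: str) -> float:
        return self._lookup(aa)[1]

    def _lookup(self, aa: str) -> tuple[float, float]:
        try:
            return self._values[aa.upper()]
        except KeyError:
            raise ValidationError(f"residue type {aa!r} absent from random-coil table") from None

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self._values


@dataclass(frozen=True)
class DeltaEntry:
    residue: int
    delta_halpha: float | None = None
    delta_calpha: float | None = None


@dataclass
class DeltaProfile:
    """Per-residue secondary chemical shifts (Δδ_Hα, Δδ_Cα), ppm."""

    molecule_id: str
    entries: list[DeltaEntry] = field(default_factory=list)

    def by_residue(self) -> dict[int, DeltaEntry]:
        return {e.residue: e for e in self.entries}

    @property
    def residues(self) -> list[int]:
        return sorted(e.residue for e in self.entries)


@dataclass(frozen=True)
class SSThresholds:
    """Classification thresholds for helix calling.

    halpha_coil_band / calpha_coil_band: half-width (ppm) of the random-coil
    band around zero for Δδ_Hα and Δδ_Cα; full_helix_halpha: Δδ_Hα of a 100 %
    helix (ppm, negative); min_segment_length / max_gap: run-finding controls
    in residues.
    """

    halpha_coil_band: float = 0.04
    calpha_coil_band: float = 0.4
    full_helix_halpha: float = FULL_HELIX_HALPHA
    min_segment_length: int = 3
    max_gap: int = 1

    def __post_init__(self) -> None:
        if self.halpha_coil_band <= 0 or self.calpha_coil_band <= 0:
            raise ValidationError("coil bands must be positive")
        if self.full_helix_halpha >= 0:
            raise ValidationError("full-helix Δδ_Hα must be negative")


@dataclass(frozen=True)
class HelixSegment:
    start: int
    end: int
    population_percent: float
    population_error_percent: float
    raw_population_percent: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("segment start must not exceed end")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PopulationEstimate:
    """Helix population as a percentage, clamped to [0, 100].

    ``raw_percent`` keeps the unclamped value for diagnostics (a strongly
    coil-shifted region can produce a negative raw estimate).
    """

    percent: float
    raw_percent: float
    n_residues: int

    def __float__(self) -> float:
        return self.percent


def compute_delta(shifts: ShiftTable, rc: RandomCoilTable) -> DeltaProfile:
    """Subtract random-coil reference shifts from observed Hα/Cα shifts.

    Residues whose type is absent from ``rc`` raise; atoms other than HA/CA
    do not contribute.  A residue with only one of HA/CA observed gets the
    other delta as None.
    """
    types = shifts.residue_types()
    ha = shifts.shifts_for("HA")
    ca = shifts.shifts_for("CA")
    entries = []
    for res in sorted(set(ha) | set(ca)):
        aa = types[res]
        if aa not in rc:
            raise ValidationError(f"residue {res} type {aa!r} absent from random-coil table")
        entries.append(
            DeltaEntry(
                residue=res,
                delta_halpha=ha[res] - rc.halpha(aa) if res in ha else None,
                delta_calpha=ca[res] - rc.calpha(aa) if res in ca else None,
            )
        )
    return DeltaProfile(molecule_id=shifts.molecule_id, entries=entries)


def is_helical(entry: DeltaEntry, thresholds: SSThresholds = SSThresholds()) -> bool:
    """A residue is helical if Δδ_Hα ≤ −band OR Δδ_Cα ≥ +band.

    The OR rule makes use of sparse natural-abundance ¹³C data: either
    indicator alone can mark a residue helical.  Residues with neither delta
    present are non-helical.
    """
    if entry.delta_halpha is not None and entry.delta_halpha <= -thresholds.halpha_coil_band:
        return True
    if entry.delta_calpha is not None and entry.delta_calpha >= thresholds.calpha_coil_band:
        return True
    return False


def call_segments(
    profile: DeltaProfile,
    thresholds: SSThresholds = SSThresholds(),
    shift_error: float = 0.01,
) -> list[HelixSegment]:
    """Find maximal helical runs and estimate each segment's population.

    Consecutive helical residues are merged into one segment when at most
    ``thresholds.max_gap`` non-helical residues (by residue number, whether
    observed-but-coil or simply unassigned) lie between them.  Runs shorter
    than ``min_segment_length`` are discarded.  Segments are returned sorted
    by start and never overlap.
    """
    if not profile.entries:
        raise ValidationError("profile is empty")
    helical = sorted(
        e.residue for e in profile.entries if is_helical(e, thresholds)
    )
    if not helical:
        return []
    runs: list[list[int]] = [[helical[0]]]
    for res in helical[1:]:
        if res - runs[-1][-1] - 1 <= thresholds.max_gap:
            runs[-1].append(res)
        else:
            runs.append([res])
    segments = []
    for run in runs:
        start, end = run[0], run[-1]
        if end - start + 1 < thresholds.min_segment_length:
            continue
        try:
            pop = helix_population(profile, (start, end), thresholds)
            pct, raw = pop.percent, pop.raw_percent
        except ValidationError:  # no Hα data in a Cα-called segment
            pct = raw = float("nan")
        segments.append(
            HelixSegment(
                start=start,
                end=end,
                population_percent=pct,
                population_error_percent=population_error(shift_error, thresholds),
                raw_population_percent=raw,
            )
        )
    return segments


def helix_population(
    profile: DeltaProfile,
    residues: tuple[int, int],
    thresholds: SSThresholds = SSThresholds(),
) -> PopulationEstimate:
    """% helix = 100 × ⟨Δδ_Hα⟩ / full_helix_halpha over an inclusive range.

    Only Hα secondary shifts enter the average.  The returned percentage is
    clamped to [0, 100]; the raw value is kept alongside.
    """
    lo, hi = residues
    deltas = [
        e.delta_halpha
        for e in profile.entries
        if lo <= e.residue <= hi and e.delta_halpha is not None
    ]
    if not deltas:
        raise ValidationError(f"no Δδ_Hα values in residue range {lo}-{hi}")
    raw = 100.0 * (sum(deltas) / len(deltas)) / thresholds.full_helix_halpha
    return PopulationEstimate(
        percent=min(100.0, max(0.0, raw)), raw_percent=raw, n_residues=len(deltas)
    )


def population_error(
    shift_error: float, thresholds: SSThresholds = SSThresholds()
) -> float:
    """Helix-population error (%) propagated from a per-shift error (ppm).

    The per-residue measurement error is propagated linearly, without √N
    reduction: error% = 100 × shift_error / |full_helix_halpha|.  A 0.01 ppm
    shift error therefore maps to 2.56 %, i.e. ±3 % at integer precision.
    """
    if shift_error < 0:
        raise ValidationError("shift error must be non-negative")
    return 100.0 * shift_error / abs(thresholds.full_helix_halpha)
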