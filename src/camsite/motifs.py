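"""1-4-8 hydrophobic calmodulin-binding-motif scanning and conservation.

Ca²⁺-dependent calmodulin-binding motifs are classified by the relative
positions of two-to-three bulky hydrophobic anchor residues (W, F, I, L, V)
along a typically helical segment.  The 1-4-8 class places anchors at
relative positions 1, 4 and 8 — residue offsets (0, +3, +7).  Scanning
reports every window whose three anchor slots all carry class residues;
intermediate positions are unconstrained.

Conservation of the anchors is summarised across a pre-computed ortholog
alignment (exact identity to the reference residue, and retention of any
class residue) and across a table of human allelic variants.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: Bulky hydrophobic anchor residues of Ca²⁺-dependent CaM-binding motifs.
ANCHOR_CLASS = frozenset("WFILV")

#: Residue offsets of motif positions 1, 4 and 8.
SPACING_148 = (0, 3, 7)

GAP = "-"
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein (or peptide) sequence with full-length residue numbering.

    ``first_residue_number`` anchors the peptide in the parent protein's
    numbering: the peptide covering residues 2-19 has first_residue_number 2.
    Aligned records may contain '-' gaps; X is tolerated and never matches
    the anchor class.
    """

    id: str
    sequence: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if self.first_residue_number < 1:
            raise ValidationError("first_residue_number must be >= 1")
        bad = set(self.sequence) - _AA - {GAP, "X"}
        if bad:
            raise ValidationError(
                f"record {self.id!r} has invalid characters {sorted(bad)}"
            )

    @property
    def is_gapped(self) -> bool:
        return GAP in self.sequence

    def residue_number(self, index: int) -> int:
        """Full-length residue number of the 0-based ungapped index."""
        return self.first_residue_number + index

    def column_of_residue(self, residue: int) -> int:
        """0-based alignment column holding the given (ungapped) residue number."""
        target = residue - self.first_residue_number
        seen = -1
        for col, ch in enumerate(self.sequence):
            if ch != GAP:
                seen += 1
                if seen == target:
                    return col
        raise ValidationError(f"residue {residue} outside record {self.id!r}")


@dataclass(frozen=True)
class MotifHit:
    """One match of the hydrophobic anchor pattern, in full-length numbering."""

    anchor_positions: tuple[int, int, int]
    anchor_residues: tuple[str, str, str]
    window: tuple[int, int]

    def __post_init__(self) -> None:
        p1, p4, p8 = self.anchor_positions
        if (p4 - p1, p8 - p1) != (3, 7):
            raise ValidationError("anchor positions must be spaced (0, +3, +7)")
        if any(r not in ANCHOR_CLASS for r in self.anchor_residues):
            raise ValidationError("anchor residues must be in {W,F,I,L,V}")


def scan_148(
    record: SequenceRecord, spacing: tuple[int, ...] = SPACING_148
) -> list[MotifHit]:
    """All windows whose anchor slots are bulky hydrophobic residues.

    ``spacing`` gives the anchor offsets relative to the window start; the
    default (0, 3, 7) is the 1-4-8 motif.  Overlapping hits are all
    reported.  Gapped records raise: degap before scanning.
    """
    if record.is_gapped:
        raise ValidationError(
            f"record {record.id!r} is gapped; remove '-' characters before scanning"
        )
    seq = record.sequence
    width = spacing[-1] + 1
    hits = []
    for i in range(len(seq) - width + 1):
        residues = tuple(seq[i + off] for off in spacing)
        if all(r in ANCHOR_CLASS for r in residues):
            positions = tuple(record.residue_number(i + off) for off in spacing)
            hits.append(
                MotifHit(
                    anchor_positions=positions,  # type: ignore[arg-type]
                    anchor_residues=residues,  # type: ignore[arg-type]
                    window=(record.residue_number(i), record.residue_number(i + width - 1)),
                )
            )
    return hits


@dataclass(frozen=True)
class AnchorConservation:
    identity_fraction: float
    class_conserved_fraction: float
    observed_residues: Counter


@dataclass
class ConservationSummary:
    """Per-anchor-column conservation statistics across an alignment."""

    reference_id: str
    n_species: int
    anchors: dict[int, AnchorConservation] = field(default_factory=dict)


def conservation_profile(
    alignment: list[SequenceRecord],
    reference_id: str,
    anchor_positions: list[int] | tuple[int, ...],
) -> ConservationSummary:
    """Identity and anchor-class retention at each anchor column.

    For each anchor position (in the reference's full-length numbering) the
    identity fraction is the share of aligned records carrying exactly the
    reference residue, and the class-conserved fraction the share carrying
    any residue in {W,F,I,L,V}.  A gap counts as neither.
    """
    if not alignment:
        raise ValidationError("alignment is empty")
    lengths = {len(r.sequence) for r in alignment}
    if len(lengths) != 1:
        raise ValidationError("aligned records must all have the same length")
    by_id = {r.id: r for r in alignment}
    if reference_id not in by_id:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    reference = by_id[reference_id]
    summary = ConservationSummary(reference_id=reference_id, n_species=len(alignment))
    for pos in anchor_positions:
        col = reference.column_of_residue(pos)
        ref_res = reference.sequence[col]
        if ref_res == GAP:
            raise ValidationError(f"anchor {pos} maps to a gap in the reference")
        column = [r.sequence[col] for r in alignment]
        observed = Counter(column)
        n = len(column)
        summary.anchors[pos] = AnchorConservation(
            identity_fraction=sum(c == ref_res for c in column) / n,
            class_conserved_fraction=sum(c in ANCHOR_CLASS for c in column) / n,
            observed_residues=observed,
        )
    return summary


@dataclass(frozen=True)
class VariantRow:
    residue: int
    ref: str
    alt: str
    frequency: float
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref equals alt at residue {self.residue}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(f"frequency out of [0,1] at residue {self.residue}")


@dataclass
class VariantTable:
    rows: list[VariantRow] = field(default_factory=list)


@dataclass(frozen=True)
class PositionVariants:
    residue: int
    alts: dict[str, float]  # alt residue -> max frequency across sources
    invariant: bool


def variant_tally(
    variants: VariantTable, region: tuple[int, int]
) -> list[PositionVariants]:
    """Per-position variant summary over an inclusive residue range.

    Positions with no variant rows are flagged invariant.  The same alt
    reported by several source databases is de-duplicated, keeping the
    maximum frequency.  Rows outside the region are ignored with a warning.
    """
    lo, hi = region
    if lo > hi:
        raise ValidationError("region start must not exceed end")
    outside = [r.residue for r in variants.rows if not lo <= r.residue <= hi]
    if outside:
        warnings.warn(f"variants outside region ignored: {sorted(set(outside))}",
                      stacklevel=2)
    per_pos: dict[int, dict[str, float]] = {}
    for row in variants.rows:
        if lo <= row.residue <= hi:
            alts = per_pos.setdefault(row.residue, {})
            alts[row.alt] = max(alts.get(row.alt, 0.0), row.frequency)
    return [
        PositionVariants(
            residue=pos,
            alts=per_pos.get(pos, {}),
            invariant=pos not in per_pos,
        )
        for pos in range(lo, hi + 1)
    ]


def find_motif_candidates(
    proteome: list[SequenceRecord], spacing: tuple[int, ...] = SPACING_148
) -> pd.DataFrame:
    """Scan every record and tabulate all hits, one row per hit."""
    rows = []
    for record in proteome:
        for hit in scan_148(record, spacing):
            rows.append(
                {
                    "protein_id": record.id,
                    "anchor_positions": hit.anchor_positions,
                    "anchor_residues": "".join(hit.anchor_residues),
                    "window_start": hit.window[0],
                    "window_end": hit.window[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "anchor_positions", "anchor_residues",
                 "window_start", "window_end"],
    )
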