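"""Chemical-shift perturbation (CSP) mapping of an HSQC titration.

An ¹⁵N-labelled protein is titrated with unlabelled ligand and a ¹H-¹⁵N HSQC
is recorded at each ligand:protein molar ratio.  Under fast exchange each
amide cross-peak moves continuously from its free position toward its bound
position; the combined perturbation at a chosen endpoint ratio is

    CSP = sqrt(((Δδ_1H)² + (Δδ_15N / 5)²) / 2)

where the ¹⁵N change is scaled by 1/5 to account for its larger ppm
dispersion.  Residues with CSP at or above a significance threshold
(0.25 ppm by default) map the binding surface; tallying them per calmodulin
lobe (N-lobe / linker / C-lobe) identifies the lobe that engages the ligand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ValidationError

#: Default significance threshold for CSP values, ppm.
DEFAULT_CSP_THRESHOLD = 0.25

LOBE_NAMES = ("N", "linker", "C")


@dataclass(frozen=True)
class Peak:
    """An amide cross-peak position: (¹H ppm, ¹⁵N ppm)."""

    h_shift: float
    n_shift: float


@dataclass
class TitrationPoint:
    ratio: float
    peaks: dict[int, Peak]


@dataclass
class TitrationSeries:
    """HSQC peak positions across ligand:protein ratios.

    Ratios must be strictly increasing and include 0 (the free-protein
    reference spectrum).
    """

    protein_id: str
    points: list[TitrationPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        ratios = [p.ratio for p in self.points]
        if any(r < 0 for r in ratios):
            raise ValidationError("ratios must be non-negative")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValidationError("ratios must be strictly increasing")
        if not ratios or ratios[0] != 0:
            raise ValidationError("the zero-ratio reference point is required")

    @property
    def ratios(self) -> list[float]:
        return [p.ratio for p in self.points]

    def point_at(self, ratio: float) -> TitrationPoint:
        for p in self.points:
            if p.ratio == ratio:
                return p
        raise ValidationError(f"no titration point at ratio {ratio}")


@dataclass(frozen=True)
class CSPEntry:
    residue: int
    csp: float
    significant: bool
    lobe: str


@dataclass
class CSPProfile:
    entries: list[CSPEntry] = field(default_factory=list)

    def by_residue(self) -> dict[int, CSPEntry]:
        return {e.residue: e for e in self.entries}


@dataclass(frozen=True)
class LobeMap:
    """Residue ranges (inclusive) of the CaM N-lobe, linker and C-lobe.

    The defaults follow the canonical calmodulin EF-hand organisation:
    N-lobe 1-77, central linker 78-81, C-lobe 82-148.
    """

    n_lobe: tuple[int, int] = (1, 77)
    linker: tuple[int, int] = (78, 81)
    c_lobe: tuple[int, int] = (82, 148)

    def __post_init__(self) -> None:
        spans = [self.n_lobe, self.linker, self.c_lobe]
        covered: set[int] = set()
        for lo, hi in spans:
            if lo > hi:
                raise ValidationError("lobe range start must not exceed end")
            rng = set(range(lo, hi + 1))
            if covered & rng:
                raise ValidationError("lobe ranges must be disjoint")
            covered |= rng
        if covered != set(range(min(covered), max(covered) + 1)):
            raise ValidationError("lobe ranges must cover the protein without holes")

    def lobe_of(self, residue: int) -> str:
        for name, (lo, hi) in zip(LOBE_NAMES, (self.n_lobe, self.linker, self.c_lobe)):
            if lo <= residue <= hi:
                return name
        raise ValidationError(f"residue {residue} outside all lobe ranges")

    def size(self, name: str) -> int:
        lo, hi = {"N": self.n_lobe, "linker": self.linker, "C": self.c_lobe}[name]
        return hi - lo + 1


def csp_value(
    delta_h: float, delta_n: float, convention: str = "pooled"
) -> float:
    """Combined amide CSP from ¹H and ¹⁵N shift changes.

    convention="pooled" (default): sqrt(((ΔδH)² + (ΔδN/5)²) / 2) — the 1/2
    averages the two squared contributions.  convention="n_only" applies the
    1/2 to the nitrogen term only: sqrt((ΔδH)² + ((ΔδN/5)²) / 2), kept as a
    sensitivity check on the formula reading.
    """
    h2 = delta_h * delta_h
    n2 = (delta_n / 5.0) ** 2
    if convention == "pooled":
        return math.sqrt((h2 + n2) / 2.0)
    if convention == "n_only":
        return math.sqrt(h2 + n2 / 2.0)
    raise ValidationError(f"unknown CSP convention {convention!r}")


def compute_csp(
    series: TitrationSeries,
    endpoint_ratio: float | None = None,
    threshold: float = DEFAULT_CSP_THRESHOLD,
    lobes: LobeMap = LobeMap(),
    convention: str = "pooled",
) -> CSPProfile:
    """Per-residue CSP between the reference (ratio 0) and an endpoint ratio.

    The endpoint defaults to the highest ratio present.  Residues missing
    from either spectrum (prolines, exchange-broadened amides) are omitted
    with a warning, never imputed.
    """
    if endpoint_ratio is None:
        endpoint_ratio = series.ratios[-1]
    reference = series.point_at(0.0)
    endpoint = series.point_at(endpoint_ratio)
    shared = sorted(reference.peaks.keys() & endpoint.peaks.keys())
    missing = sorted(reference.peaks.keys() ^ endpoint.peaks.keys())
    if missing:
        warnings.warn(
            f"residues missing at reference or endpoint, omitted: {missing}",
            stacklevel=2,
        )
    entries = []
    for res in shared:
        ref, end = reference.peaks[res], endpoint.peaks[res]
        csp = csp_value(end.h_shift - ref.h_shift, end.n_shift - ref.n_shift, convention)
        entries.append(
            CSPEntry(
                residue=res,
                csp=csp,
                significant=csp >= threshold,
                lobe=lobes.lobe_of(res),
            )
        )
    return CSPProfile(entries=entries)


def significant_residues(
    profile: CSPProfile, threshold: float = DEFAULT_CSP_THRESHOLD
) -> set[int]:
    """Residues with CSP ≥ threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    return {e.residue for e in profile.entries if e.csp >= threshold}


@dataclass(frozen=True)
class LobeSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    majority: str | None


def lobe_summary(profile: CSPProfile, lobes: LobeMap = LobeMap()) -> LobeSummary:
    """Count significant residues per lobe and name the majority lobe.

    Fractions are relative to each lobe's total residue count in the lobe
    map.  With no significant residues the majority is undefined (None).
    """
    counts = {name: 0 for name in LOBE_NAMES}
    for e in profile.entries:
        lobe = lobes.lobe_of(e.residue)  # raises if outside all ranges
        if e.significant:
            counts[lobe] += 1
    fractions = {name: counts[name] / lobes.size(name) for name in LOBE_NAMES}
    total = sum(counts.values())
    majority = max(counts, key=lambda n: counts[n]) if total else None
    return LobeSummary(counts=counts, fractions=fractions, majority=majority)
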