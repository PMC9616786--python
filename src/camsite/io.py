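"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

- chemical shifts: NMR-STAR v3 (the assigned-chemical-shift loop only) or a
  TSV dialect with header ``residue  aa  atom  shift_ppm``;
- HSQC peak lists: TSV ``residue  h_ppm  n_ppm``, one file per titration
  point, tied together by a manifest TSV ``ratio  path``;
- sensorgrams: CSV ``time_s,response_ru`` with ``# conc_M=`` / ``# cell=``
  metadata header lines; equilibrium sets: CSV ``conc_M,req_ru``;
- sequences and alignments: FASTA (gaps as ``-``), via Biopython;
- allelic variants: TSV ``residue  ref  alt  frequency  source``.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import IO, Iterable

import numpy as np
from Bio import SeqIO

from .chemshift import VALID_ATOMS, ShiftEntry, ShiftTable
from .errors import ParseError
from .motifs import SequenceRecord, VariantRow, VariantTable
from .spr import EquilibriumBindingSet, Sensorgram
from .titration import Peak, TitrationPoint, TitrationSeries

logger = logging.getLogger(__name__)

# three-letter -> one-letter residue codes, as used in NMR-STAR Comp_ID
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _as_lines(source) -> list[str]:
    if isinstance(source, (str, Path)):
        return Path(source).read_text().splitlines()
    return source.read().splitlines()


def load_shift_table(
    source: str | Path | IO[str],
    dialect: str,
    molecule_id: str = "",
    condition: str = "",
) -> ShiftTable:
    """Read a chemical-shift table in the named dialect ('nmrstar' or 'tsv').

    Atoms other than HA/CA/N/H are skipped with a logged warning.  Duplicate
    (residue, atom) pairs and malformed lines raise.
    """
    lines = _as_lines(source)
    if not any(line.strip() for line in lines):
        raise ParseError("empty stream")
    if dialect == "tsv":
        entries = _parse_shift_tsv(lines)
    elif dialect == "nmrstar":
        entries = _parse_shift_nmrstar(lines)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    return ShiftTable(molecule_id=molecule_id, condition=condition, entries=entries)


def _normalise_aa(code: str, line: int) -> str:
    code = code.strip().upper()
    if len(code) == 1:
        return code
    try:
        return THREE_TO_ONE[code]
    except KeyError:
        raise ParseError(f"unknown residue type {code!r}", line) from None


def _parse_shift_tsv(lines: list[str]) -> list[ShiftEntry]:
    entries = []
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 tab-separated fields, got {len(fields)}", lineno)
        res_s, aa, atom, shift_s = fields
        try:
            residue, shift = int(res_s), float(shift_s)
        except ValueError:
            raise ParseError(f"non-numeric residue or shift: {line!r}", lineno) from None
        atom = atom.strip().upper()
        if atom not in VALID_ATOMS:
            logger.warning("line %d: skipping unknown atom %r", lineno, atom)
            continue
        entries.append(ShiftEntry(residue=residue, aa=_normalise_aa(aa, lineno),
                                  atom=atom, shift=shift))
    return entries


def _parse_shift_nmrstar(lines: list[str]) -> list[ShiftEntry]:
    """Minimal reader for the NMR-STAR v3 _Atom_chem_shift loop.

    Understands only what the assigned-chemical-shift loop needs: ``loop_``
    blocks, ``_Atom_chem_shift.*`` tag headers and whitespace-separated value
    rows terminated by ``stop_``.  Everything else in the file is skipped.
    """
    wanted = {"Seq_ID", "Comp_ID", "Atom_ID", "Val"}
    # locate a loop whose tags include the _Atom_chem_shift columns
    i, n = 0, len(lines)
    while i < n:
        if lines[i].strip().lower() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                cols = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}
                missing = wanted - cols.keys()
                if missing:
                    raise ParseError(
                        f"_Atom_chem_shift loop lacks columns {sorted(missing)}", j
                    )
                return _parse_star_rows(lines, j, len(tags), cols)
        i += 1
    raise ParseError("no _Atom_chem_shift loop found")


def _parse_star_rows(
    lines: list[str], start: int, ncols: int, cols: dict[str, int]
) -> list[ShiftEntry]:
    entries = []
    for lineno in range(start, len(lines)):
        stripped = lines[lineno].strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.lower() in {"stop_", "save_"}:
            break
        values = stripped.split()
        if len(values) != ncols:
            raise ParseError(
                f"expected {ncols} values in loop row, got {len(values)}", lineno + 1
            )
        atom = values[cols["Atom_ID"]].upper()
        if atom not in VALID_ATOMS:
            logger.warning("line %d: skipping atom %r", lineno + 1, atom)
            continue
        try:
            residue = int(values[cols["Seq_ID"]])
            shift = float(values[cols["Val"]])
        except ValueError:
            raise ParseError(f"non-numeric Seq_ID or Val in {stripped!r}", lineno + 1) from None
        entries.append(
            ShiftEntry(
                residue=residue,
                aa=_normalise_aa(values[cols["Comp_ID"]], lineno + 1),
                atom=atom,
                shift=shift,
            )
        )
    return entries


def read_peak_list(source: str | Path | IO[str]) -> dict[int, Peak]:
    """TSV peak list ``residue  h_ppm  n_ppm`` -> residue -> Peak."""
    peaks: dict[int, Peak] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        if lineno == 1 or not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 fields, got {len(fields)}", lineno)
        try:
            residue, h, nshift = int(fields[0]), float(fields[1]), float(fields[2])
        except ValueError:
            raise ParseError(f"non-numeric peak row {line!r}", lineno) from None
        if residue in peaks:
            raise ParseError(f"duplicate residue {residue} in peak list", lineno)
        peaks[residue] = Peak(h_shift=h, n_shift=nshift)
    return peaks


def read_titration_manifest(path: str | Path, protein_id: str = "") -> TitrationSeries:
    """Manifest TSV ``ratio  path`` (paths relative to the manifest)."""
    path = Path(path)
    points = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if lineno == 1 or not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"expected 'ratio<TAB>path', got {line!r}", lineno)
        ratio = float(fields[0])
        peaks = read_peak_list(path.parent / fields[1])
        points.append(TitrationPoint(ratio=ratio, peaks=peaks))
    points.sort(key=lambda p: p.ratio)
    return TitrationSeries(protein_id=protein_id or path.stem, points=points)


def read_sensorgram_csv(source: str | Path | IO[str]) -> Sensorgram:
    """CSV ``time_s,response_ru`` with ``# conc_M=`` / ``# cell=`` headers."""
    conc, cell = float("nan"), "sample"
    times, resp = [], []
    lines = _as_lines(source)
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            meta = stripped.lstrip("#").strip()
            if meta.startswith("conc_M="):
                conc = float(meta.split("=", 1)[1])
            elif meta.startswith("cell="):
                cell = meta.split("=", 1)[1].strip()
            continue
        if stripped.lower().startswith("time_s"):
            continue
        parts = stripped.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected 'time_s,response_ru', got {line!r}", lineno)
        times.append(float(parts[0]))
        resp.append(float(parts[1]))
    if not times:
        raise ParseError("sensorgram has no data rows")
    return Sensorgram(analyte_conc=conc, times=np.asarray(times),
                      response=np.asarray(resp), cell=cell)


def write_sensorgram_csv(sg: Sensorgram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# conc_M={sg.analyte_conc!r}\n# cell={sg.cell}\ntime_s,response_ru\n")
        for t, r in zip(sg.times, sg.response):
            fh.write(f"{t},{r}\n")


def read_equilibrium_csv(
    source: str | Path | IO[str], ligand_id: str = ""
) -> EquilibriumBindingSet:
    """CSV ``conc_M,req_ru``; replicate rows allowed."""
    concs, reqs = [], []
    for lineno, line in enumerate(_as_lines(source), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or stripped.lower().startswith("conc_m"):
            continue
        parts = stripped.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected 'conc_M,req_ru', got {line!r}", lineno)
        concs.append(float(parts[0]))
        reqs.append(float(parts[1]))
    if not concs:
        raise ParseError("equilibrium set has no data rows")
    return EquilibriumBindingSet(
        concentrations=np.asarray(concs), responses=np.asarray(reqs), ligand_id=ligand_id
    )


def write_equilibrium_csv(data: EquilibriumBindingSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("conc_M,req_ru\n")
        for c, r in zip(data.concentrations, data.responses):
            fh.write(f"{c},{r}\n")


def read_fasta(
    source: str | Path | IO[str], first_residue_number: int = 1
) -> list[SequenceRecord]:
    """FASTA (plain or aligned, '-' gaps) -> SequenceRecords.

    ``first_residue_number`` applies to every record — appropriate for
    peptide alignments that all start at the same full-length position.
    """
    handle = _io.StringIO(Path(source).read_text()) if isinstance(source, (str, Path)) else source
    return [
        SequenceRecord(
            id=rec.id, sequence=str(rec.seq), first_residue_number=first_residue_number
        )
        for rec in SeqIO.parse(handle, "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_variant_table(source: str | Path | IO[str]) -> VariantTable:
    """TSV ``residue  ref  alt  frequency  source`` -> VariantTable."""
    rows = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        if lineno == 1 or not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"expected 5 fields, got {len(fields)}", lineno)
        try:
            rows.append(
                VariantRow(
                    residue=int(fields[0]),
                    ref=fields[1].strip().upper(),
                    alt=fields[2].strip().upper(),
                    frequency=float(fields[3]),
                    source_db=fields[4].strip(),
                )
            )
        except ValueError as exc:
            raise ParseError(f"bad variant row {line!r}: {exc}", lineno) from None
    return VariantTable(rows=rows)
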