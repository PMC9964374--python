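"""Readers and writers for the formats the pipeline touches.

FASTA (plain and aligned), TSV tables with a header row, and the PDB v3.3
ATOM-record subset needed for backbone geometry and per-residue confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/rare letters accepted at ingest (X, B, Z, U).
AMBIGUOUS_AA = "XBZU"
VALID_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA)


class SeqIOError(ValueError):
    """Raised for malformed sequence, table, or structure input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein as it flows through the funnel."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record must have a non-empty id")
        if not self.sequence:
            raise SeqIOError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """An ingested multiple sequence alignment (gaps as '-')."""

    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment must contain at least one sequence")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise SeqIOError(
                f"alignment sequences have unequal lengths: {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    def column(self, index: int) -> str:
        """Residues of 1-based column *index*, one per sequence."""
        return "".join(r.sequence[index - 1] for r in self.records)


@dataclass
class Residue:
    """One residue of a parsed structure; coordinates in Å, or None if absent."""

    chain: str
    number: int
    name: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None
    confidence: float = 0.0

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def confidences(self) -> list[float]:
        return [r.confidence for r in self.residues]


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq.rstrip("*")
    if "*" in seq:
        warnings.warn(
            f"record {rec_id!r}: internal stop character(s) stripped", stacklevel=3
        )
        seq = seq.replace("*", "")
    for pos, letter in enumerate(seq, start=1):
        if letter not in VALID_AA:
            raise SeqIOError(
                f"record {rec_id!r}: invalid amino-acid character "
                f"{letter!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated, upper-cased :class:`ProteinRecord`\\ s.

    Raises :class:`SeqIOError` on duplicate ids, empty sequences, or
    characters outside the 20 standard residues plus X/B/Z/U.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise SeqIOError(f"empty sequence for record {rec.id!r}")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; all sequences must have equal length."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, letter in enumerate(seq, start=1):
            if letter != "-" and letter not in VALID_AA:
                raise SeqIOError(
                    f"record {rec.id!r}: invalid alignment character "
                    f"{letter!r} at column {pos}"
                )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise SeqIOError(f"no sequences in alignment file {path}")
    return Alignment(records=tuple(records))


def read_table(
    path: str | Path,
    required_columns: Sequence[str],
    numeric_columns: Sequence[str] = (),
) -> list[dict]:
    """Read a header-bearing TSV into row dicts.

    ``numeric_columns`` are converted to float; a cell that fails conversion
    raises :class:`SeqIOError` naming the (1-based data) row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise SeqIOError(f"empty table {path}")
        header = header_line.split("\t")
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise SeqIOError(f"{path}: missing required column(s) {missing}")
        rows: list[dict] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise SeqIOError(
                    f"{path}: row {lineno} has {len(cells)} cells, "
                    f"expected {len(header)}"
                )
            row = dict(zip(header, cells))
            for col in numeric_columns:
                if col not in row:
                    continue
                try:
                    row[col] = float(row[col])
                except ValueError:
                    raise SeqIOError(
                        f"{path}: unparseable numeric value {row[col]!r} "
                        f"in row {lineno}, column {col!r}"
                    ) from None
            rows.append(row)
    return rows


def write_table(rows: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


_BACKBONE = {"N": "n", "CA": "ca", "C": "c"}


def read_structure(path: str | Path) -> Structure:
    """Parse PDB v3.3 ATOM records into a backbone-only :class:`Structure`.

    Only the first model and the first alternate location are read.  Residue
    confidence is taken from the B-factor field (the AlphaFold convention).
    Residues missing any of N/CA/C stay in the structure flagged incomplete.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = Structure()
    current: Residue | None = None
    last_number: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag == "ENDMDL":
                break
            if tag != "ATOM  ":
                continue
            try:
                atom = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                bfac = float(line[60:66])
            except (ValueError, IndexError):
                raise SeqIOError(
                    f"{path}: malformed ATOM record at line {lineno}"
                ) from None
            if altloc not in (" ", "A"):
                continue
            if chain in last_number and resnum < last_number[chain]:
                raise SeqIOError(
                    f"{path}: residue numbers not increasing in chain "
                    f"{chain!r} at line {lineno}"
                )
            if current is None or current.chain != chain or current.number != resnum:
                current = Residue(chain=chain, number=resnum, name=resname, confidence=bfac)
                structure.residues.append(current)
                last_number[chain] = resnum
            if atom in _BACKBONE and getattr(current, _BACKBONE[atom]) is None:
                setattr(current, _BACKBONE[atom], np.array([x, y, z]))
    if not structure.residues:
        raise SeqIOError(f"{path}: no ATOM records")
    return structure


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{num:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write backbone atoms back out as PDB v3.3 ATOM records."""
    serial = 1
    with open(path, "w") as fh:
        for res in structure.residues:
            for atom_name, attr in _BACKBONE.items():
                coord = getattr(res, attr)
                if coord is None:
                    continue
                fh.write(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=atom_name,
                        alt=" ",
                        res=res.name,
                        chain=res.chain,
                        num=res.number,
                        icode=" ",
                        x=coord[0],
                        y=coord[1],
                        z=coord[2],
                        occ=1.0,
                        b=res.confidence,
                        elem=atom_name[0],
                    )
                )
                serial += 1
        fh.write("END\n")
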