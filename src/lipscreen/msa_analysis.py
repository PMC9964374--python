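"""Family-alignment analysis: column conservation, gap-aware motif mapping,
catalytic-partner candidates and oxyanion-hole typing.

All reported positions are 1-based alignment-column positions (gap-inclusive).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from lipscreen.motif_scan import MotifHit
from lipscreen.seqio import Alignment

DEFAULT_CONSERVATION_THRESHOLD = 0.8
DEFAULT_OXYANION_WINDOW = 300

OXYANION_TYPES = ("GX", "GGGX", "GDSL-type", "Y", "unknown")


@dataclass(frozen=True)
class ColumnConservation:
    column: int  # 1-based
    modal_residue: str
    fraction: float
    gap_fraction: float
    highlighted: bool


@dataclass
class CatalyticAssignment:
    """Candidate catalytic columns downstream of the serine, with conservation.

    Deliberately lists candidates rather than electing "the" triad; weakly
    conserved candidates appear with ``below_threshold`` flags so they stay
    visible.
    """

    serine_column: int
    acidic_candidates: list[tuple[int, str, float]]  # (column, residue, conservation)
    histidine_candidates: list[tuple[int, str, float]]
    below_threshold: list[tuple[int, str, float]]


def column_conservation(
    alignment: Alignment,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    count_gaps: bool = False,
) -> list[ColumnConservation]:
    """Per-column modal residue and its fraction.

    Gaps are excluded from the denominator unless ``count_gaps`` is set.
    A column is highlighted when its fraction strictly exceeds *threshold*.
    All-gap columns get fraction 0 and modal residue '-'.
    """
    n_rows = len(alignment.records)
    out = []
    for col in range(1, alignment.n_columns + 1):
        residues = alignment.column(col)
        non_gap = residues.replace("-", "")
        gap_fraction = (n_rows - len(non_gap)) / n_rows
        if not non_gap:
            out.append(ColumnConservation(col, "-", 0.0, 1.0, False))
            continue
        counts = Counter(non_gap)
        # ties broken alphabetically so results never depend on row order
        modal = min(counts, key=lambda aa: (-counts[aa], aa))
        count = counts[modal]
        denominator = n_rows if count_gaps else len(non_gap)
        fraction = count / denominator
        out.append(
            ColumnConservation(col, modal, fraction, gap_fraction, fraction > threshold)
        )
    return out


def ungapped_to_column(gapped_sequence: str, position: int) -> int:
    """1-based ungapped position -> 1-based alignment column."""
    seen = 0
    for col, letter in enumerate(gapped_sequence, start=1):
        if letter != "-":
            seen += 1
            if seen == position:
                return col
    raise IndexError(
        f"ungapped position {position} beyond sequence of {seen} residues"
    )


def column_to_ungapped(gapped_sequence: str, column: int) -> int:
    """1-based alignment column -> 1-based ungapped position."""
    if column < 1 or column > len(gapped_sequence):
        raise IndexError(f"column {column} outside alignment of {len(gapped_sequence)}")
    if gapped_sequence[column - 1] == "-":
        raise ValueError(f"column {column} is a gap in this sequence")
    return len(gapped_sequence[:column].replace("-", ""))


def map_motif_to_columns(
    alignment: Alignment, hits: dict[str, MotifHit]
) -> dict[str, list[int]]:
    """Lift per-sequence motif hits (ungapped coordinates) to column indices."""
    by_id = {r.id: r.sequence for r in alignment.records}
    out: dict[str, list[int]] = {}
    for pid, hit in hits.items():
        gapped = by_id[pid]
        out[pid] = [
            ungapped_to_column(gapped, hit.start + offset)
            for offset in range(len(hit.matched))
        ]
    return out


def find_catalytic_partners(
    alignment: Alignment,
    serine_column: int,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> CatalyticAssignment:
    """List conserved D/E and H columns downstream of the catalytic serine.

    Columns whose modal residue is D/E or H but whose conservation does not
    exceed the threshold are reported under ``below_threshold``.
    """
    conservation = column_conservation(alignment, threshold)
    acidic, histidine, weak = [], [], []
    for col in conservation[serine_column:]:  # columns after the serine
        if col.modal_residue in ("D", "E"):
            entry = (col.column, col.modal_residue, col.fraction)
            (acidic if col.highlighted else weak).append(entry)
        elif col.modal_residue == "H":
            entry = (col.column, col.modal_residue, col.fraction)
            (histidine if col.highlighted else weak).append(entry)
    return CatalyticAssignment(
        serine_column=serine_column,
        acidic_candidates=acidic,
        histidine_candidates=histidine,
        below_threshold=weak,
    )


def classify_oxyanion(
    alignment: Alignment,
    serine_column: int,
    family: str,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    window: int = DEFAULT_OXYANION_WINDOW,
) -> tuple[str, str]:
    """(oxyanion type, X residue) from the conserved region upstream of the serine.

    GDSL family short-circuits to "GDSL-type".  Otherwise a conserved
    G-G-G-X run upstream of the serine gives GGGX, a conserved G-X pair
    gives GX; the nearest match to the serine wins.  No conserved match
    gives "unknown" (the Y type has no published detection rule).
    """
    if family == "GDSL lipase":
        return "GDSL-type", ""
    conservation = column_conservation(alignment, threshold)
    start = max(0, serine_column - 1 - window)
    region = conservation[start : serine_column - 1]
    # nearest-first search upstream of the serine
    for i in range(len(region) - 1, -1, -1):
        cols = region[i : i + 4]
        if (
            len(cols) == 4
            and all(c.highlighted for c in cols)
            and cols[0].modal_residue == "G"
            and cols[1].modal_residue == "G"
            and cols[2].modal_residue == "G"
            and cols[3].modal_residue != "G"
        ):
            return "GGGX", cols[3].modal_residue
    for i in range(len(region) - 2, -1, -1):
        first, second = region[i], region[i + 1]
        if (
            first.highlighted
            and second.highlighted
            and first.modal_residue == "G"
            and second.modal_residue != "G"
        ):
            return "GX", second.modal_residue
    return "unknown", ""


def conservation_rows(conservation: list[ColumnConservation]) -> list[dict]:
    return [
        {
            "column": c.column,
            "modal_residue": c.modal_residue,
            "fraction": round(c.fraction, 4),
            "gap_fraction": round(c.gap_fraction, 4),
            "highlighted": int(c.highlighted),
        }
        for c in conservation
    ]


def render_highlighted(alignment: Alignment, threshold: float = 0.8, width: int = 60) -> str:
    """Plain-text rendering with a marker line under conserved columns."""
    conservation = column_conservation(alignment, threshold)
    marks = "".join("*" if c.highlighted else " " for c in conservation)
    lines = []
    for block in range(0, alignment.n_columns, width):
        for rec in alignment.records:
            lines.append(f"{rec.id:<20s} {rec.sequence[block : block + width]}")
        lines.append(f"{'':<20s} {marks[block : block + width]}")
        lines.append("")
    return "\n".join(lines)
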