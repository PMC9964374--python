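"""Sequence-motif detection: catalytic pentapeptide, GDS(L), targeting signals.

All grammars are exact residue-class patterns; wildcard positions ("X") match
only the 20 standard amino acids, never ambiguity letters, because catalytic
context positions must be real residues.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from lipscreen.seqio import STANDARD_AA, ProteinRecord

#: X₂ residues counted as hydrophobic in pentapeptide summaries.
HYDROPHOBIC_X2 = frozenset("ILMVA")

_X = f"[{STANDARD_AA}]"


@dataclass(frozen=True)
class MotifPattern:
    """A named residue-class grammar with an anchoring rule."""

    name: str
    pattern: str
    anchor: str = "anywhere"  # anywhere | cterm | nterm


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based
    matched: str
    x1: str = ""
    x2: str = ""
    flags: tuple[str, ...] = field(default=())

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags


#: Registry of every grammar the pipeline scans for.
PATTERNS: dict[str, MotifPattern] = {
    "pentapeptide": MotifPattern("pentapeptide", f"G{_X}S{_X}G"),
    "gdsl": MotifPattern("gdsl", "GDS"),
    "dileucine_exxxll": MotifPattern("dileucine_exxxll", f"[DE]{_X}{_X}{_X}L[LI]"),
    "dileucine_dxxll": MotifPattern("dileucine_dxxll", f"D{_X}{_X}LL"),
    "er_retention": MotifPattern("er_retention", "[KD][DE]EL", anchor="cterm"),
    "pts1": MotifPattern("pts1", "[SAC][KRH][LM]", anchor="cterm"),
    "pts2": MotifPattern("pts2", "SSL", anchor="cterm"),
}


def _overlapping_matches(pattern: str, sequence: str):
    return re.finditer(f"(?=({pattern}))", sequence)


def scan_pentapeptide(record: ProteinRecord) -> list[MotifHit]:
    """Report every G-X-S-X-G window, including overlapping ones, by start."""
    hits = []
    for m in _overlapping_matches(PATTERNS["pentapeptide"].pattern, record.sequence):
        matched = m.group(1)
        hits.append(
            MotifHit(
                protein_id=record.id,
                motif="pentapeptide",
                start=m.start() + 1,
                matched=matched,
                x1=matched[1],
                x2=matched[3],
            )
        )
    return hits


def scan_gdsl(record: ProteinRecord, nterm_fraction: float = 0.25) -> list[MotifHit]:
    """Report GDS tri-residue matches with N-terminal and L-extension flags.

    A hit is flagged ``nterm`` when its start lies within the first
    ``nterm_fraction`` of the sequence (never less than 10 residues, so
    short toy sequences behave sensibly), and ``l_extended`` when the
    residue following the match is a leucine.
    """
    hits = []
    seq = record.sequence
    window = max(10.0, nterm_fraction * len(seq))
    for m in _overlapping_matches("GDS", seq):
        start = m.start() + 1
        flags = []
        if start <= window:
            flags.append("nterm")
        if m.start() + 3 < len(seq) and seq[m.start() + 3] == "L":
            flags.append("l_extended")
        hits.append(
            MotifHit(
                protein_id=record.id,
                motif="gdsl",
                start=start,
                matched="GDS",
                flags=tuple(flags),
            )
        )
    return hits


def scan_targeting_signals(
    record: ProteinRecord, pts2_anchor: str = "cterm"
) -> list[MotifHit]:
    """Scan targeting-signal grammars.

    Di-leucine motifs ([D/E]XXXL[L/I], DXXLL) are reported anywhere in the
    sequence.  ER retention ([K/D][D/E]EL), PTS1 ([S/A/C][K/R/H][L/M]) and
    PTS2 (SSL) fire only when the terminal residues match.  ``pts2_anchor``
    may be set to ``"nterm"`` to search SSL in the first 25% of the sequence
    instead of at the C-terminus.
    """
    seq = record.sequence
    hits: list[MotifHit] = []
    for name in ("dileucine_exxxll", "dileucine_dxxll"):
        for m in _overlapping_matches(PATTERNS[name].pattern, seq):
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    motif=name,
                    start=m.start() + 1,
                    matched=m.group(1),
                )
            )
    for name in ("er_retention", "pts1", "pts2"):
        if name == "pts2" and pts2_anchor == "nterm":
            window = max(3, int(0.25 * len(seq)))
            for m in _overlapping_matches("SSL", seq[:window]):
                hits.append(
                    MotifHit(
                        protein_id=record.id,
                        motif=name,
                        start=m.start() + 1,
                        matched="SSL",
                        flags=("nterm",),
                    )
                )
            continue
        pat = PATTERNS[name]
        length = 4 if name == "er_retention" else 3
        if len(seq) < length:
            continue
        tail = seq[-length:]
        if re.fullmatch(pat.pattern, tail):
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    motif=name,
                    start=len(seq) - length + 1,
                    matched=tail,
                    flags=("cterm",),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def first_hit_per_protein(hits: list[MotifHit]) -> list[MotifHit]:
    """Keep the first hit (by position) of each protein."""
    best: dict[str, MotifHit] = {}
    for hit in hits:
        if hit.protein_id not in best or hit.start < best[hit.protein_id].start:
            best[hit.protein_id] = hit
    return [best[k] for k in best]


def summarize_pentapeptide_variants(hits: list[MotifHit]) -> dict:
    """Frequencies of X₁/X₂ residues and the hydrophobic-X₂ fraction.

    Expects one retained pentapeptide hit per protein (see
    :func:`first_hit_per_protein`).  Returns an empty summary for no hits.
    """
    if not hits:
        return {"x1": {}, "x2": {}, "hydrophobic_x2_fraction": None, "n": 0}
    n = len(hits)
    x1_counts = Counter(h.x1 for h in hits)
    x2_counts = Counter(h.x2 for h in hits)
    hydro = sum(1 for h in hits if h.x2 in HYDROPHOBIC_X2)
    return {
        "x1": {aa: c / n for aa, c in sorted(x1_counts.items())},
        "x2": {aa: c / n for aa, c in sorted(x2_counts.items())},
        "hydrophobic_x2_fraction": hydro / n,
        "n": n,
    }


def hits_to_rows(hits: list[MotifHit]) -> list[dict]:
    """Flatten hits for TSV export."""
    return [
        {
            "protein": h.protein_id,
            "motif": h.motif,
            "start": h.start,
            "match": h.matched,
            "x1": h.x1,
            "x2": h.x2,
            "flags": ",".join(h.flags),
        }
        for h in hits
    ]
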