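"""Physico-chemical descriptor panel (ProtParam conventions).

Molecular weight, charge counts, extinction coefficients, isoelectric point,
instability index, aliphatic index, GRAVY and N-end-rule half-life, with the
usual classification thresholds (instability 40, aliphatic 80).

Residue-level constant tables (average masses, Kyte-Doolittle hydropathies,
Guruprasad dipeptide instability weights) are taken from Biopython's
published-data modules; the Bjellqvist pKa set and the N-end-rule half-life
table are embedded below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights as _RESIDUE_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KD

from lipscreen.seqio import STANDARD_AA, ProteinRecord

_WATER = 18.0153  # average mass of one water molecule, Da

# Bjellqvist pKa values used by the ProtParam server.
_PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_NTERM_DEFAULT = 7.5
_PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PKA_CTERM_DEFAULT = 3.55
_PKA_CTERM = {"D": 4.55, "E": 4.75}

# N-end-rule half-life labels, keyed by organism then N-terminal residue.
_HALF_LIFE = {
    "mammalian": {
        "A": "4.4 h", "R": "1 h", "N": "1.4 h", "D": "1.1 h", "C": "1.2 h",
        "Q": "0.8 h", "E": "1 h", "G": "30 h", "H": "3.5 h", "I": "20 h",
        "L": "5.5 h", "K": "1.3 h", "M": "30 h", "F": "1.1 h", "P": ">20 h",
        "S": "1.9 h", "T": "7.2 h", "W": "2.8 h", "Y": "2.8 h", "V": "100 h",
    },
    "yeast": {
        "A": ">20 h", "R": "2 min", "N": "3 min", "D": "3 min", "C": ">20 h",
        "Q": "10 min", "E": "30 min", "G": ">20 h", "H": "10 min", "I": "30 min",
        "L": "3 min", "K": "3 min", "M": ">20 h", "F": "3 min", "P": ">20 h",
        "S": ">20 h", "T": ">20 h", "W": "3 min", "Y": "10 min", "V": ">20 h",
    },
    "bacterial": {
        "A": ">10 h", "R": "2 min", "N": ">10 h", "D": ">10 h", "C": ">10 h",
        "Q": ">10 h", "E": ">10 h", "G": ">10 h", "H": ">10 h", "I": ">10 h",
        "L": "2 min", "K": "2 min", "M": ">10 h", "F": "2 min", "P": "unknown",
        "S": ">10 h", "T": ">10 h", "W": "2 min", "Y": "2 min", "V": ">10 h",
    },
}

INSTABILITY_THRESHOLD = 40.0
ALIPHATIC_THRESHOLD = 80.0


class AmbiguousResidueError(ValueError):
    """Raised in strict mode when a sequence carries X/B/Z/U."""


def _prepare(sequence: str, mode: str) -> str:
    """Validate and, in lenient mode, drop ambiguity letters with a warning."""
    if not sequence:
        raise ValueError("empty sequence")
    ambiguous = [aa for aa in sequence if aa not in STANDARD_AA]
    if ambiguous:
        if mode == "strict":
            raise AmbiguousResidueError(
                f"ambiguity letter(s) {sorted(set(ambiguous))} in sequence"
            )
        warnings.warn(
            f"{len(ambiguous)} ambiguity letter(s) excluded from descriptor",
            stacklevel=3,
        )
        sequence = "".join(aa for aa in sequence if aa in STANDARD_AA)
        if not sequence:
            raise ValueError("no standard residues left after removing ambiguity letters")
    return sequence


def molecular_weight(sequence: str, mode: str = "lenient") -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    seq = _prepare(sequence, mode)
    return sum(_RESIDUE_WEIGHTS[aa] for aa in seq) - (len(seq) - 1) * _WATER


def charge_counts(sequence: str) -> tuple[int, int]:
    """(#D + #E, #R + #K) — histidine is not counted, per ProtParam."""
    neg = sequence.count("D") + sequence.count("E")
    pos = sequence.count("R") + sequence.count("K")
    return neg, pos


def extinction_coefficient_280(sequence: str) -> tuple[int, int]:
    """Molar extinction at 280 nm (M⁻¹cm⁻¹): (reduced, all-cystine form)."""
    reduced = 5500 * sequence.count("W") + 1490 * sequence.count("Y")
    cystine = reduced + 125 * (sequence.count("C") // 2)
    return reduced, cystine


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at *ph* (termini + ionizable side chains)."""
    def positive(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def negative(pka: float) -> float:
        return -1.0 / (1.0 + 10 ** (pka - ph))

    charge = positive(_PKA_NTERM.get(sequence[0], _PKA_NTERM_DEFAULT))
    charge += negative(_PKA_CTERM.get(sequence[-1], _PKA_CTERM_DEFAULT))
    for aa, pka in _PKA_POSITIVE.items():
        charge += sequence.count(aa) * positive(pka)
    for aa, pka in _PKA_NEGATIVE.items():
        charge += sequence.count(aa) * negative(pka)
    return charge


def isoelectric_point(sequence: str, mode: str = "lenient", tol: float = 1e-3) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH so the root is unique.
    """
    seq = _prepare(sequence, mode)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(sequence: str, mode: str = "lenient") -> tuple[float, str]:
    """Guruprasad instability index and stable/unstable class at 40."""
    seq = _prepare(sequence, mode)
    if len(seq) < 2:
        raise ValueError("instability index undefined for sequences of length < 2")
    total = sum(_DIWV[a][b] for a, b in zip(seq, seq[1:]))
    value = (10.0 / len(seq)) * total
    return value, ("unstable" if value > INSTABILITY_THRESHOLD else "stable")


def aliphatic_index(sequence: str, mode: str = "lenient") -> tuple[float, bool]:
    """Ikai aliphatic index and thermostable flag at 80.

    AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile) + X(Leu)), X in mole percent.
    """
    seq = _prepare(sequence, mode)
    n = len(seq)
    value = (
        100.0 * seq.count("A") / n
        + 2.9 * 100.0 * seq.count("V") / n
        + 3.9 * 100.0 * (seq.count("I") + seq.count("L")) / n
    )
    return value, value > ALIPHATIC_THRESHOLD


def gravy(sequence: str, mode: str = "lenient") -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    seq = _prepare(sequence, mode)
    return sum(_KD[aa] for aa in seq) / len(seq)


def half_life_class(sequence: str, organism: str = "mammalian") -> str:
    """N-end-rule half-life label for the N-terminal residue."""
    try:
        table = _HALF_LIFE[organism]
    except KeyError:
        raise ValueError(
            f"unknown organism {organism!r}; expected one of {sorted(_HALF_LIFE)}"
        ) from None
    return table.get(sequence[0], "unknown")


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    molecular_weight: float
    n_negative: int
    n_positive: int
    extinction_280_reduced: int
    extinction_280_cystine: int
    isoelectric_point: float
    instability_index: float | None
    instability_class: str
    aliphatic_index: float
    thermostable: bool
    gravy: float
    half_life: str


def profile(
    record: ProteinRecord, organism: str = "mammalian", mode: str = "lenient"
) -> PhyschemProfile:
    """Compute the full descriptor panel for one protein."""
    seq = record.sequence
    neg, pos = charge_counts(seq)
    ext_red, ext_cys = extinction_coefficient_280(seq)
    if len(_prepare(seq, mode)) >= 2:
        ii, ii_class = instability_index(seq, mode)
    else:
        ii, ii_class = None, "undefined"
    ai, thermo = aliphatic_index(seq, mode)
    return PhyschemProfile(
        protein_id=record.id,
        length=len(seq),
        molecular_weight=molecular_weight(seq, mode),
        n_negative=neg,
        n_positive=pos,
        extinction_280_reduced=ext_red,
        extinction_280_cystine=ext_cys,
        isoelectric_point=isoelectric_point(seq, mode),
        instability_index=ii,
        instability_class=ii_class,
        aliphatic_index=ai,
        thermostable=thermo,
        gravy=gravy(seq, mode),
        half_life=half_life_class(seq, organism),
    )


def profile_rows(profiles: list[PhyschemProfile]) -> list[dict]:
    """Rows for TSV export, rounded at reporting precision (MW/pI 2, GRAVY 3)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "protein": p.protein_id,
                "length": p.length,
                "molecular_weight": round(p.molecular_weight, 2),
                "n_negative": p.n_negative,
                "n_positive": p.n_positive,
                "ext280_reduced": p.extinction_280_reduced,
                "ext280_cystine": p.extinction_280_cystine,
                "pI": round(p.isoelectric_point, 2),
                "half_life": p.half_life,
                "instability_index": "" if p.instability_index is None else round(p.instability_index, 2),
                "instability_class": p.instability_class,
                "aliphatic_index": round(p.aliphatic_index, 2),
                "thermostable": int(p.thermostable),
                "gravy": round(p.gravy, 3),
            }
        )
    return rows
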