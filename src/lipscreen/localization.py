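"""Rule-based subcellular localization from external-predictor tables plus
motif evidence, and lipid-modification site summaries.

The decision tree applies a fixed, configurable precedence:
plastid > mitochondrion > secretory (ER) > membrane (ER/cytosol) >
peroxisome > cytosol.  Vacuole is never emitted as a compartment; secretory
proteins carrying a di-leucine motif are flagged as vacuole candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from lipscreen.motif_scan import MotifHit

COMPARTMENTS = (
    "cytosol",
    "ER/cytosol",
    "ER",
    "chloroplast",
    "mitochondria",
    "mitochondria/peroxisome",
    "peroxisome",
)

DEFAULT_MITO_CUTOFF = 0.85


@dataclass(frozen=True)
class PredictorRow:
    """Combined external-predictor calls for one protein."""

    protein_id: str
    signal_peptide: bool
    plastid_positive: bool
    mito_score: float
    tm_count: int
    raw: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_score <= 1.0:
            raise ValueError(
                f"{self.protein_id}: mito_score {self.mito_score} outside [0, 1]"
            )
        if self.tm_count < 0:
            raise ValueError(f"{self.protein_id}: negative tm_count")


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    compartment: str
    evidence: tuple[str, ...]
    vacuole_candidate: bool = False


@dataclass(frozen=True)
class LipidSite:
    protein_id: str
    modification: str  # S-palmitoylation | N-myristoylation | prenylation | other-acylation
    position: int


def majority_vote(calls: list[bool]) -> bool:
    """Resolve multiple signal-peptide predictors: majority, ties positive."""
    if not calls:
        return False
    positive = sum(calls)
    return positive * 2 >= len(calls)


def decide_localization(
    predictors: PredictorRow,
    motifs: list[MotifHit],
    mito_cutoff: float = DEFAULT_MITO_CUTOFF,
) -> LocalizationCall:
    """Assign exactly one of the seven compartments."""
    motif_names = {m.motif for m in motifs}
    has_pts = bool({"pts1", "pts2"} & motif_names)
    has_dileucine = bool({"dileucine_exxxll", "dileucine_dxxll"} & motif_names)
    evidence: list[str] = []

    if predictors.plastid_positive:
        evidence.append("plastid predictor positive")
        return LocalizationCall(predictors.protein_id, "chloroplast", tuple(evidence))

    if predictors.mito_score >= mito_cutoff:
        evidence.append(f"mito score {predictors.mito_score:.2f} >= {mito_cutoff}")
        if has_pts:
            evidence.append("peroxisomal targeting signal")
            return LocalizationCall(
                predictors.protein_id, "mitochondria/peroxisome", tuple(evidence)
            )
        return LocalizationCall(predictors.protein_id, "mitochondria", tuple(evidence))

    if predictors.signal_peptide:
        evidence.append("signal peptide")
        if "er_retention" in motif_names:
            evidence.append("ER-retention signal")
        vacuole = has_dileucine
        if vacuole:
            evidence.append("di-leucine motif (vacuole candidate)")
        return LocalizationCall(
            predictors.protein_id, "ER", tuple(evidence), vacuole_candidate=vacuole
        )

    if predictors.tm_count >= 1:
        evidence.append(f"{predictors.tm_count} transmembrane segment(s)")
        return LocalizationCall(predictors.protein_id, "ER/cytosol", tuple(evidence))

    if has_pts:
        evidence.append("peroxisomal targeting signal")
        return LocalizationCall(predictors.protein_id, "peroxisome", tuple(evidence))

    evidence.append("no targeting evidence")
    return LocalizationCall(predictors.protein_id, "cytosol", tuple(evidence))


def decide_all(
    predictor_rows: dict[str, PredictorRow],
    motif_hits: dict[str, list[MotifHit]],
    protein_ids: list[str],
    mito_cutoff: float = DEFAULT_MITO_CUTOFF,
) -> list[LocalizationCall]:
    calls = []
    for pid in protein_ids:
        if pid not in predictor_rows:
            raise KeyError(f"no predictor row for protein {pid!r}")
        calls.append(
            decide_localization(
                predictor_rows[pid], motif_hits.get(pid, []), mito_cutoff
            )
        )
    return calls


def summarize_localization(calls: list[LocalizationCall]) -> dict[str, dict]:
    """Compartment counts and integer-rounded percentages."""
    if not calls:
        raise ValueError("no localization calls to summarize")
    counts = Counter(c.compartment for c in calls)
    total = len(calls)
    return {
        comp: {"count": counts.get(comp, 0), "percent": round(100 * counts.get(comp, 0) / total)}
        for comp in COMPARTMENTS
    }


def flag_vacuolar_candidates(calls: list[LocalizationCall]) -> list[str]:
    """Sorted ids of secretory proteins that also carry a di-leucine motif."""
    return sorted(c.protein_id for c in calls if c.vacuole_candidate)


def summarize_lipid_sites(sites: list[LipidSite]) -> dict:
    """Per-modification proportions, per-protein counts, and coverage."""
    per_protein = Counter(s.protein_id for s in sites)
    by_type = Counter(s.modification for s in sites)
    total = len(sites)
    max_count = max(per_protein.values()) if per_protein else 0
    return {
        "n_sites": total,
        "n_proteins_with_sites": len(per_protein),
        "type_proportions": {t: c / total for t, c in sorted(by_type.items())} if total else {},
        "sites_per_protein": dict(sorted(per_protein.items())),
        "max_site_proteins": sorted(p for p, c in per_protein.items() if c == max_count),
    }


def predictor_rows_from_table(rows: list[dict]) -> dict[str, PredictorRow]:
    """Build PredictorRows from a TSV row list.

    Expected columns: ``protein``, ``signal_peptide`` (0/1, or semicolon-
    separated 0/1 votes from several predictors), ``plastid_positive`` (0/1),
    ``mito_score`` (float), ``tm_count`` (int).
    """
    out: dict[str, PredictorRow] = {}
    for row in rows:
        sp_raw = str(row["signal_peptide"])
        if ";" in sp_raw:
            sp = majority_vote([bool(int(float(v))) for v in sp_raw.split(";")])
        else:
            sp = bool(int(float(sp_raw)))
        out[row["protein"]] = PredictorRow(
            protein_id=row["protein"],
            signal_peptide=sp,
            plastid_positive=bool(int(float(row["plastid_positive"]))),
            mito_score=float(row["mito_score"]),
            tm_count=int(float(row["tm_count"])),
            raw=dict(row),
        )
    return out


def lipid_sites_from_table(rows: list[dict]) -> list[LipidSite]:
    """Expected columns: ``protein``, ``modification``, ``position``."""
    return [
        LipidSite(
            protein_id=row["protein"],
            modification=row["modification"],
            position=int(float(row["position"])),
        )
        for row in rows
    ]


def calls_to_rows(calls: list[LocalizationCall]) -> list[dict]:
    return [
        {
            "protein": c.protein_id,
            "compartment": c.compartment,
            "vacuole_candidate": int(c.vacuole_candidate),
            "evidence": "; ".join(c.evidence),
        }
        for c in calls
    ]
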