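"""Stress-transcriptomics ranking: signed maximal regulation per gene across
datasets and timepoints, threshold classification, and candidate selection.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass

DEFAULT_BANDS = (1.0, 2.0)


@dataclass(frozen=True)
class RegulationObservation:
    gene: str
    dataset: str
    timepoint: str
    log2fc: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.gene}: non-finite log2 fold change")


@dataclass(frozen=True)
class RegulationSummary:
    gene: str
    max_signed_log2: float
    source_dataset: str
    source_timepoint: str
    direction: str  # up | down | flat
    band: str  # "|log2|<=1" | "1<|log2|<=2" | "|log2|>2"
    min_signed: float  # dispersion diagnostics across all observations
    max_signed: float
    ambiguous: bool = False  # opposite-sign tie on |log2fc|


def _band(value: float, thresholds: tuple[float, float] = DEFAULT_BANDS) -> str:
    low, high = thresholds
    mag = abs(value)
    if mag > high:
        return f"|log2|>{high:g}"
    if mag > low:
        return f"{low:g}<|log2|<={high:g}"
    return f"|log2|<={low:g}"


def _direction(value: float) -> str:
    if value > 0:
        return "up"
    if value < 0:
        return "down"
    return "flat"


def max_regulation(
    observations: list[RegulationObservation],
) -> dict[str, RegulationSummary]:
    """Signed value of maximal |log2fc| per gene.

    Opposite-sign ties in absolute value are flagged ambiguous and resolved
    toward the lexicographically earliest dataset label.
    """
    grouped: dict[str, list[RegulationObservation]] = defaultdict(list)
    seen: set[tuple[str, str, str]] = set()
    for obs in observations:
        key = (obs.gene, obs.dataset, obs.timepoint)
        if key in seen:
            raise ValueError(f"duplicate observation {key}")
        seen.add(key)
        grouped[obs.gene].append(obs)

    summaries: dict[str, RegulationSummary] = {}
    for gene, group in grouped.items():
        best_mag = max(abs(o.log2fc) for o in group)
        top = [o for o in group if abs(o.log2fc) == best_mag]
        ambiguous = len({o.log2fc > 0 for o in top}) > 1
        chosen = min(top, key=lambda o: (o.dataset, o.timepoint))
        signed = [o.log2fc for o in group]
        summaries[gene] = RegulationSummary(
            gene=gene,
            max_signed_log2=chosen.log2fc,
            source_dataset=chosen.dataset,
            source_timepoint=chosen.timepoint,
            direction=_direction(chosen.log2fc),
            band=_band(chosen.log2fc),
            min_signed=min(signed),
            max_signed=max(signed),
            ambiguous=ambiguous,
        )
    return summaries


def summarize_genes(
    observations: list[RegulationObservation], expected_genes: list[str] | None = None
) -> dict[str, RegulationSummary]:
    """Like :func:`max_regulation` but warns about expected genes with no data."""
    summaries = max_regulation(observations)
    if expected_genes:
        for gene in expected_genes:
            if gene not in summaries:
                warnings.warn(f"gene {gene!r} has no regulation observations", stacklevel=2)
    return summaries


def classify_regulation(
    summaries: dict[str, RegulationSummary],
    thresholds: tuple[float, float] = DEFAULT_BANDS,
) -> dict:
    """Direction counts overall and above each (strict) threshold, plus bands."""
    values = [s.max_signed_log2 for s in summaries.values()]
    low, high = thresholds
    counts = {
        "n": len(values),
        "up": sum(1 for v in values if v > 0),
        "down": sum(1 for v in values if v < 0),
        "flat": sum(1 for v in values if v == 0),
        f"up_gt_{low:g}": sum(1 for v in values if v > low),
        f"down_gt_{low:g}": sum(1 for v in values if v < -low),
        f"up_gt_{high:g}": sum(1 for v in values if v > high),
        f"down_gt_{high:g}": sum(1 for v in values if v < -high),
        "bands": {},
    }
    band_counts: dict[str, int] = {}
    for v in values:
        band = _band(v, thresholds)
        band_counts[band] = band_counts.get(band, 0) + 1
    counts["bands"] = band_counts
    return counts


def select_candidates(
    summaries: dict[str, RegulationSummary], threshold: float = 2.0
) -> list[RegulationSummary]:
    """Genes with |max signed log2| strictly above *threshold*.

    Sorted by descending absolute regulation, ties broken by gene id.
    """
    hits = [s for s in summaries.values() if abs(s.max_signed_log2) > threshold]
    hits.sort(key=lambda s: (-abs(s.max_signed_log2), s.gene))
    return hits


def observations_from_table(rows: list[dict]) -> list[RegulationObservation]:
    """Expected columns: ``gene``, ``dataset``, ``timepoint``, ``log2fc``."""
    return [
        RegulationObservation(
            gene=row["gene"],
            dataset=row["dataset"],
            timepoint=str(row["timepoint"]),
            log2fc=float(row["log2fc"]),
        )
        for row in rows
    ]


def summaries_to_rows(summaries: dict[str, RegulationSummary]) -> list[dict]:
    return [
        {
            "gene": s.gene,
            "max_signed_log2": round(s.max_signed_log2, 4),
            "direction": s.direction,
            "band": s.band,
            "source_dataset": s.source_dataset,
            "source_timepoint": s.source_timepoint,
            "min_signed": round(s.min_signed, 4),
            "max_signed": round(s.max_signed, 4),
            "ambiguous": int(s.ambiguous),
        }
        for s in sorted(summaries.values(), key=lambda s: s.gene)
    ]
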