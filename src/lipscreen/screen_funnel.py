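"""Candidate-retention funnel with a full per-protein audit trail.

Stages, in order: keyword query, annotation-significance filter (domain-hit
E-value), catalytic-motif requirement, functional-homology exclusion, family
assignment, and exclusion of family-specific inactive motifs (GDS→GDE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from lipscreen import motif_scan
from lipscreen.seqio import ProteinRecord

FAMILIES = (
    "alpha/beta hydrolase",
    "class 3 lipase",
    "GDSL lipase",
    "patatin-like phospholipase",
)

STAGES = (
    "keyword",
    "significance",
    "motif",
    "function",
    "family",
    "inactive_motif",
    "retained",
)

#: Default mapping from description/domain keywords to family, first match wins.
DEFAULT_FAMILY_RULES: tuple[tuple[str, str], ...] = (
    ("gdsl", "GDSL lipase"),
    ("patatin", "patatin-like phospholipase"),
    ("lipase_3", "class 3 lipase"),
    ("class 3", "class 3 lipase"),
    ("triacylglycerol lipase", "class 3 lipase"),
    ("abhydrolase", "alpha/beta hydrolase"),
    ("alpha/beta hydrolase", "alpha/beta hydrolase"),
)


@dataclass(frozen=True)
class AnnotationRow:
    """One protein's annotation evidence."""

    protein_id: str
    description: str = ""
    domain_hits: tuple[tuple[str, float], ...] = ()
    best_homolog_function: str = ""

    def __post_init__(self) -> None:
        for name, evalue in self.domain_hits:
            if evalue < 0:
                raise ValueError(
                    f"{self.protein_id}: negative E-value for domain {name!r}"
                )


@dataclass
class ScreenConfig:
    keywords: tuple[str, ...] = ("lipase", "phospholipase", "alpha/beta hydrolase")
    evalue_threshold: float = 1e-5
    excluded_functions: tuple[str, ...] = (
        "proline iminopeptidase",
        "pheophytinase",
    )
    forced_include: tuple[str, ...] = ()
    nterm_fraction: float = 0.25
    family_rules: tuple[tuple[str, str], ...] = DEFAULT_FAMILY_RULES

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("at least one query keyword is required")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


@dataclass
class ProteinOutcome:
    protein_id: str
    stage_reached: str = "retained"
    family: str = ""
    exclusion_reason: str = ""

    @property
    def retained(self) -> bool:
        return self.stage_reached == "retained"


@dataclass
class ScreenResult:
    outcomes: dict[str, ProteinOutcome] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def retained_ids(self) -> list[str]:
        return sorted(pid for pid, o in self.outcomes.items() if o.retained)

    def to_rows(self) -> list[dict]:
        return [
            {
                "protein": pid,
                "stage_reached": o.stage_reached,
                "family": o.family,
                "exclusion_reason": o.exclusion_reason,
            }
            for pid, o in sorted(self.outcomes.items())
        ]


def keyword_filter(
    annotations: list[AnnotationRow], config: ScreenConfig
) -> tuple[set[str], set[str]]:
    """(retained ids, forced-include ids among them)."""
    retained: set[str] = set()
    forced: set[str] = set()
    lowered = [kw.lower() for kw in config.keywords]
    for row in annotations:
        desc = row.description.lower()
        if any(kw in desc for kw in lowered):
            retained.add(row.protein_id)
        elif row.protein_id in config.forced_include:
            retained.add(row.protein_id)
            forced.add(row.protein_id)
    return retained, forced


def significance_filter(
    annotations: list[AnnotationRow], config: ScreenConfig
) -> set[str]:
    """Ids whose minimum domain-hit E-value is strictly below the threshold."""
    retained: set[str] = set()
    for row in annotations:
        if not row.domain_hits:
            continue
        if min(ev for _, ev in row.domain_hits) < config.evalue_threshold:
            retained.add(row.protein_id)
    return retained


def _family_hint(row: AnnotationRow, config: ScreenConfig) -> str:
    """Family by first matching rule over description then domain names."""
    haystacks = [row.description.lower()] + [name.lower() for name, _ in row.domain_hits]
    for keyword, family in config.family_rules:
        if any(keyword in h for h in haystacks):
            return family
    return ""


def motif_requirement_filter(
    records: dict[str, ProteinRecord],
    family_hints: dict[str, str],
    config: ScreenConfig,
) -> dict[str, str]:
    """Per-protein exclusion reason ('' = retained).

    Non-GDSL candidates need at least one G-X-S-X-G pentapeptide; GDSL
    candidates need a GDS motif carrying the catalytic serine.
    """
    reasons: dict[str, str] = {}
    for pid, record in records.items():
        if family_hints.get(pid) == "GDSL lipase":
            hits = motif_scan.scan_gdsl(record, config.nterm_fraction)
            reasons[pid] = "" if hits else "missing catalytic serine"
        else:
            hits = motif_scan.scan_pentapeptide(record)
            reasons[pid] = "" if hits else "no pentapeptide motif"
    return reasons


def function_exclusion_filter(
    annotations: list[AnnotationRow], config: ScreenConfig
) -> set[str]:
    """Ids retained: best-homolog function absent or not on the excluded list."""
    retained: set[str] = set()
    excluded = [f.lower() for f in config.excluded_functions]
    for row in annotations:
        function = row.best_homolog_function.strip().lower()
        if not function:
            warnings.warn(
                f"{row.protein_id}: no best-homolog function; retained",
                stacklevel=2,
            )
            retained.add(row.protein_id)
        elif any(excl in function for excl in excluded):
            continue
        else:
            retained.add(row.protein_id)
    return retained


def assign_family(row: AnnotationRow, config: ScreenConfig) -> str:
    """Family by rule table; unmatched proteins default to alpha/beta hydrolase."""
    family = _family_hint(row, config)
    if not family:
        warnings.warn(
            f"{row.protein_id}: no family rule matched; "
            "defaulting to alpha/beta hydrolase",
            stacklevel=2,
        )
        family = "alpha/beta hydrolase"
    return family


def run_screen(
    records: list[ProteinRecord],
    annotations: list[AnnotationRow],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Apply the funnel stages in order and return the audit trail."""
    config = config or ScreenConfig()
    record_map = {r.id: r for r in records}
    missing = [a.protein_id for a in annotations if a.protein_id not in record_map]
    if missing:
        raise KeyError(
            f"annotation rows without a sequence record: {sorted(missing)}"
        )
    ann_map = {a.protein_id: a for a in annotations}
    result = ScreenResult()
    for row in annotations:
        result.outcomes[row.protein_id] = ProteinOutcome(protein_id=row.protein_id)

    def live() -> list[str]:
        return [pid for pid, o in result.outcomes.items() if o.retained]

    result.stage_counts["input"] = len(annotations)

    kw_retained, _forced = keyword_filter(annotations, config)
    for pid in live():
        if pid not in kw_retained:
            result.outcomes[pid].stage_reached = "keyword"
            result.outcomes[pid].exclusion_reason = "no keyword"
    result.stage_counts["keyword"] = len(live())

    sig_retained = significance_filter([ann_map[p] for p in live()], config)
    for pid in live():
        if pid not in sig_retained:
            out = result.outcomes[pid]
            out.stage_reached = "significance"
            out.exclusion_reason = (
                "no annotation" if not ann_map[pid].domain_hits else "no significant annotation"
            )
    result.stage_counts["significance"] = len(live())

    hints = {pid: _family_hint(ann_map[pid], config) for pid in live()}
    motif_reasons = motif_requirement_filter(
        {pid: record_map[pid] for pid in live() if hints.get(pid) != "GDSL lipase"},
        hints,
        config,
    )
    for pid, reason in motif_reasons.items():
        if reason:
            result.outcomes[pid].stage_reached = "motif"
            result.outcomes[pid].exclusion_reason = reason
    result.stage_counts["motif"] = len(live())

    fn_retained = function_exclusion_filter([ann_map[p] for p in live()], config)
    for pid in live():
        if pid not in fn_retained:
            result.outcomes[pid].stage_reached = "function"
            result.outcomes[pid].exclusion_reason = (
                f"excluded function: {ann_map[pid].best_homolog_function}"
            )
    result.stage_counts["function"] = len(live())

    for pid in live():
        result.outcomes[pid].family = assign_family(ann_map[pid], config)
    result.stage_counts["family"] = len(live())

    gdsl_ids = [pid for pid in live() if result.outcomes[pid].family == "GDSL lipase"]
    gdsl_reasons = motif_requirement_filter(
        {pid: record_map[pid] for pid in gdsl_ids},
        {pid: "GDSL lipase" for pid in gdsl_ids},
        config,
    )
    for pid, reason in gdsl_reasons.items():
        if reason:
            out = result.outcomes[pid]
            out.stage_reached = "inactive_motif"
            out.exclusion_reason = reason
            out.family = ""
    result.stage_counts["retained"] = len(live())

    return result


def family_counts(result: ScreenResult) -> dict[str, int]:
    counts = {family: 0 for family in FAMILIES}
    for outcome in result.outcomes.values():
        if outcome.retained:
            counts[outcome.family] = counts.get(outcome.family, 0) + 1
    return counts
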