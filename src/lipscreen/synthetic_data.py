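"""Generators for every input the pipeline consumes, with planted ground truth.

Each generator is deterministic under a fixed seed and emits exactly the
formats the readers in :mod:`lipscreen.seqio` accept.  Backgrounds for
motif-planting exclude the letters that could create chance matches (no G or
S in the random alphabet), so planted-truth recovery tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipscreen.localization import PredictorRow
from lipscreen.motif_scan import MotifHit
from lipscreen.regulation import RegulationObservation
from lipscreen.screen_funnel import AnnotationRow
from lipscreen.seqio import STANDARD_AA, ProteinRecord, Residue, Structure

#: Background alphabet free of G and S: no chance GXSXG or GDS matches.
MOTIF_FREE_ALPHABET = "ACDEFHIKLMNPQRTVWY"


@dataclass
class GroundTruth:
    """Planted truth for one generated bundle, keyed by protein/gene id."""

    motifs: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    funnel: dict[str, tuple[str, str]] = field(default_factory=dict)  # (stage, reason)
    compartments: dict[str, str] = field(default_factory=dict)
    regulation_max: dict[str, float] = field(default_factory=dict)
    dihedrals: dict[str, tuple[float, float]] = field(default_factory=dict)
    confidence_plans: dict[str, list[float]] = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_protein(
    length: int,
    weights: dict[str, float] | None = None,
    seed=0,
    protein_id: str = "synth",
    alphabet: str = STANDARD_AA,
) -> ProteinRecord:
    """Random protein with the given background composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    letters = list(alphabet)
    if weights is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        probs = np.array([weights.get(aa, 0.0) for aa in letters], dtype=float)
        if probs.sum() <= 0 or (probs < 0).any():
            raise ValueError("composition weights must be non-negative and sum > 0")
        probs = probs / probs.sum()
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return ProteinRecord(id=protein_id, sequence=seq)


def plant_motifs(
    record: ProteinRecord, plants: list[tuple[str, int]]
) -> tuple[ProteinRecord, GroundTruth]:
    """Overwrite the sequence with exact motif strings at 1-based positions."""
    seq = list(record.sequence)
    occupied: set[int] = set()
    truth = GroundTruth()
    truth.motifs[record.id] = []
    for motif, start in plants:
        end = start + len(motif) - 1
        if start < 1 or end > len(seq):
            raise ValueError(f"plant {motif!r} at {start} out of range")
        span = set(range(start, end + 1))
        if span & occupied:
            raise ValueError(f"plant {motif!r} at {start} overlaps a previous plant")
        occupied |= span
        seq[start - 1 : end] = motif
        truth.motifs[record.id].append((motif, start, motif))
    new_record = ProteinRecord(
        id=record.id, sequence="".join(seq), description=record.description
    )
    return new_record, truth


_FAMILY_DESCRIPTIONS = {
    "alpha/beta hydrolase": "alpha/beta hydrolase fold protein",
    "class 3 lipase": "triacylglycerol lipase, class 3",
    "GDSL lipase": "GDSL lipase/esterase family protein",
    "patatin-like phospholipase": "patatin-like phospholipase domain protein",
}
_FAMILY_DOMAINS = {
    "alpha/beta hydrolase": "Abhydrolase_1",
    "class 3 lipase": "Lipase_3",
    "GDSL lipase": "GDSL_lipase",
    "patatin-like phospholipase": "Patatin",
}


def _background(rng: np.random.Generator, length: int, pid: str) -> ProteinRecord:
    return generate_protein(
        length, seed=rng, protein_id=pid, alphabet=MOTIF_FREE_ALPHABET
    )


def generate_screen_set(
    n_per_family: dict[str, int] | None = None,
    exclusions: dict[str, int] | None = None,
    seed=0,
    length: int = 120,
) -> tuple[list[ProteinRecord], list[AnnotationRow], GroundTruth]:
    """A FASTA + annotation bundle whose funnel outcome is known per protein.

    ``n_per_family`` counts proteins intended to survive the whole funnel;
    ``exclusions`` counts proteins planted to fail at a specific stage, keyed
    by one of ``no_keyword``, ``insignificant``, ``no_annotation``,
    ``motifless``, ``function_excluded``, ``gde``.
    """
    n_per_family = dict(n_per_family or {})
    exclusions = dict(exclusions or {})
    unknown = set(exclusions) - {
        "no_keyword", "insignificant", "no_annotation", "motifless",
        "function_excluded", "gde",
    }
    if unknown:
        raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
    rng = _rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[AnnotationRow] = []
    truth = GroundTruth()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    def significant_evalue() -> float:
        return float(10.0 ** rng.uniform(-30, -6))

    def insignificant_evalue() -> float:
        return float(10.0 ** rng.uniform(-4, -1))

    for family, n in n_per_family.items():
        if family not in _FAMILY_DESCRIPTIONS:
            raise ValueError(f"unknown family {family!r}")
        for _ in range(n):
            pid = next_id()
            rec = _background(rng, length, pid)
            motif = "GDSL" if family == "GDSL lipase" else "GHSLG"
            pos = int(rng.integers(10, length - 10))
            rec, motif_truth = plant_motifs(rec, [(motif, pos)])
            records.append(rec)
            annotations.append(
                AnnotationRow(
                    protein_id=pid,
                    description=_FAMILY_DESCRIPTIONS[family],
                    domain_hits=((_FAMILY_DOMAINS[family], significant_evalue()),),
                    best_homolog_function="triacylglycerol lipase",
                )
            )
            truth.motifs.update(motif_truth.motifs)
            truth.families[pid] = family
            truth.funnel[pid] = ("retained", "")

    for _ in range(exclusions.get("no_keyword", 0)):
        pid = next_id()
        records.append(_background(rng, length, pid))
        annotations.append(
            AnnotationRow(
                protein_id=pid,
                description="serine/threonine protein kinase",
                domain_hits=(("Pkinase", significant_evalue()),),
            )
        )
        truth.funnel[pid] = ("keyword", "no keyword")

    for _ in range(exclusions.get("insignificant", 0)):
        pid = next_id()
        rec = _background(rng, length, pid)
        rec, _ = plant_motifs(rec, [("GHSLG", int(rng.integers(10, length - 10)))])
        records.append(rec)
        annotations.append(
            AnnotationRow(
                protein_id=pid,
                description="putative lipase",
                domain_hits=(("Abhydrolase_1", insignificant_evalue()),),
            )
        )
        truth.funnel[pid] = ("significance", "no significant annotation")

    for _ in range(exclusions.get("no_annotation", 0)):
        pid = next_id()
        records.append(_background(rng, length, pid))
        annotations.append(
            AnnotationRow(protein_id=pid, description="putative lipase", domain_hits=())
        )
        truth.funnel[pid] = ("significance", "no annotation")

    for _ in range(exclusions.get("motifless", 0)):
        pid = next_id()
        records.append(_background(rng, length, pid))  # no G/S: no motif possible
        annotations.append(
            AnnotationRow(
                protein_id=pid,
                description="alpha/beta hydrolase fold protein",
                domain_hits=(("Abhydrolase_1", significant_evalue()),),
            )
        )
        truth.funnel[pid] = ("motif", "no pentapeptide motif")

    for _ in range(exclusions.get("function_excluded", 0)):
        pid = next_id()
        rec = _background(rng, length, pid)
        rec, _ = plant_motifs(rec, [("GHSLG", int(rng.integers(10, length - 10)))])
        records.append(rec)
        annotations.append(
            AnnotationRow(
                protein_id=pid,
                description="alpha/beta hydrolase fold protein",
                domain_hits=(("Abhydrolase_1", significant_evalue()),),
                best_homolog_function="proline iminopeptidase",
            )
        )
        truth.funnel[pid] = ("function", "excluded function: proline iminopeptidase")

    for _ in range(exclusions.get("gde", 0)):
        pid = next_id()
        rec = _background(rng, length, pid)
        rec, _ = plant_motifs(rec, [("GDE", int(rng.integers(5, length // 4)))])
        records.append(rec)
        annotations.append(
            AnnotationRow(
                protein_id=pid,
                description="GDSL lipase/esterase family protein",
                domain_hits=(("GDSL_lipase", significant_evalue()),),
            )
        )
        truth.funnel[pid] = ("inactive_motif", "missing catalytic serine")

    return records, annotations, truth


_COMPARTMENT_PLANS = {
    "cytosol": dict(signal_peptide=False, plastid=False, mito=0.1, tm=0, motifs=()),
    "ER/cytosol": dict(signal_peptide=False, plastid=False, mito=0.1, tm=1, motifs=()),
    "ER": dict(signal_peptide=True, plastid=False, mito=0.1, tm=0, motifs=()),
    "chloroplast": dict(signal_peptide=False, plastid=True, mito=0.1, tm=0, motifs=()),
    "mitochondria": dict(signal_peptide=False, plastid=False, mito=0.95, tm=0, motifs=()),
    "mitochondria/peroxisome": dict(
        signal_peptide=False, plastid=False, mito=0.95, tm=0, motifs=("pts1",)
    ),
    "peroxisome": dict(signal_peptide=False, plastid=False, mito=0.1, tm=0, motifs=("pts1",)),
}


def generate_predictor_table(
    plants: dict[str, str],
    noise_rate: float = 0.0,
    seed=0,
) -> tuple[dict[str, PredictorRow], dict[str, list[MotifHit]], GroundTruth]:
    """Predictor rows + motif evidence that decode to the planted compartments.

    With probability ``noise_rate`` one evidence column of a row is flipped.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    rng = _rng(seed)
    rows: dict[str, PredictorRow] = {}
    motif_hits: dict[str, list[MotifHit]] = {}
    truth = GroundTruth()
    for pid, compartment in plants.items():
        try:
            plan = dict(_COMPARTMENT_PLANS[compartment])
        except KeyError:
            raise ValueError(f"unknown compartment {compartment!r}") from None
        if noise_rate and rng.random() < noise_rate:
            flip = rng.choice(["signal_peptide", "plastid", "mito", "tm"])
            if flip == "signal_peptide":
                plan["signal_peptide"] = not plan["signal_peptide"]
            elif flip == "plastid":
                plan["plastid"] = not plan["plastid"]
            elif flip == "mito":
                plan["mito"] = 0.95 if plan["mito"] < 0.85 else 0.1
            else:
                plan["tm"] = 0 if plan["tm"] else 1
        rows[pid] = PredictorRow(
            protein_id=pid,
            signal_peptide=bool(plan["signal_peptide"]),
            plastid_positive=bool(plan["plastid"]),
            mito_score=float(plan["mito"]),
            tm_count=int(plan["tm"]),
        )
        hits = []
        for motif in plan["motifs"]:
            hits.append(
                MotifHit(protein_id=pid, motif=motif, start=1, matched="SKL", flags=("cterm",))
            )
        motif_hits[pid] = hits
        truth.compartments[pid] = compartment
    return rows, motif_hits, truth


def generate_regulation_table(
    gene_effects: dict[str, float],
    datasets: tuple[str, ...] = ("dsA", "dsB", "dsC"),
    timepoints: tuple[str, ...] = ("t1", "t2"),
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[list[RegulationObservation], GroundTruth]:
    """Observations whose signed maximal regulation per gene is planted.

    The planted value is placed at one random dataset/timepoint; all other
    observations have strictly smaller magnitude.  Gaussian noise of
    ``noise_sd`` is added to the non-maximal observations only, so planted
    maxima stay exact at noise 0 and within a few sd otherwise.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    rng = _rng(seed)
    observations: list[RegulationObservation] = []
    truth = GroundTruth()
    slots = [(d, t) for d in datasets for t in timepoints]
    for gene, planted in gene_effects.items():
        target = slots[int(rng.integers(len(slots)))]
        for slot in slots:
            if slot == target:
                value = planted
            else:
                value = float(rng.uniform(-0.5, 0.5)) * abs(planted) * 0.9
                value += float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                # keep filler strictly below the planted magnitude
                limit = abs(planted) * 0.99
                value = float(np.clip(value, -limit, limit))
            observations.append(
                RegulationObservation(
                    gene=gene, dataset=slot[0], timepoint=slot[1], log2fc=value
                )
            )
        truth.regulation_max[gene] = planted
    return observations, truth


# Backbone internal-coordinate constants for chain construction (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Next atom D from A-B-C by bond length |CD|, angle B-C-D, torsion A-B-C-D."""
    angle_r = np.radians(angle)
    torsion_r = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle_r),
            bond * np.sin(angle_r) * np.cos(torsion_r),
            bond * np.sin(angle_r) * np.sin(torsion_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_helix_pdb(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    confidence_plan: list[float] | None = None,
    chain: str = "A",
) -> tuple[Structure, GroundTruth]:
    """Ideal-geometry backbone whose measured dihedrals equal (phi, psi).

    The B-factor field of each residue carries ``confidence_plan`` (default
    90 everywhere).  Construction is exact internal-coordinate chaining, so a
    build-then-measure round trip agrees to well below 1e-4 degrees.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if confidence_plan is None:
        confidence_plan = [90.0] * n_residues
    if len(confidence_plan) != n_residues:
        raise ValueError("confidence plan length must match residue count")
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = np.radians(ANGLE_N_CA_C)
    c1 = ca1 + BOND_CA_C * np.array([-np.cos(angle), np.sin(angle), 0.0])
    atoms = [(n1, ca1, c1)]
    for i in range(1, n_residues):
        prev_n, prev_ca, prev_c = atoms[-1]
        n_i = _place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place_atom(prev_ca, prev_c, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(prev_c, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms.append((n_i, ca_i, c_i))
    structure = Structure(
        residues=[
            Residue(
                chain=chain,
                number=i + 1,
                name="ALA",
                n=n,
                ca=ca,
                c=c,
                confidence=float(confidence_plan[i]),
            )
            for i, (n, ca, c) in enumerate(atoms)
        ]
    )
    truth = GroundTruth()
    truth.dihedrals["helix"] = (phi, psi)
    truth.confidence_plans["helix"] = list(confidence_plan)
    return structure, truth
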