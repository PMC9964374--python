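"""Predicted-structure quality control.

Backbone phi/psi dihedrals, Ramachandran region fractions, per-residue
confidence (plDDT) summaries, and rolling-window smoothing of per-residue
score series.

The default Ramachandran region map is a coarse 10 deg x 10 deg lookup
bundled as package data (``data/rama_map_10deg.tsv``); any map file with the
same three-column layout (phi_min, psi_min, region) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from lipscreen.seqio import Structure

REGIONS = ("highly_favored", "favored", "questionable")

PLDDT_BANDS = ("<50", "50-70", "70-90", ">90")


@dataclass(frozen=True)
class DihedralRecord:
    index: int  # 0-based residue index within the structure
    phi: float | None  # degrees in (-180, 180]
    psi: float | None
    complete: bool = True


@dataclass(frozen=True)
class RamachandranSummary:
    fractions: dict[str, float]
    counted: int


@dataclass(frozen=True)
class PlddtSummary:
    mean: float
    series: tuple[float, ...]
    band_fractions: dict[str, float]


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral (degrees) of four points, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(structure: Structure) -> list[DihedralRecord]:
    """Phi/psi per residue; None at termini and around incomplete residues."""
    residues = structure.residues
    out: list[DihedralRecord] = []
    for i, res in enumerate(residues):
        if not res.complete:
            out.append(DihedralRecord(index=i, phi=None, psi=None, complete=False))
            continue
        phi = psi = None
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        if prev_res is not None and prev_res.complete and prev_res.chain == res.chain:
            phi = dihedral_angle(prev_res.c, res.n, res.ca, res.c)
        if next_res is not None and next_res.complete and next_res.chain == res.chain:
            psi = dihedral_angle(res.n, res.ca, res.c, next_res.n)
        out.append(DihedralRecord(index=i, phi=phi, psi=psi))
    return out


class RamachandranMap:
    """10x10-degree grid lookup partitioning the (phi, psi) torus."""

    CELL = 10

    def __init__(self, cells: dict[tuple[int, int], str]):
        self.cells = cells

    @classmethod
    def load(cls, path: str | Path) -> "RamachandranMap":
        cells: dict[tuple[int, int], str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["phi_min", "psi_min", "region"]:
                raise ValueError(f"{path}: expected columns phi_min, psi_min, region")
            for line in fh:
                phi_s, psi_s, region = line.rstrip("\n").split("\t")
                if region not in REGIONS:
                    raise ValueError(f"{path}: unknown region {region!r}")
                cells[(int(phi_s), int(psi_s))] = region
        return cls(cells)

    @classmethod
    def default(cls) -> "RamachandranMap":
        ref = resources.files("lipscreen").joinpath("data/rama_map_10deg.tsv")
        with resources.as_file(ref) as path:
            return cls.load(path)

    def classify(self, phi: float, psi: float) -> str:
        # map angle to its cell's lower bound; 180 wraps to the -180 cell
        def floor_cell(angle: float) -> int:
            wrapped = ((angle + 180.0) % 360.0) - 180.0
            return int(np.floor(wrapped / self.CELL)) * self.CELL

        return self.cells.get((floor_cell(phi), floor_cell(psi)), "questionable")


def ramachandran_classify(
    dihedrals: list[DihedralRecord], region_map: RamachandranMap | None = None
) -> RamachandranSummary:
    """Region fractions over residues with both angles defined."""
    region_map = region_map or RamachandranMap.default()
    counts = {region: 0 for region in REGIONS}
    counted = 0
    for rec in dihedrals:
        if rec.phi is None or rec.psi is None:
            continue
        counts[region_map.classify(rec.phi, rec.psi)] += 1
        counted += 1
    fractions = {
        region: (counts[region] / counted if counted else 0.0) for region in REGIONS
    }
    return RamachandranSummary(fractions=fractions, counted=counted)


def plddt_summary(structure: Structure) -> PlddtSummary:
    """Mean confidence and band fractions at the 50/70/90 boundaries."""
    series = structure.confidences
    if not series:
        raise ValueError("structure has no residues")
    for i, value in enumerate(series):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"residue {i}: confidence {value} outside [0, 100]")
    values = np.asarray(series)
    bands = {
        "<50": float(np.mean(values < 50)),
        "50-70": float(np.mean((values >= 50) & (values < 70))),
        "70-90": float(np.mean((values >= 70) & (values <= 90))),
        ">90": float(np.mean(values > 90)),
    }
    return PlddtSummary(
        mean=float(values.mean()), series=tuple(series), band_fractions=bands
    )


def rolling_mean(series, window: int = 40) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges.

    For window ``w`` the value at position ``i`` averages indices
    ``[i - (w-1)//2, i + w//2]`` clipped to the series bounds; output length
    equals input length.
    """
    values = np.asarray(series, dtype=float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def dihedral_rows(dihedrals: list[DihedralRecord]) -> list[dict]:
    return [
        {
            "index": d.index,
            "phi": "" if d.phi is None else round(d.phi, 4),
            "psi": "" if d.psi is None else round(d.psi, 4),
            "complete": int(d.complete),
        }
        for d in dihedrals
    ]
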