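"""Sequence and structure preference analyses of modified tyrosines.

Positional preference splits each protein into equal thirds (N-terminal /
Middle / C-terminal, boundaries at ceil(L/3) and ceil(2L/3)).  Structural
preferences consume externally produced per-residue annotations (secondary
structure probabilities, relative surface accessibility, disorder) via a
documented TSV schema; predictors themselves are never run here.

Conventions, pinned as defaults: secondary structure = argmax probability
(ties prefer coil, then strand); exposed iff RSA >= 0.25 (inclusive);
disordered iff disorder score >= 0.5.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import FormatError, ModSite
from .stats import FourfoldTable, e_ratio, yates_chi_square

log = logging.getLogger(__name__)

REGIONS = ("N-terminal", "Middle", "C-terminal")
SS_CLASSES = ("helix", "strand", "coil")
RSA_EXPOSED_THRESHOLD = 0.25
DISORDER_THRESHOLD = 0.5


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-residue structural annotation from an external predictor run."""

    protein_id: str
    position: int
    p_helix: float
    p_strand: float
    p_coil: float
    rsa: float
    disorder: float

    def __post_init__(self) -> None:
        total = self.p_helix + self.p_strand + self.p_coil
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ContractError(
                f"{self.protein_id}:{self.position}: ss probabilities sum to {total}, not 1"
            )
        if not 0.0 <= self.rsa <= 1.0:
            raise ContractError(f"rsa {self.rsa} outside [0, 1]")


STRUCTURE_TABLE_COLUMNS = [
    "protein_id", "position", "p_helix", "p_strand", "p_coil", "rsa", "disorder",
]


def read_structure_table(path: str | Path) -> dict[tuple[str, int], StructureAnnotation]:
    path = Path(path)
    out: dict[tuple[str, int], StructureAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in STRUCTURE_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for row in reader:
            ann = StructureAnnotation(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                p_helix=float(row["p_helix"]),
                p_strand=float(row["p_strand"]),
                p_coil=float(row["p_coil"]),
                rsa=float(row["rsa"]),
                disorder=float(row["disorder"]),
            )
            out[(ann.protein_id, ann.position)] = ann
    return out


def write_structure_table(
    annotations: Iterable[StructureAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(STRUCTURE_TABLE_COLUMNS)
        for a in annotations:
            writer.writerow(
                [a.protein_id, a.position, repr(a.p_helix), repr(a.p_strand),
                 repr(a.p_coil), repr(a.rsa), repr(a.disorder)]
            )


# ---------------------------------------------------------------------------
# terminal thirds
# ---------------------------------------------------------------------------


def terminal_region(position: int, protein_length: int) -> str:
    """Which equal third of the protein a 1-based position falls in.

    Boundaries at ceil(L/3) and ceil(2L/3): position <= first third ->
    N-terminal, <= second -> Middle, else C-terminal.  Every position maps to
    exactly one region.
    """
    if not 1 <= position <= protein_length:
        raise ContractError(f"position {position} outside 1..{protein_length}")
    first = math.ceil(protein_length / 3)
    second = math.ceil(2 * protein_length / 3)
    if position <= first:
        return "N-terminal"
    if position <= second:
        return "Middle"
    return "C-terminal"


def region_counts(positions: Iterable[tuple[int, int]]) -> dict[str, int]:
    """Tally (position, protein_length) pairs into the three regions."""
    counts = {r: 0 for r in REGIONS}
    for pos, length in positions:
        counts[terminal_region(pos, length)] += 1
    return counts


# ---------------------------------------------------------------------------
# category assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteCategories:
    ss_class: str
    exposure: str  # "exposed" | "buried"
    order: str  # "disordered" | "ordered"


def assign_categories(
    site: ModSite | tuple[str, int], annotation: StructureAnnotation
) -> SiteCategories:
    """Discretise one site's structural annotation.

    Secondary structure is the argmax probability; exact ties prefer coil,
    then strand, then helix.  Exposure and disorder use inclusive thresholds.
    """
    probs = {
        "coil": annotation.p_coil,
        "strand": annotation.p_strand,
        "helix": annotation.p_helix,
    }
    ss = max(probs, key=lambda c: (probs[c], ("helix", "strand", "coil").index(c)))
    exposure = "exposed" if annotation.rsa >= RSA_EXPOSED_THRESHOLD else "buried"
    order = "disordered" if annotation.disorder >= DISORDER_THRESHOLD else "ordered"
    return SiteCategories(ss, exposure, order)


def categorize_sites(
    sites: Iterable[ModSite | tuple[str, int]],
    annotations: Mapping[tuple[str, int], StructureAnnotation],
) -> tuple[list[SiteCategories], int]:
    """Assign categories to every annotated site; returns (categories,
    n_excluded) where excluded sites lacked an annotation (count logged)."""
    out: list[SiteCategories] = []
    excluded = 0
    for s in sites:
        key = (s.protein_id, s.position) if isinstance(s, ModSite) else s
        ann = annotations.get(key)
        if ann is None:
            excluded += 1
            continue
        out.append(assign_categories(s, ann))
    if excluded:
        log.info("categorize_sites: %d sites without structure annotation excluded", excluded)
    return out, excluded


# ---------------------------------------------------------------------------
# category preference tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryPreference:
    category: str
    modified_in: int
    modified_total: int
    background_in: int
    background_total: int
    e_ratio: float
    chi2: float
    p_value: float


def _axis_values(cats: Sequence[SiteCategories], axis: str) -> list[str]:
    return [getattr(c, axis) for c in cats]


def category_preference(
    modified: Sequence[SiteCategories],
    background: Sequence[SiteCategories],
    axes: Sequence[str] = ("ss_class", "exposure", "order"),
) -> list[CategoryPreference]:
    """Per-category enrichment of modified sites against background.

    For each category value a 2x2 table (modified vs background, in-category
    vs not) feeds the two-proportion E-ratio and Yates' chi-square.
    Categories absent from both sets are skipped; a zero background rate
    flags the ratio as infinite.
    """
    if not modified or not background:
        raise ContractError("both site sets must be non-empty")
    out: list[CategoryPreference] = []
    for axis in axes:
        mod_vals = _axis_values(modified, axis)
        bg_vals = _axis_values(background, axis)
        categories = sorted(set(mod_vals) | set(bg_vals))
        for cat in categories:
            a = sum(1 for v in mod_vals if v == cat)
            c = sum(1 for v in bg_vals if v == cat)
            if a == 0 and c == 0:
                continue
            b = len(mod_vals) - a
            d = len(bg_vals) - c
            ratio = e_ratio(a, len(mod_vals), c, len(bg_vals))
            stat, p = yates_chi_square(FourfoldTable(a, b, c, d))
            out.append(
                CategoryPreference(cat, a, len(mod_vals), c, len(bg_vals), ratio, stat, p)
            )
    return out
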