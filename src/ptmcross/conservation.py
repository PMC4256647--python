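"""Long-term evolutionary analysis of modified tyrosines.

Pipeline: detect orthologs of human proteins by reciprocal best BLAST hits
(RBH), build human-anchored ortholog groups, map each human site into its
multiple-alignment column, and score the column's tyrosine conservation:

    RCS_Y = N_Y / N

where N_Y is the number of group members carrying a tyrosine in the column
and N is the number of member species inside the smallest species-tree clade
spanning the maximum-branch-length (MBL) pair — the two tyrosine-bearing
species at the largest patristic distance.  RCS_Y = 1 (all species in the
MBL span retain the tyrosine) marks a conserved residue by default; the
threshold is adjustable for sensitivity analysis, and lowering it can only
grow the conserved set.

Conservation of one site class against another (e.g. phosphorylated vs
unmodified tyrosines) is compared with the same E-ratio + hypergeometric
machinery used everywhere else in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import BlastHit, ProteinRecord, SpeciesTree, read_aligned_fasta
from .stats import ContingencyCounts, EnrichmentResult, e_ratio


class ContractError(ValueError):
    pass


class IntegrityError(ValueError):
    """Sequence/alignment inconsistency: a site maps into nothing."""


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def _best_hits(hits: Iterable[BlastHit]) -> dict[str, str]:
    """Best subject per query: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or (h.bitscore, -h.evalue, _NegStr(h.subject)) > (
            cur.bitscore,
            -cur.evalue,
            _NegStr(cur.subject),
        ):
            best[h.query] = h
    return {q: h.subject for q, h in best.items()}


class _NegStr(str):
    """Reverses string ordering so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def reciprocal_best_hits(
    hits_ab: Iterable[BlastHit], hits_ba: Iterable[BlastHit]
) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


def build_groups(
    rbh_by_species: Mapping[str, Iterable[tuple[str, str]]],
) -> dict[str, dict[str, str]]:
    """Human-anchored star groups from per-species RBH pair lists.

    ``rbh_by_species`` maps a species label to (human_id, partner_id) pairs.
    Returns anchor human id -> {species: partner id}; anchors with no partner
    in any species yield no group.
    """
    groups: dict[str, dict[str, str]] = {}
    for species, pairs in rbh_by_species.items():
        for human_id, partner in pairs:
            groups.setdefault(human_id, {})[species] = partner
    return {h: members for h, members in groups.items() if members}


# ---------------------------------------------------------------------------
# ortholog groups and site -> column mapping
# ---------------------------------------------------------------------------


@dataclass
class OrthologGroup:
    """One human protein with its aligned orthologs (one per species)."""

    anchor: str
    anchor_species: str
    members: dict[str, ProteinRecord]  # species -> aligned record

    def __post_init__(self) -> None:
        if self.anchor_species not in self.members:
            raise ContractError(f"anchor species {self.anchor_species!r} missing from members")
        lengths = {len(r.sequence) for r in self.members.values()}
        if len(lengths) > 1:
            raise ContractError(f"aligned member lengths differ: {sorted(lengths)}")

    @property
    def anchor_row(self) -> str:
        return self.members[self.anchor_species].sequence

    @property
    def n_columns(self) -> int:
        return len(self.anchor_row)

    def column(self, col: int) -> dict[str, str]:
        """Residues (or '-') per species at a 1-based column."""
        return {sp: rec.sequence[col - 1] for sp, rec in self.members.items()}


def load_group(path: str | Path, anchor_species: str = "HUMAN") -> OrthologGroup:
    """Read one group's aligned FASTA; species labels come from id suffixes."""
    records = read_aligned_fasta(path)
    members: dict[str, ProteinRecord] = {}
    anchor = None
    for rec in records:
        species = rec.species or rec.id
        if species in members:
            raise ContractError(f"{path}: two members for species {species!r}")
        members[species] = rec
        if species == anchor_species:
            anchor = rec.id
    if anchor is None:
        raise ContractError(f"{path}: no {anchor_species} row in alignment")
    return OrthologGroup(anchor, anchor_species, members)


def map_site_to_column(group: OrthologGroup, human_position: int) -> int:
    """1-based alignment column whose ungapped human index equals the position."""
    row = group.anchor_row
    ungapped = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            ungapped += 1
            if ungapped == human_position:
                return col
    raise IntegrityError(
        f"group {group.anchor}: human position {human_position} beyond "
        f"ungapped length {ungapped}"
    )


def column_to_position(group: OrthologGroup, column: int) -> int:
    """Inverse of :func:`map_site_to_column`; errors on a gap column."""
    row = group.anchor_row
    if not 1 <= column <= len(row):
        raise IntegrityError(f"column {column} outside 1..{len(row)}")
    if row[column - 1] == "-":
        raise IntegrityError(f"column {column} is a gap in the human row")
    return sum(1 for ch in row[:column] if ch != "-")


# ---------------------------------------------------------------------------
# RCS_Y
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RCSResult:
    column: int
    n_y: int
    n: int
    rcs: float
    mbl_pair: tuple[str, str]
    mbl: float
    conserved: bool
    degenerate: bool  # single-species tyrosine span


def rcs_y(
    group: OrthologGroup,
    column: int,
    tree: SpeciesTree,
    threshold: float = 1.0,
) -> RCSResult:
    """Tyrosine residue-conservation score of one alignment column.

    Preconditions: the human residue at the column is a tyrosine (so the
    column has >= 1 Y).  The MBL pair is the pair of tyrosine-bearing member
    species at maximum patristic distance (ties broken lexicographically);
    N counts member species inside the smallest tree clade containing that
    pair.  A column whose only tyrosine is human's collapses to N = N_Y = 1,
    rcs = 1 — reported with ``degenerate=True``.
    """
    residues = group.column(column)
    y_species = sorted(sp for sp, aa in residues.items() if aa == "Y")
    if not y_species:
        raise ContractError(f"column {column} contains no tyrosine")
    if residues.get(group.anchor_species) != "Y":
        raise ContractError(
            f"column {column}: anchor residue is {residues.get(group.anchor_species)!r}, not Y"
        )
    if len(y_species) == 1:
        sp = y_species[0]
        return RCSResult(column, 1, 1, 1.0, (sp, sp), 0.0, 1.0 >= threshold, True)
    best_pair = None
    best_dist = -1.0
    for i, a in enumerate(y_species):
        for b in y_species[i + 1 :]:
            d = tree.patristic(a, b)
            if d > best_dist:
                best_dist, best_pair = d, (a, b)
    clade = tree.clade_leafset(*best_pair)
    n = sum(1 for sp in group.members if sp in clade)
    n_y = len(y_species)
    rcs = n_y / n
    return RCSResult(column, n_y, n, rcs, best_pair, best_dist, rcs >= threshold, False)


def site_conservation(
    group: OrthologGroup,
    human_positions: Sequence[int],
    tree: SpeciesTree,
    threshold: float = 1.0,
) -> list[RCSResult]:
    """RCS_Y for each human (ungapped) tyrosine position in one group."""
    return [
        rcs_y(group, map_site_to_column(group, pos), tree, threshold)
        for pos in human_positions
    ]


def conservation_comparison(
    conserved_a: Sequence[bool], conserved_b: Sequence[bool]
) -> EnrichmentResult:
    """Compare conserved fractions of two site classes.

    E-ratio = fraction(A) / fraction(B); p from the hypergeometric test with
    N = |A| + |B|, K = total conserved, n = |A|, k = conserved in A.
    """
    if not len(conserved_a) or not len(conserved_b):
        raise ContractError("both site classes must be non-empty")
    ka, kb = sum(conserved_a), sum(conserved_b)
    na, nb = len(conserved_a), len(conserved_b)
    ratio = e_ratio(ka, na, kb, nb)
    counts = ContingencyCounts(N=na + nb, K=ka + kb, n=na, k=ka)
    tail = "over" if (math.isinf(ratio) or ratio >= 1) else "under"
    from .stats import hypergeom_tail

    return EnrichmentResult(ratio, hypergeom_tail(counts, tail), tail, counts)
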