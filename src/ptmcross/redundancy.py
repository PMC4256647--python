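"""Redundancy clearing for training data.

Homologous substrates inflate apparent predictor performance: a site that is
present at the equivalent aligned position of two near-identical proteins is
effectively the same training example twice.  This module clusters substrate
sequences at a global-identity threshold (default 40%) and removes member
sites whose aligned column coincides with a site already kept.

Alignment is Needleman-Wunsch global alignment (BLOSUM62, gap open -11,
extend -1 by default), with identity defined as matches over alignment
columns — gaps count in the denominator, which is more conservative than
CD-HIT's shorter-sequence convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import ModSite, ProteinRecord, SiteDataset

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(matrix=None, match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -11.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is None:
        aligner.substitution_matrix = _BLOSUM62
    elif matrix == "simple":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        aligner.substitution_matrix = matrix
    # First gap position costs `gap_open`, each further position `gap_extend`.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_alignment(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns ``(aligned_a, aligned_b, score)`` with ``'-'`` gaps.  The default
    scoring is BLOSUM62 with affine gaps (-11 open, -1 extend); pass
    ``matrix="simple"`` for plain match/mismatch scores.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    return a, b, float(alignment.score)


def global_identity(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> float:
    """Identity fraction of the optimal global alignment.

    identity = identical columns / total alignment columns (gaps included in
    the denominator), hence symmetric and 1.0 only for identical sequences.
    """
    a, b, _ = global_alignment(seq_a, seq_b, matrix, gap_open, gap_extend, match, mismatch)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


@dataclass
class SequenceCluster:
    """A representative and its members at >= threshold identity."""

    representative: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        return [self.representative] + self.members


def greedy_cluster(
    proteins: Iterable[ProteinRecord], threshold: float = 0.40
) -> list[SequenceCluster]:
    """Longest-first greedy clustering at a global-identity threshold.

    Sequences are visited longest first (ties broken by id); each joins the
    first existing cluster whose representative identity meets the threshold,
    else founds a new cluster.  Clusters partition the input.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(proteins, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[SequenceCluster] = []
    by_id = {r.id: r for r in ordered}
    for rec in ordered:
        placed = False
        for cl in clusters:
            ident = global_identity(rec.sequence, by_id[cl.representative].sequence)
            if ident >= threshold:
                cl.members.append(rec.id)
                cl.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(representative=rec.id))
    return clusters


def _member_to_rep_map(member_seq: str, rep_seq: str) -> dict[int, int | None]:
    """1-based member position -> 1-based representative position (None at gaps)."""
    a, b, _ = global_alignment(member_seq, rep_seq)
    mapping: dict[int, int | None] = {}
    mi = ri = 0
    for x, y in zip(a, b):
        if x != "-":
            mi += 1
        if y != "-":
            ri += 1
        if x != "-":
            mapping[mi] = ri if y != "-" else None
    return mapping


def clear_redundant_sites(dataset: SiteDataset, clusters: Sequence[SequenceCluster]) -> SiteDataset:
    """Drop member sites aligned to a column where a site is already kept.

    Within each cluster the representative's sites are kept; each member's
    sites are mapped through the member-vs-representative alignment and
    dropped when their representative column (per PTM class) already carries
    a kept site.  Deterministic given cluster member order.
    """
    kept: list[ModSite] = []
    site_index: dict[str, list[ModSite]] = {}
    for s in dataset.sites:
        site_index.setdefault(s.protein_id, []).append(s)

    for cl in clusters:
        rep = dataset.proteins[cl.representative]
        occupied: dict[tuple[str, int], ModSite] = {}
        for s in site_index.get(rep.id, []):
            occupied[(s.ptm, s.position)] = s
            kept.append(s)
        for member_id in cl.members:
            member = dataset.proteins[member_id]
            sites = site_index.get(member_id, [])
            if not sites:
                continue
            mapping = _member_to_rep_map(member.sequence, rep.sequence)
            for s in sites:
                rep_pos = mapping.get(s.position)
                if rep_pos is not None and (s.ptm, rep_pos) in occupied:
                    continue  # redundant homologous site
                kept.append(s)
                if rep_pos is not None:
                    occupied[(s.ptm, rep_pos)] = s
    return SiteDataset(dataset.proteins.values(), kept)


def write_cluster_report(clusters: Sequence[SequenceCluster], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["representative", "member", "identity"])
        for cl in clusters:
            writer.writerow([cl.representative, cl.representative, "1.0000"])
            for m in cl.members:
                writer.writerow([cl.representative, m, f"{cl.identities[m]:.4f}"])
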