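"""Short-term evolutionary analysis: PTM sites versus human genetic variants.

Modification sites are intersected with amino-acid variant tables (from
inherited-disease, cancer, or population resources); a site is "hit" when a
variant shares its (protein, position) and the variant's reference residue
is the tyrosine itself.  Variants are split into rare (allele frequency
strictly below 1%) and common; class-versus-class enrichment of variant hits
uses the package's standard E-ratio + hypergeometric test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ModSite, ProteinRecord, VariantRecord
from .stats import ContingencyCounts, EnrichmentResult, e_ratio, hypergeom_tail

log = logging.getLogger(__name__)

RARE_AF_THRESHOLD = 0.01


class ContractError(ValueError):
    pass


@dataclass
class VariantSiteOverlap:
    """How many modified tyrosines of a class are touched by >= 1 variant."""

    num: int
    all: int
    hits: dict[tuple[str, int], list[VariantRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.num > self.all:
            raise ContractError(f"num={self.num} exceeds all={self.all}")


def map_variants(
    sites: Sequence[ModSite | tuple[str, int]],
    variants: Iterable[VariantRecord],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> VariantSiteOverlap:
    """Intersect sites with a variant table.

    A site is hit iff some variant shares its (protein_id, position) with
    ref_aa == 'Y'; multiple variants on one site count once toward ``num``.
    When sequences are supplied, variants whose ref_aa contradicts the
    sequence are skipped (count logged).  Idempotent.
    """
    site_keys: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for s in sites:
        key = (s.protein_id, s.position) if isinstance(s, ModSite) else tuple(s)
        if key not in seen:
            seen.add(key)
            site_keys.append(key)
    skipped = 0
    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        if proteins is not None and v.protein_id in proteins:
            actual = proteins[v.protein_id].residue(v.position)
            if actual != v.ref_aa:
                skipped += 1
                continue
        by_pos.setdefault((v.protein_id, v.position), []).append(v)
    if skipped:
        log.info("map_variants: %d variants with mismatching ref_aa skipped", skipped)
    hits = {
        key: [v for v in by_pos.get(key, []) if v.ref_aa == "Y"] for key in site_keys
    }
    hits = {k: vs for k, vs in hits.items() if vs}
    return VariantSiteOverlap(num=len(hits), all=len(site_keys), hits=hits)


def classify_rare(
    variants: Iterable[VariantRecord], af_threshold: float = RARE_AF_THRESHOLD
) -> dict[str, list[VariantRecord]]:
    """Partition variants into rare (AF strictly < threshold), common, and
    unclassified (missing AF, excluded from fraction denominators)."""
    out: dict[str, list[VariantRecord]] = {"rare": [], "common": [], "unclassified": []}
    for v in variants:
        if v.allele_frequency is None:
            out["unclassified"].append(v)
        elif v.allele_frequency < af_threshold:
            out["rare"].append(v)
        else:
            out["common"].append(v)
    return out


def rare_fraction(variants: Iterable[VariantRecord], af_threshold: float = RARE_AF_THRESHOLD) -> float:
    parts = classify_rare(variants, af_threshold)
    classified = len(parts["rare"]) + len(parts["common"])
    if classified == 0:
        raise ContractError("no variants carry an allele frequency")
    return len(parts["rare"]) / classified


def variation_enrichment(
    overlap_a: VariantSiteOverlap, overlap_b: VariantSiteOverlap
) -> EnrichmentResult:
    """Enrichment of variant hits in class A versus class B.

    E-ratio = (Num_A/All_A)/(Num_B/All_B); hypergeometric p with
    N = All_A + All_B, K = Num_A + Num_B, n = All_A, k = Num_A (auto tail).
    A zero Num_B flags the ratio infinite rather than raising.
    """
    if overlap_a.all == 0 or overlap_b.all == 0:
        raise ContractError("both classes need All > 0")
    ratio = e_ratio(overlap_a.num, overlap_a.all, overlap_b.num, overlap_b.all)
    counts = ContingencyCounts(
        N=overlap_a.all + overlap_b.all,
        K=overlap_a.num + overlap_b.num,
        n=overlap_a.all,
        k=overlap_a.num,
    )
    tail = "over" if (math.isinf(ratio) or ratio >= 1) else "under"
    return EnrichmentResult(ratio, hypergeom_tail(counts, tail), tail, counts)
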