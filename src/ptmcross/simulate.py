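"""Deterministic generators for every input the package consumes.

The curated sulfation/nitration/phosphorylation datasets behind the original
analyses are no longer distributed, so benchmarking and end-to-end testing
run on synthetic data with known ground truth.  Every generator is a pure
function of a :class:`SyntheticSpec` (seed included): the same spec yields
byte-identical files on any platform, and each artifact ships with a
ground-truth sidecar JSON recording what was planted.

What the generators emulate:

* ``generate_motif_dataset`` — substrates whose positive tyrosine windows
  follow the sulfation sequence profile (acidic enrichment immediately
  upstream, strongest at -1; tyrosine over-representation at +1/+2 and,
  weakly, upstream; mild G/Q enrichment near the center) against windows
  drawn from background residue frequencies.  Default sizes echo the
  non-redundant training set shape (200 positives / 1,027 negatives / 116
  substrates).  Background and linker sampling excludes tyrosine so the
  derived negative count is exact by construction.
* ``generate_ortholog_set`` — human-anchored ortholog groups over a fixed
  eight-species vertebrate tree with class-specific tyrosine retention, plus
  BLAST-tabular hit tables consistent with the true orthology (decoys
  strictly weaker).
* ``generate_annotations`` / ``generate_variants`` /
  ``generate_structure_annotations`` — annotation tables with a planted
  enriched term, variant tables with a planted hit rate and rare/common
  allele-frequency split, and structure annotations with a planted coil
  skew.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .conservation import OrthologGroup
from .io import (
    BlastHit,
    ModSite,
    ProteinRecord,
    SiteDataset,
    write_blast_tabular,
    write_fasta,
    write_site_table,
    write_variant_table,
    VariantRecord,
)
from .features import StructureAnnotation, write_structure_table

# Swiss-Prot-like background residue frequencies.
BACKGROUND_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: Default per-offset residue-probability overrides encoding the sulfation
#: sequence profile; remaining mass follows the (tyrosine-free) background.
DEFAULT_MOTIF: dict[int, dict[str, float]] = {
    -7: {"Y": 0.08, "D": 0.12, "E": 0.12},
    -6: {"Y": 0.08, "D": 0.12, "E": 0.12},
    -5: {"Y": 0.08, "D": 0.16, "E": 0.14},
    -4: {"Y": 0.08, "D": 0.16, "E": 0.14},
    -3: {"D": 0.18, "E": 0.16, "G": 0.08},
    -2: {"D": 0.20, "E": 0.18, "G": 0.08, "Q": 0.06},
    -1: {"D": 0.35, "E": 0.28, "G": 0.06},
    1: {"Y": 0.20, "D": 0.16, "E": 0.14, "G": 0.07, "Q": 0.06},
    2: {"Y": 0.20, "D": 0.14, "E": 0.12},
    3: {"D": 0.14, "E": 0.12, "G": 0.06},
    4: {"D": 0.10, "E": 0.10},
    5: {"D": 0.10, "E": 0.10},
    6: {},
    7: {},
}

#: Eight-species vertebrate tree (branch lengths in substitutions/site).
SPECIES = ("HUMAN", "MOUSE", "RAT", "CANFA", "BOVIN", "PIG", "CHICK", "DANRE")
SPECIES_TREE_NEWICK = (
    "(DANRE:0.65,(CHICK:0.35,((CANFA:0.11,(BOVIN:0.09,PIG:0.09):0.03):0.05,"
    "((MOUSE:0.05,RAT:0.05):0.11,HUMAN:0.10):0.04):0.18):0.12);"
)
#: Species that may lose the tyrosine in a non-conserved column.  Keeping
#: human and zebrafish ensures the MBL clade spans all eight species, so a
#: single internal loss already drives RCS_Y below 1.
INTERNAL_SPECIES = ("MOUSE", "RAT", "CANFA", "BOVIN", "PIG", "CHICK")


@dataclass
class SyntheticSpec:
    """All knobs of the fixture generators, seed included."""

    seed: int = 42
    # motif dataset
    n_pos: int = 200
    n_neg: int = 1027
    n_proteins: int = 116
    window: tuple[int, int] = (7, 7)
    motif: dict[int, dict[str, float]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF.items()}
    )
    ptm: str = "sulfation"
    # ortholog set
    n_groups: int = 100
    sites_per_class_per_group: int = 5
    conservation: dict[str, float] = field(
        default_factory=lambda: {"modified": 0.8, "unmodified": 0.5}
    )
    tree: str = SPECIES_TREE_NEWICK
    # annotations
    n_background_proteins: int = 400
    n_foreground_proteins: int = 40
    planted_term: str = "GO:PLANTED"
    planted_background_rate: float = 0.10
    n_base_terms: int = 8
    # variants
    n_variant_sites: int = 2000
    variant_hit_rate: float = 0.05
    rare_weight: float = 0.90
    # structure annotations
    n_structure_sites: int = 400
    coil_rate_modified: float = 0.60
    coil_rate_background: float = 0.30
    exposed_rate: float = 0.50
    disordered_rate: float = 0.30


def standard_motif_spec(seed: int = 42) -> SyntheticSpec:
    """The standard benchmark fixture: 200 positives, 1,000 negatives."""
    return SyntheticSpec(seed=seed, n_pos=200, n_neg=1000, n_proteins=116)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

_BG_AAS = sorted(BACKGROUND_FREQS)
_BG_P = np.array([BACKGROUND_FREQS[a] for a in _BG_AAS])
_BG_P = _BG_P / _BG_P.sum()
_BG_NOY_AAS = [a for a in _BG_AAS if a != "Y"]
_BG_NOY_P = np.array([BACKGROUND_FREQS[a] for a in _BG_NOY_AAS])
_BG_NOY_P = _BG_NOY_P / _BG_NOY_P.sum()


def _offset_distribution(overrides: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    """Residue distribution for one window offset: the override masses, with
    the remainder spread over other residues proportionally to the
    tyrosine-free background."""
    total_override = sum(overrides.values())
    if total_override > 1.0:
        raise ValueError(f"override mass {total_override} exceeds 1")
    aas, probs = [], []
    for a, p in sorted(overrides.items()):
        aas.append(a)
        probs.append(p)
    rest = [(a, BACKGROUND_FREQS[a]) for a in _BG_NOY_AAS if a not in overrides]
    rest_total = sum(p for _, p in rest)
    for a, p in rest:
        aas.append(a)
        probs.append((1.0 - total_override) * p / rest_total)
    return aas, np.asarray(probs)


def _sample_background(rng: np.random.Generator, n: int, allow_y: bool = False) -> str:
    aas, p = (_BG_AAS, _BG_P) if allow_y else (_BG_NOY_AAS, _BG_NOY_P)
    return "".join(rng.choice(aas, size=n, p=p))


# ---------------------------------------------------------------------------
# motif dataset
# ---------------------------------------------------------------------------


def generate_motif_dataset(spec: SyntheticSpec) -> tuple[SiteDataset, dict]:
    """Motif-bearing positives embedded with background negatives.

    Positive windows are drawn from the motif table (``motif=None`` draws
    them from the background — the null case); dedicated negative windows and
    all linkers are tyrosine-free, so the derived negative count equals
    ``n_neg`` exactly: incidental tyrosines in positive flanks plus dedicated
    negative centers.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.window
    offsets = list(range(-m, 0)) + list(range(1, n + 1))

    # positive windows, column by column
    pos_cols: dict[int, np.ndarray] = {}
    for off in offsets:
        overrides = (spec.motif or {}).get(off, {}) if spec.motif is not None else {}
        aas, p = _offset_distribution(overrides)
        pos_cols[off] = rng.choice(aas, size=spec.n_pos, p=p)
    positives = []
    for i in range(spec.n_pos):
        letters = "".join(pos_cols[off][i] for off in offsets[:m]) + "Y" + "".join(
            pos_cols[off][i] for off in offsets[m:]
        )
        positives.append(letters)

    incidental = sum(pep.count("Y") - 1 for pep in positives)
    n_dedicated = spec.n_neg - incidental
    if n_dedicated < 0:
        raise ValueError(
            f"motif produced {incidental} incidental tyrosines, exceeding n_neg={spec.n_neg}"
        )
    negatives = [
        _sample_background(rng, m) + "Y" + _sample_background(rng, n)
        for _ in range(n_dedicated)
    ]

    # every substrate must carry >= 1 positive, else its tyrosines would not
    # enter the derived negative set
    n_proteins = min(spec.n_proteins, spec.n_pos)
    assignments: list[list[tuple[str, bool]]] = [[] for _ in range(n_proteins)]
    for rank, idx in enumerate(rng.permutation(spec.n_pos)):
        assignments[rank % n_proteins].append((positives[idx], True))
    for rank, idx in enumerate(rng.permutation(len(negatives))):
        assignments[rank % n_proteins].append((negatives[idx], False))
    for peps in assignments:
        rng.shuffle(peps)

    proteins: list[ProteinRecord] = []
    sites: list[ModSite] = []
    for pi, peps in enumerate(assignments):
        pid = f"SYN{pi:04d}_HUMAN"
        chunks: list[str] = []
        length = 0
        for pep, is_pos in peps:
            linker = _sample_background(rng, int(rng.integers(8, 20)))
            chunks.append(linker)
            length += len(linker)
            center = length + m + 1
            chunks.append(pep)
            length += len(pep)
            if is_pos:
                sites.append(ModSite(pid, center, "Y", spec.ptm, "known"))
        chunks.append(_sample_background(rng, int(rng.integers(8, 20))))
        if not peps:  # a protein must not be empty
            chunks = [_sample_background(rng, 40)]
        proteins.append(ProteinRecord(pid, "".join(chunks), species="HUMAN"))

    dataset = SiteDataset(proteins, sites)
    n_neg_actual = len(dataset.negatives(spec.ptm))
    assert n_neg_actual == spec.n_neg, (n_neg_actual, spec.n_neg)
    truth = {
        "seed": spec.seed,
        "n_pos": spec.n_pos,
        "n_neg": spec.n_neg,
        "n_proteins": spec.n_proteins,
        "window": list(spec.window),
        "null_motif": spec.motif is None,
        "incidental_tyrosines": incidental,
    }
    return dataset, truth


def write_motif_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_motif_dataset(spec)
    write_fasta(dataset.proteins.values(), outdir / "proteins.fasta")
    write_site_table(dataset, outdir / "sites.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


# ---------------------------------------------------------------------------
# ortholog set
# ---------------------------------------------------------------------------


def generate_ortholog_set(
    spec: SyntheticSpec,
) -> tuple[list[OrthologGroup], list[ModSite], dict[str, dict[str, list[BlastHit]]], dict]:
    """Human-anchored ortholog groups with planted per-class conservation.

    The planted "conservation rate" of a class is the probability that a
    site's column is fully retained (tyrosine in all eight species, hence
    RCS_Y = 1).  A non-conserved column keeps the tyrosine in human and
    zebrafish — so the MBL pair spans the root and N = 8 — and loses it in
    one to three internal species, forcing RCS_Y < 1.  Hit tables are
    consistent with the true orthology; decoy hits score strictly lower.
    """
    rng = np.random.default_rng(spec.seed)
    groups: list[OrthologGroup] = []
    sites: list[ModSite] = []
    truth_sites: list[dict] = []
    hits: dict[str, dict[str, list[BlastHit]]] = {
        sp: {"fwd": [], "rev": []} for sp in SPECIES if sp != "HUMAN"
    }
    per_class = spec.sites_per_class_per_group

    for gi in range(spec.n_groups):
        # human sequence: tyrosine-free segments with planted Y positions
        n_sites = 2 * per_class
        segments = [_sample_background(rng, int(rng.integers(10, 18))) for _ in range(n_sites + 1)]
        human_seq = segments[0]
        y_positions: list[int] = []
        for seg in segments[1:]:
            human_seq += "Y"
            y_positions.append(len(human_seq))
            human_seq += seg
        classes = ["modified"] * per_class + ["unmodified"] * per_class
        rng.shuffle(classes)

        length = len(human_seq)
        anchor_id = f"G{gi:04d}_HUMAN"
        rows: dict[str, list[str]] = {"HUMAN": list(human_seq)}
        # homologous rows: per-species substitutions and sparse deletions
        for sp in SPECIES[1:]:
            row = list(human_seq)
            p_sub = min(0.30, 0.25 * _TREE_DIST[sp])
            p_gap = 0.02
            for ci in range(length):
                if human_seq[ci] == "Y":
                    continue  # tyrosine columns handled below
                r = rng.random()
                if r < p_gap:
                    row[ci] = "-"
                elif r < p_gap + p_sub:
                    row[ci] = _BG_NOY_AAS[int(rng.integers(len(_BG_NOY_AAS)))]
            rows[sp] = row

        for pos, cls in zip(y_positions, classes):
            rate = spec.conservation[cls]
            conserved = bool(rng.random() < rate)
            ci = pos - 1
            if not conserved:
                n_lost = int(rng.integers(1, 4))
                losers = rng.choice(INTERNAL_SPECIES, size=n_lost, replace=False)
                for sp in losers:
                    rows[sp][ci] = str(rng.choice(list("FHLNS")))
            if cls == "modified":
                sites.append(ModSite(anchor_id, pos, "Y", "phosphorylation", "known"))
            truth_sites.append(
                {"group": anchor_id, "position": pos, "class": cls, "conserved": conserved}
            )

        members = {
            sp: ProteinRecord(f"G{gi:04d}_{sp}", "".join(row), species=sp)
            for sp, row in rows.items()
        }
        groups.append(OrthologGroup(anchor_id, "HUMAN", members))

        # hit tables: one true reciprocal pair per group plus a weaker decoy
        for sp in SPECIES[1:]:
            partner = f"G{gi:04d}_{sp}"
            score = float(280.0 + rng.normal(0.0, 15.0))
            decoy_gi = (gi + 1) % spec.n_groups
            decoy_score = score * 0.45
            common = dict(length=length, mismatch=0, gapopen=0, qstart=1,
                          qend=length, sstart=1, send=length)
            hits[sp]["fwd"].append(
                BlastHit(anchor_id, partner, 95.0, evalue=1e-60, bitscore=round(score, 1), **common)
            )
            hits[sp]["fwd"].append(
                BlastHit(anchor_id, f"G{decoy_gi:04d}_{sp}", 40.0, evalue=1e-10,
                         bitscore=round(decoy_score, 1), **common)
            )
            hits[sp]["rev"].append(
                BlastHit(partner, anchor_id, 95.0, evalue=1e-60, bitscore=round(score, 1), **common)
            )
            hits[sp]["rev"].append(
                BlastHit(partner, f"G{decoy_gi:04d}_HUMAN", 40.0, evalue=1e-10,
                         bitscore=round(decoy_score, 1), **common)
            )

    truth = {
        "seed": spec.seed,
        "n_groups": spec.n_groups,
        "conservation": dict(spec.conservation),
        "sites": truth_sites,
        "conserved_fraction": {
            cls: float(
                np.mean([t["conserved"] for t in truth_sites if t["class"] == cls])
            )
            for cls in ("modified", "unmodified")
        },
    }
    return groups, sites, hits, truth


def _tree_distances() -> dict[str, float]:
    from .io import read_newick_string

    tree = read_newick_string(SPECIES_TREE_NEWICK)
    return {sp: tree.patristic("HUMAN", sp) for sp in SPECIES if sp != "HUMAN"}


_TREE_DIST = _tree_distances()


def write_ortholog_set(spec: SyntheticSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    (outdir / "groups").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    groups, sites, hits, truth = generate_ortholog_set(spec)
    for g in groups:
        write_fasta(g.members.values(), outdir / "groups" / f"{g.anchor.split('_')[0]}.fasta")
    anchors = [g.members["HUMAN"] for g in groups]
    ungapped = [ProteinRecord(r.id, r.sequence.replace("-", ""), r.species) for r in anchors]
    write_fasta(ungapped, outdir / "human.fasta")
    write_site_table(sites, outdir / "sites.tsv")
    (outdir / "tree.nwk").write_text(spec.tree + "\n")
    for sp, tables in hits.items():
        write_blast_tabular(tables["fwd"], outdir / "hits" / f"HUMAN_{sp}.tsv")
        write_blast_tabular(tables["rev"], outdir / "hits" / f"{sp}_HUMAN.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


# ---------------------------------------------------------------------------
# annotations / variants / structure
# ---------------------------------------------------------------------------


def generate_annotations(spec: SyntheticSpec) -> tuple[dict[str, set[str]], list[str], dict]:
    """An annotation mapping with one planted enriched term.

    The planted term annotates every foreground protein but only a fixed
    fraction of the rest of the background; base terms annotate proteins at
    random rates, and a fallback term guarantees every protein >= 1 term.
    """
    rng = np.random.default_rng(spec.seed)
    background = [f"P{i:05d}" for i in range(spec.n_background_proteins)]
    foreground = background[: spec.n_foreground_proteins]
    mapping: dict[str, set[str]] = {p: set() for p in background}
    base_rates = {}
    for t in range(spec.n_base_terms):
        term = f"GO:BASE{t:02d}"
        rate = float(rng.uniform(0.05, 0.30))
        base_rates[term] = rate
        for p in background:
            if rng.random() < rate:
                mapping[p].add(term)
    for p in foreground:
        mapping[p].add(spec.planted_term)
    for p in background[spec.n_foreground_proteins:]:
        if rng.random() < spec.planted_background_rate:
            mapping[p].add(spec.planted_term)
    for p in background:
        if not mapping[p]:
            mapping[p].add("GO:FALLBACK")
    truth = {
        "seed": spec.seed,
        "planted_term": spec.planted_term,
        "planted_background_rate": spec.planted_background_rate,
        "base_rates": base_rates,
        "foreground": foreground,
    }
    return mapping, foreground, truth


def write_annotations(spec: SyntheticSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping, foreground, truth = generate_annotations(spec)
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("protein_id\tterm\n")
        for p in sorted(mapping):
            for t in sorted(mapping[p]):
                fh.write(f"{p}\t{t}\n")
    (outdir / "foreground.txt").write_text("\n".join(foreground) + "\n")
    (outdir / "background.txt").write_text("\n".join(sorted(mapping)) + "\n")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


def generate_variants(
    spec: SyntheticSpec,
) -> tuple[list[tuple[str, int]], list[VariantRecord], dict]:
    """Tyrosine sites with a planted variant hit rate and rare/common AF mix.

    Each site is hit by >= 1 tyrosine variant with probability
    ``variant_hit_rate``; population allele frequencies are drawn from a
    rare/common mixture with rare weight ``rare_weight`` (rare = log-uniform
    on [1e-4, 1e-2), common = uniform on [1e-2, 0.5]), so the analytic rare
    fraction equals the mixture weight.
    """
    rng = np.random.default_rng(spec.seed)
    sites: list[tuple[str, int]] = []
    variants: list[VariantRecord] = []
    n_hit = 0
    alts = list("FCHNSD")
    for i in range(spec.n_variant_sites):
        pid = f"V{i // 10:04d}"
        pos = 10 * (i % 10 + 1)
        sites.append((pid, pos))
        if rng.random() < spec.variant_hit_rate:
            n_hit += 1
            for _ in range(int(rng.integers(1, 3))):
                if rng.random() < spec.rare_weight:
                    af = float(10 ** rng.uniform(-4, -2))
                    af = min(af, np.nextafter(0.01, 0))
                else:
                    af = float(rng.uniform(0.01, 0.5))
                variants.append(
                    VariantRecord(pid, pos, "Y", str(rng.choice(alts)), af, "population")
                )
        # decoy variant off-site
        if rng.random() < 0.05:
            variants.append(
                VariantRecord(pid, 10 * (i % 10 + 1) + 1, "A",
                              str(rng.choice(alts)), None, "inherited_disease")
            )
    truth = {
        "seed": spec.seed,
        "n_sites": spec.n_variant_sites,
        "hit_rate": spec.variant_hit_rate,
        "rare_weight": spec.rare_weight,
        "n_hit_sites": n_hit,
    }
    return sites, variants, truth


def write_variants(spec: SyntheticSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites, variants, truth = generate_variants(spec)
    with open(outdir / "sites.txt", "w") as fh:
        for pid, pos in sites:
            fh.write(f"{pid}\t{pos}\n")
    write_variant_table(variants, outdir / "variants.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


def _category_probs(rng: np.random.Generator, chosen: str) -> tuple[float, float, float]:
    """(p_helix, p_strand, p_coil) whose argmax is `chosen`."""
    top = float(rng.uniform(0.55, 0.85))
    split = float(rng.uniform(0.2, 0.8))
    rest = 1.0 - top
    others = (rest * split, rest * (1 - split))
    if chosen == "helix":
        return (top, others[0], others[1])
    if chosen == "strand":
        return (others[0], top, others[1])
    return (others[0], others[1], top)


def generate_structure_annotations(
    spec: SyntheticSpec,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]],
           dict[tuple[str, int], StructureAnnotation], dict]:
    """Structure annotations with a planted coil skew for modified sites.

    Modified sites are coil with probability ``coil_rate_modified`` versus
    ``coil_rate_background`` for background tyrosines (helix/strand split the
    remainder evenly), so the planted coil E-ratio is the rate ratio.
    """
    rng = np.random.default_rng(spec.seed)
    annotations: dict[tuple[str, int], StructureAnnotation] = {}

    def make(prefix: str, n: int, coil_rate: float) -> list[tuple[str, int]]:
        out = []
        for i in range(n):
            key = (f"{prefix}{i // 20:04d}", 5 * (i % 20 + 1))
            out.append(key)
            r = rng.random()
            if r < coil_rate:
                chosen = "coil"
            elif r < coil_rate + (1 - coil_rate) / 2:
                chosen = "helix"
            else:
                chosen = "strand"
            ph, ps, pc = _category_probs(rng, chosen)
            rsa = float(rng.uniform(0.25, 1.0)) if rng.random() < spec.exposed_rate \
                else float(rng.uniform(0.0, 0.25 - 1e-9))
            dis = float(rng.uniform(0.5, 1.0)) if rng.random() < spec.disordered_rate \
                else float(rng.uniform(0.0, 0.5 - 1e-9))
            annotations[key] = StructureAnnotation(key[0], key[1], ph, ps, pc, rsa, dis)
        return out

    modified = make("MOD", spec.n_structure_sites, spec.coil_rate_modified)
    background = make("BGR", spec.n_structure_sites, spec.coil_rate_background)
    truth = {
        "seed": spec.seed,
        "coil_rate_modified": spec.coil_rate_modified,
        "coil_rate_background": spec.coil_rate_background,
        "planted_coil_e_ratio": spec.coil_rate_modified / spec.coil_rate_background,
        "exposed_rate": spec.exposed_rate,
        "disordered_rate": spec.disordered_rate,
    }
    return modified, background, annotations, truth


def write_structure_annotations(spec: SyntheticSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    modified, background, annotations, truth = generate_structure_annotations(spec)
    write_structure_table(
        [annotations[k] for k in sorted(annotations)], outdir / "structure.tsv"
    )
    with open(outdir / "modified_sites.txt", "w") as fh:
        for pid, pos in modified:
            fh.write(f"{pid}\t{pos}\n")
    with open(outdir / "background_sites.txt", "w") as fh:
        for pid, pos in background:
            fh.write(f"{pid}\t{pos}\n")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
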