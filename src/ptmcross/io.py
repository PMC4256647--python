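"""Domain types and readers/writers for every external format the package touches.

Coordinates are 1-based and inclusive throughout (the UniProt convention);
conversion to Python offsets happens only inside this module.  Window padding
beyond protein termini uses ``'*'``, which every scoring routine treats as
inert (score 0 against any residue).

Formats handled here: plain and aligned FASTA, the package's TSV site /
variant / annotation dialects (headers documented in the README), BLAST
tabular (outfmt 6), a GAF 2.x subset, and newick species trees.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Phylo, SeqIO

log = logging.getLogger(__name__)

#: The 20 standard residues plus X for anything ambiguous.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
#: Non-standard letters silently folded into X on read.
NONSTANDARD_MAP = {"U": "X", "B": "X", "Z": "X", "O": "X", "J": "X"}

PTM_TYPES = frozenset({"sulfation", "nitration", "phosphorylation"})
EVIDENCE_TYPES = frozenset({"known", "predicted"})
VARIANT_SOURCES = frozenset({"inherited_disease", "cancer", "population"})

PAD = "*"


class FormatError(ValueError):
    """Raised when an input file does not parse under its declared format."""


class ValidationError(ValueError):
    """Raised when parsed records violate dataset invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and (optional) species label."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"protein {self.id!r}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class ModSite:
    """One typed modification site: (protein, 1-based position, PTM class)."""

    protein_id: str
    position: int
    residue: str
    ptm: str
    evidence: str = "known"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.ptm not in PTM_TYPES:
            raise ValidationError(f"unknown ptm type {self.ptm!r}")
        if self.evidence not in EVIDENCE_TYPES:
            raise ValidationError(f"unknown evidence class {self.evidence!r}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.position, self.ptm)


class SiteDataset:
    """Proteins plus their typed PTM site annotations.

    Positives of a PTM class are the annotated sites; negatives are derived:
    every other tyrosine of a protein carrying at least one positive site of
    that class.  The two sets are disjoint by construction.
    """

    def __init__(self, proteins: Iterable[ProteinRecord], sites: Iterable[ModSite]):
        self.proteins: dict[str, ProteinRecord] = {}
        for rec in proteins:
            if rec.id in self.proteins:
                raise ValidationError(f"duplicate protein id {rec.id!r}")
            self.proteins[rec.id] = rec
        self.sites: list[ModSite] = []
        seen: set[tuple[str, int, str]] = set()
        for site in sites:
            if site.protein_id not in self.proteins:
                raise ValidationError(f"site references unknown protein {site.protein_id!r}")
            rec = self.proteins[site.protein_id]
            if rec.residue(site.position) != site.residue:
                raise ValidationError(
                    f"site {site.protein_id}:{site.position} declares residue "
                    f"{site.residue!r} but sequence has {rec.residue(site.position)!r}"
                )
            if site.key in seen:
                raise ValidationError(f"duplicate site {site.key}")
            seen.add(site.key)
            self.sites.append(site)

    def positives(self, ptm: str) -> list[ModSite]:
        return [s for s in self.sites if s.ptm == ptm]

    def negatives(self, ptm: str) -> list[tuple[str, int]]:
        """All non-positive tyrosines of proteins bearing >=1 positive of *ptm*."""
        pos = {(s.protein_id, s.position) for s in self.positives(ptm)}
        substrate_ids = sorted({pid for pid, _ in pos})
        neg: list[tuple[str, int]] = []
        for pid in substrate_ids:
            seq = self.proteins[pid].sequence
            for i, aa in enumerate(seq, start=1):
                if aa == "Y" and (pid, i) not in pos:
                    neg.append((pid, i))
        return neg

    def substrates(self, ptm: str) -> list[ProteinRecord]:
        ids = sorted({s.protein_id for s in self.positives(ptm)})
        return [self.proteins[i] for i in ids]


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-shape peptide around a central residue.

    ``letters`` has length ``m + 1 + n`` with ``'*'`` padding for positions
    that fall outside the protein.
    """

    protein_id: str
    position: int
    m: int
    n: int
    letters: str

    def __post_init__(self) -> None:
        if len(self.letters) != self.m + 1 + self.n:
            raise ValidationError(
                f"window {self.protein_id}:{self.position}: letters length "
                f"{len(self.letters)} != {self.m}+1+{self.n}"
            )

    @property
    def center(self) -> str:
        return self.letters[self.m]


@dataclass(frozen=True)
class VariantRecord:
    """A single amino-acid variant with optional population allele frequency."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    allele_frequency: float | None = None
    source: str = "population"

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError("ref_aa must differ from alt_aa")
        if self.allele_frequency is not None and not 0.0 <= self.allele_frequency <= 1.0:
            raise ValidationError(f"allele frequency {self.allele_frequency} outside [0, 1]")
        if self.source not in VARIANT_SOURCES:
            raise ValidationError(f"unknown variant source {self.source!r}")


@dataclass
class AnnotationTable:
    """protein id -> set of term ids, with optional term metadata."""

    mapping: dict[str, set[str]] = field(default_factory=dict)
    terms: dict[str, dict[str, str]] = field(default_factory=dict)

    def annotated(self) -> set[str]:
        return {p for p, t in self.mapping.items() if t}

    def proteins_with(self, term: str) -> set[str]:
        return {p for p, t in self.mapping.items() if term in t}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.mapping.values():
            out |= t
        return out


class SpeciesTree:
    """A rooted species tree with branch lengths, wrapping ``Bio.Phylo``."""

    def __init__(self, tree) -> None:
        self._tree = tree
        self._clades = {}
        for leaf in tree.get_terminals():
            if leaf.name in self._clades:
                raise FormatError(f"duplicate leaf label {leaf.name!r}")
            self._clades[leaf.name] = leaf

    @property
    def leaves(self) -> set[str]:
        return set(self._clades)

    def _leaf(self, name: str):
        try:
            return self._clades[name]
        except KeyError:
            raise KeyError(f"unknown leaf label {name!r}") from None

    def patristic(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique path between two leaves."""
        if a == b:
            self._leaf(a)
            return 0.0
        return float(self._tree.distance(self._leaf(a), self._leaf(b)))

    def clade_leafset(self, a: str, b: str) -> set[str]:
        """Leaf labels under the smallest clade containing both *a* and *b*."""
        if a == b:
            return {a}
        mrca = self._tree.common_ancestor(self._leaf(a), self._leaf(b))
        return {t.name for t in mrca.get_terminals()}


def patristic_distance(tree: SpeciesTree, a: str, b: str) -> float:
    return tree.patristic(a, b)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _clean_sequence(raw: str, rec_id: str, aligned: bool) -> str:
    seq = raw.upper()
    cleaned = []
    warned = False
    allowed = VALID_RESIDUES | ({"-"} if aligned else set())
    for ch in seq:
        if ch in NONSTANDARD_MAP:
            if not warned:
                log.warning("protein %s: non-standard residues mapped to X", rec_id)
                warned = True
            ch = "X"
        if ch not in allowed:
            raise FormatError(f"protein {rec_id!r}: invalid character {ch!r} in sequence")
        cleaned.append(ch)
    return "".join(cleaned)


def _species_from_id(rec_id: str) -> str:
    # UniProt mnemonic convention NAME_SPECIES; empty when absent.
    if "_" in rec_id:
        return rec_id.rsplit("_", 1)[1]
    return ""


def _read_fasta_records(path: str | Path, aligned: bool) -> list[ProteinRecord]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id, aligned)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(ProteinRecord(rec.id, seq, species=_species_from_id(rec.id)))
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a plain (ungapped) FASTA file."""
    return _read_fasta_records(path, aligned=False)


def read_aligned_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an aligned FASTA file; ``'-'`` gap characters are retained."""
    records = _read_fasta_records(path, aligned=True)
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"{path}: aligned sequences have unequal lengths {sorted(lengths)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site / variant / annotation tables
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ["protein_id", "position", "residue", "ptm", "evidence"]
VARIANT_TABLE_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "af", "source"]


def _open_tsv(path: str | Path, required: Sequence[str]) -> Iterator[dict[str, str]]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        yield from reader


def read_site_table(path: str | Path, proteins: Iterable[ProteinRecord]) -> SiteDataset:
    """Read the package's TSV site dialect and validate against sequences.

    Validation failures are pooled so a single error names every bad row.
    """
    proteins = list(proteins)
    sites: list[ModSite] = []
    bad: list[str] = []
    for lineno, row in enumerate(_open_tsv(path, SITE_TABLE_COLUMNS), start=2):
        try:
            sites.append(
                ModSite(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    residue=row["residue"],
                    ptm=row["ptm"],
                    evidence=row["evidence"],
                )
            )
        except (ValueError, ValidationError) as exc:
            bad.append(f"row {lineno}: {exc}")
    if bad:
        raise ValidationError(f"{path}: " + "; ".join(bad))
    try:
        return SiteDataset(proteins, sites)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_site_table(dataset_or_sites, path: str | Path) -> None:
    sites = dataset_or_sites.sites if isinstance(dataset_or_sites, SiteDataset) else dataset_or_sites
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for s in sites:
            writer.writerow([s.protein_id, s.position, s.residue, s.ptm, s.evidence])


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    bad: list[str] = []
    for lineno, row in enumerate(_open_tsv(path, VARIANT_TABLE_COLUMNS), start=2):
        try:
            af = row["af"].strip()
            out.append(
                VariantRecord(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    ref_aa=row["ref_aa"],
                    alt_aa=row["alt_aa"],
                    allele_frequency=float(af) if af else None,
                    source=row["source"],
                )
            )
        except (ValueError, ValidationError) as exc:
            bad.append(f"row {lineno}: {exc}")
    if bad:
        raise ValidationError(f"{path}: " + "; ".join(bad))
    return out


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_TABLE_COLUMNS)
        for v in variants:
            af = "" if v.allele_frequency is None else repr(v.allele_frequency)
            writer.writerow([v.protein_id, v.position, v.ref_aa, v.alt_aa, af, v.source])


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Two-column TSV: protein_id <tab> term_id (one association per row)."""
    table = AnnotationTable()
    for row in _open_tsv(path, ["protein_id", "term"]):
        table.mapping.setdefault(row["protein_id"], set()).add(row["term"])
    table.mapping = {p: t for p, t in table.mapping.items() if t}
    return table


def read_gaf(path: str | Path) -> AnnotationTable:
    """GAF 2.x subset reader: DB Object ID (col 2), GO ID (col 5), Aspect (col 9)."""
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: fewer than 9 GAF columns")
            pid, term, aspect = fields[1], fields[4], fields[8]
            table.mapping.setdefault(pid, set()).add(term)
            table.terms.setdefault(term, {"id": term, "name": "", "namespace": aspect})
    return table


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output.  An empty file yields an empty list."""
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query=fields[0],
                        subject=fields[1],
                        pident=float(fields[2]),
                        length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_blast_tabular(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        f"{h.pident:.2f}",
                        str(h.length),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.2g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> SpeciesTree:
    tree = Phylo.read(str(path), "newick")
    return SpeciesTree(tree)


def read_newick_string(newick: str) -> SpeciesTree:
    import io as _io

    tree = Phylo.read(_io.StringIO(newick), "newick")
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# peptide windows
# ---------------------------------------------------------------------------


def extract_window(protein: ProteinRecord, position: int, m: int, n: int) -> PeptideWindow:
    """Cut the ``PY(m, n)`` peptide around a 1-based position.

    Positions falling outside ``[1, len]`` are padded with ``'*'``.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValidationError(
            f"protein {protein.id!r}: position {position} outside 1..{len(seq)}"
        )
    letters = []
    for offset in range(-m, n + 1):
        p = position + offset
        letters.append(seq[p - 1] if 1 <= p <= len(seq) else PAD)
    return PeptideWindow(protein.id, position, m, n, "".join(letters))


def windows_for_sites(
    proteins: Mapping[str, ProteinRecord],
    sites: Iterable[tuple[str, int]] | Iterable[ModSite],
    m: int,
    n: int,
) -> list[PeptideWindow]:
    out = []
    for s in sites:
        pid, pos = (s.protein_id, s.position) if isinstance(s, ModSite) else s
        out.append(extract_window(proteins[pid], pos, m, n))
    return out
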