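"""Genome annotation model: gene records, neighbour pairs, and pair filters.

Coordinates follow the usual dual convention: GFF3 files on disk are 1-based
inclusive, everything in memory is 0-based half-open.  Under the half-open
convention the gap between two transcripts is simply ``right.tx_start -
left.tx_end``: abutting transcripts have gap 0 and overlapping ones a
negative gap.
"""

from __future__ import annotations

import logging
import urllib.parse
from bisect import bisect_right, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"
OTHER = "other"

#: relative orientations of an ordered (left, right) gene pair
BIDIRECTIONAL = "bidirectional"  # <- ->  (divergent; 5' ends face the gap)
UNIDIRECTIONAL = "unidirectional"  # -> -> or <- <-
CONVERGENT = "convergent"  # -> <-  (3' ends face the gap)

ORIENTATIONS = (BIDIRECTIONAL, UNIDIRECTIONAL, CONVERGENT)

#: overlap taxonomy for opposite-strand gene pairs
OVERLAP_NONE = "none"
OVERLAP_3P = "overlap_3p"  # partial overlap of both 3' ends (convergent)
OVERLAP_5P = "overlap_5p"  # partial overlap of both 5' ends (divergent)
OVERLAP_CONTAINED = "contained"  # one gene nested inside the other
OVERLAP_UNCLASSIFIABLE = "unclassifiable"  # same-strand overlap; excluded

# GFF3 feature types accepted as genes.  Types other than plain "gene" are
# kept but marked non-coding so they still count as intervening transcripts.
_GENE_TYPES = {
    "gene": None,
    "protein_coding_gene": PROTEIN_CODING,
    "ncRNA_gene": OTHER,
    "pseudogene": OTHER,
    "transposable_element_gene": OTHER,
}

_NONCODING_BIOTYPE_HINTS = (
    "rna", "pseudo", "transposable", "other", "antisense", "mirna",
)


class GFF3ParseError(ValueError):
    """Raised for a structurally malformed GFF3 line (carries line number)."""


@dataclass(frozen=True)
class GeneRecord:
    """One transcript-bearing gene locus.

    ``tx_start``/``tx_end`` are the outermost transcript boundaries of the
    gene feature, 0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tx_start: int
    tx_end: int
    biotype: str = PROTEIN_CODING

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def overlaps(self, other: "GeneRecord") -> bool:
        return (
            self.chrom == other.chrom
            and self.tx_start < other.tx_end
            and other.tx_start < self.tx_end
        )


@dataclass
class Annotation:
    """Genes grouped per chromosome, sorted by (tx_start, tx_end, gene_id)."""

    genes_by_chrom: dict[str, list[GeneRecord]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[GeneRecord]) -> "Annotation":
        by_chrom: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in annotation")
            seen.add(rec.gene_id)
            by_chrom.setdefault(rec.chrom, []).append(rec)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda g: (g.tx_start, g.tx_end, g.gene_id))
        return cls(by_chrom)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in sorted(self.genes_by_chrom):
            yield from self.genes_by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self.genes_by_chrom.values())

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.genes_by_chrom)

    def get(self, gene_id: str) -> GeneRecord:
        for genes in self.genes_by_chrom.values():
            for g in genes:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def gene_ids(self, biotype: str | None = None) -> list[str]:
        return [g.gene_id for g in self if biotype is None or g.biotype == biotype]

    def overlapping_gene_ids(self) -> set[str]:
        """Ids of genes whose interval intersects any other annotated gene."""
        flagged: set[str] = set()
        for genes in self.genes_by_chrom.values():
            # sweep over start-sorted genes; intervals still open when the
            # next gene starts overlap it
            open_owner: list[GeneRecord] = []
            for g in genes:
                still_open = [o for o in open_owner if o.tx_end > g.tx_start]
                if still_open:
                    flagged.add(g.gene_id)
                    flagged.update(o.gene_id for o in still_open)
                open_owner = still_open + [g]
        return flagged


@dataclass(frozen=True)
class NeighborPair:
    """An ordered same-chromosome gene pair (left precedes right)."""

    left: GeneRecord
    right: GeneRecord
    orientation: str
    overlap_class: str
    intergenic_bp: int
    n_intervening: int = 0

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("pair members must share a chromosome")
        if self.left.tx_start > self.right.tx_start:
            raise ValueError("pair members must be in genomic order")
        if (self.overlap_class == OVERLAP_NONE) != (self.intergenic_bp >= 0):
            raise ValueError(
                f"pair {self.pair_id}: overlap_class {self.overlap_class!r} "
                f"inconsistent with intergenic_bp {self.intergenic_bp}"
            )
        if self.n_intervening < 0:
            raise ValueError("n_intervening must be >= 0")

    @property
    def pair_id(self) -> str:
        return f"{self.left.gene_id}|{self.right.gene_id}"

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def gene_ids(self) -> tuple[str, str]:
        return (self.left.gene_id, self.right.gene_id)


# ---------------------------------------------------------------------------
# GFF3 input / output
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def _infer_biotype(ftype: str, attrs: Mapping[str, str]) -> str:
    for key in ("biotype", "gene_biotype", "locus_type", "so_term_name"):
        if key in attrs:
            value = attrs[key].lower()
            if value == PROTEIN_CODING:
                return PROTEIN_CODING
            if any(h in value for h in _NONCODING_BIOTYPE_HINTS):
                return OTHER
            return OTHER
    fixed = _GENE_TYPES.get(ftype)
    if fixed is not None:
        return fixed
    # bare "gene" feature with no biotype attribute: assume protein coding,
    # matching TAIR-style annotations where ncRNAs use dedicated types
    return PROTEIN_CODING


def read_gff3(path: str | Path) -> Annotation:
    """Read gene features from a GFF3 file into an :class:`Annotation`.

    Only gene-level features are retained (mRNA/exon/CDS children are
    skipped); disk coordinates (1-based inclusive) are converted to 0-based
    half-open.  Gene features with a strand other than ``+``/``-`` are
    rejected with a warning; structurally malformed lines raise
    :class:`GFF3ParseError` with the offending line number.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr = fields
            if ftype not in _GENE_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from exc
            if strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: gene with strand %r rejected", path.name, lineno, strand
                )
                continue
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            if gene_id is None:
                raise GFF3ParseError(f"{path.name}:{lineno}: gene feature without ID")
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start - 1,  # to 0-based half-open
                    tx_end=end,
                    biotype=_infer_biotype(ftype, attrs),
                )
            )
    if not records:
        logger.warning("%s: no gene features found; annotation is empty", path.name)
    return Annotation.from_records(records)


def write_gff3(ann: Annotation, path: str | Path) -> None:
    """Write gene features back to GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ann:
            biotype = gene.biotype
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "coexpair",
                        "gene",
                        str(gene.tx_start + 1),
                        str(gene.tx_end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id};biotype={biotype}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def classify_orientation(left: GeneRecord, right: GeneRecord) -> str:
    """Relative orientation of an ordered gene pair.

    ``(-,+)`` is bidirectional/divergent (5' ends face each other),
    ``(+,-)`` convergent (3' ends face each other), equal strands
    unidirectional.
    """
    if left.chrom != right.chrom:
        raise ValueError("orientation is defined for same-chromosome pairs only")
    if left.strand == right.strand:
        return UNIDIRECTIONAL
    return BIDIRECTIONAL if left.strand == "-" else CONVERGENT


def classify_overlap(left: GeneRecord, right: GeneRecord) -> str:
    """Overlap taxonomy for an ordered gene pair.

    The taxonomy is defined for opposite-strand overlaps only: partial
    overlap in convergent geometry involves both 3' ends (``overlap_3p``),
    in divergent geometry both 5' ends (``overlap_5p``); full nesting is
    ``contained``.  Same-strand overlapping pairs are flagged
    ``unclassifiable`` with a warning and excluded from downstream
    overlap statistics.  Symmetric in the order of its arguments.
    """
    if left.tx_start > right.tx_start:
        left, right = right, left
    inter = min(left.tx_end, right.tx_end) - max(left.tx_start, right.tx_start)
    if inter <= 0:
        return OVERLAP_NONE
    if left.strand == right.strand:
        logger.warning(
            "same-strand overlap between %s and %s is unclassifiable",
            left.gene_id, right.gene_id,
        )
        return OVERLAP_UNCLASSIFIABLE
    if (left.tx_start <= right.tx_start and right.tx_end <= left.tx_end) or (
        right.tx_start <= left.tx_start and left.tx_end <= right.tx_end
    ):
        return OVERLAP_CONTAINED
    # partial overlap between ordered opposite-strand genes: the facing ends
    # intersect, and which ends face depends on the orientation
    return OVERLAP_3P if left.strand == "+" else OVERLAP_5P


def intergenic_bp(left: GeneRecord, right: GeneRecord) -> int:
    """Bases strictly between the two transcripts (negative iff overlapping)."""
    if left.chrom != right.chrom:
        raise ValueError("intergenic distance is defined within a chromosome")
    if left.tx_start > right.tx_start:
        raise ValueError("pair must be in genomic order")
    return right.tx_start - left.tx_end


def _make_pair(left: GeneRecord, right: GeneRecord, n_intervening: int) -> NeighborPair:
    return NeighborPair(
        left=left,
        right=right,
        orientation=classify_orientation(left, right),
        overlap_class=classify_overlap(left, right),
        intergenic_bp=intergenic_bp(left, right),
        n_intervening=n_intervening,
    )


def direct_neighbor_pairs(ann: Annotation) -> list[NeighborPair]:
    """All directly adjacent protein-coding gene pairs.

    Adjacency is over *all* annotated genes, so a protein-coding pair
    separated by a non-coding gene is not emitted ("no intervening genes,
    coding or non-coding").
    """
    pairs: list[NeighborPair] = []
    for chrom in sorted(ann.genes_by_chrom):
        genes = ann.genes_by_chrom[chrom]
        for left, right in zip(genes, genes[1:]):
            if left.biotype == PROTEIN_CODING and right.biotype == PROTEIN_CODING:
                pairs.append(_make_pair(left, right, n_intervening=0))
    return pairs


def all_chromosome_pairs(ann: Annotation, max_intervening: int) -> list[NeighborPair]:
    """All same-chromosome protein-coding pairs up to ``max_intervening``.

    ``n_intervening`` counts annotated transcripts of any biotype whose full
    interval lies between the pair's facing transcript boundaries.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    pairs: list[NeighborPair] = []
    for chrom in sorted(ann.genes_by_chrom):
        genes = ann.genes_by_chrom[chrom]
        n = len(genes)
        for i in range(n):
            left = genes[i]
            # an intervener of (i, j) must start at/after left.tx_end and end
            # at/before right.tx_start; with start-sorted genes only indices
            # strictly between i and j qualify, and the count is
            # non-decreasing in j, allowing an early break
            cand_ends: list[int] = []
            for j in range(i + 1, n):
                right = genes[j]
                if j - 1 > i:
                    prev = genes[j - 1]
                    if prev.tx_start >= left.tx_end:
                        insort(cand_ends, prev.tx_end)
                n_between = bisect_right(cand_ends, right.tx_start)
                if n_between > max_intervening:
                    break
                if (
                    left.biotype == PROTEIN_CODING
                    and right.biotype == PROTEIN_CODING
                ):
                    pairs.append(_make_pair(left, right, n_intervening=n_between))
    return pairs


# ---------------------------------------------------------------------------
# Pair filters
# ---------------------------------------------------------------------------

def filter_overlapping_genes(
    pairs: Sequence[NeighborPair], ann: Annotation
) -> list[NeighborPair]:
    """Keep only pairs whose members overlap no other annotated gene.

    Pairs whose two members overlap each other are also removed here; they
    belong to the opposite-strand overlap analysis instead.
    """
    flagged = ann.overlapping_gene_ids()
    kept = [
        p
        for p in pairs
        if p.left.gene_id not in flagged and p.right.gene_id not in flagged
    ]
    logger.info(
        "overlap filter: %d of %d pairs retained", len(kept), len(pairs)
    )
    return kept


def filter_tandem_duplicates(
    pairs: Sequence[NeighborPair],
    similarity: Iterable[tuple[str, str, float]],
    threshold: float = 0.2,
) -> list[NeighborPair]:
    """Remove putative tandem duplicates by pairwise-similarity E-value.

    ``similarity`` rows are ``(id_a, id_b, evalue)`` in either gene order;
    a pair listed with ``evalue < threshold`` is removed.  An empty table
    is the identity filter.
    """
    dup: set[frozenset[str]] = set()
    sim_ids: set[str] = set()
    for id_a, id_b, evalue in similarity:
        sim_ids.update((id_a, id_b))
        if float(evalue) < threshold:
            dup.add(frozenset((id_a, id_b)))
    pair_genes = {g for p in pairs for g in p.gene_ids}
    unknown = sim_ids - pair_genes
    if unknown:
        logger.warning(
            "similarity table names %d ids not present in any pair", len(unknown)
        )
    kept = [p for p in pairs if frozenset(p.gene_ids) not in dup]
    logger.info("tandem filter (E < %g): %d of %d pairs retained",
                threshold, len(kept), len(pairs))
    return kept


def exclude_gene_list(
    pairs: Sequence[NeighborPair], gene_ids: Iterable[str]
) -> list[NeighborPair]:
    """Remove pairs with either member in ``gene_ids`` (e.g. bicistronic loci)."""
    exclude = set(gene_ids)
    pair_genes = {g for p in pairs for g in p.gene_ids}
    missing = exclude - pair_genes
    if exclude and missing == exclude:
        logger.warning("exclusion list has no overlap with the pair set")
    kept = [
        p
        for p in pairs
        if p.left.gene_id not in exclude and p.right.gene_id not in exclude
    ]
    logger.info("gene-list exclusion: %d of %d pairs retained", len(kept), len(pairs))
    return kept


def orientation_counts(pairs: Sequence[NeighborPair]) -> dict[str, int]:
    """Number of pairs per relative orientation."""
    counts = {o: 0 for o in ORIENTATIONS}
    for p in pairs:
        counts[p.orientation] += 1
    return counts
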