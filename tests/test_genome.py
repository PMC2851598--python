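"""Annotation parsing, pair classification and pair filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexpair.genome import (
    BIDIRECTIONAL,
    CONVERGENT,
    OTHER,
    OVERLAP_3P,
    OVERLAP_5P,
    OVERLAP_CONTAINED,
    OVERLAP_NONE,
    OVERLAP_UNCLASSIFIABLE,
    PROTEIN_CODING,
    UNIDIRECTIONAL,
    Annotation,
    GFF3ParseError,
    all_chromosome_pairs,
    classify_orientation,
    classify_overlap,
    direct_neighbor_pairs,
    exclude_gene_list,
    filter_overlapping_genes,
    filter_tandem_duplicates,
    intergenic_bp,
    orientation_counts,
    read_gff3,
    write_gff3,
)
from conftest import brute_force_pair_index, make_gene, random_annotation


# ---------------------------------------------------------------------------
# GFF3 input
# ---------------------------------------------------------------------------

GFF3_TWO_GENES = """##gff-version 3
chr1\tTAIR\tgene\t101\t200\t.\t+\t.\tID=AT1G01;biotype=protein_coding
chr1\tTAIR\tmRNA\t101\t200\t.\t+\t.\tID=AT1G01.1;Parent=AT1G01
chr1\tTAIR\tgene\t501\t900\t.\t-\t.\tID=AT1G02;biotype=protein_coding
"""


def test_read_gff3_converts_to_zero_based_half_open(tmp_path):
    path = tmp_path / "two.gff3"
    path.write_text(GFF3_TWO_GENES)
    ann = read_gff3(path)
    genes = list(ann)
    assert [g.gene_id for g in genes] == ["AT1G01", "AT1G02"]
    assert (genes[0].tx_start, genes[0].tx_end) == (100, 200)
    assert (genes[1].tx_start, genes[1].tx_end) == (500, 900)
    assert genes[1].strand == "-"


def test_read_gff3_ignores_subfeatures_and_warns_on_empty(tmp_path, caplog):
    path = tmp_path / "cds_only.gff3"
    path.write_text("chr1\tx\tCDS\t10\t50\t.\t+\t0\tID=c1\n")
    with caplog.at_level("WARNING"):
        ann = read_gff3(path)
    assert len(ann) == 0
    assert "no gene features" in caplog.text


def test_read_gff3_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("chr1\tx\tgene\t10\n")
    with pytest.raises(GFF3ParseError, match="bad.gff3:1"):
        read_gff3(path)


def test_read_gff3_rejects_strandless_gene_with_warning(tmp_path, caplog):
    path = tmp_path / "strand.gff3"
    path.write_text(
        "chr1\tx\tgene\t10\t50\t.\t.\t.\tID=g1\n"
        "chr1\tx\tgene\t100\t150\t.\t+\t.\tID=g2\n"
    )
    with caplog.at_level("WARNING"):
        ann = read_gff3(path)
    assert [g.gene_id for g in ann] == ["g2"]
    assert "strand" in caplog.text


def test_gff3_round_trip(tmp_path):
    ann = Annotation.from_records(
        [
            make_gene("a", 100, 200, "+"),
            make_gene("b", 500, 900, "-"),
            make_gene("n", 1000, 1100, "+", biotype=OTHER),
        ]
    )
    path = tmp_path / "rt.gff3"
    write_gff3(ann, path)
    back = read_gff3(path)
    assert [
        (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.biotype)
        for g in back
    ] == [
        (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.biotype)
        for g in ann
    ]


# ---------------------------------------------------------------------------
# Classification and distances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "left_strand,right_strand,expected",
    [
        ("-", "+", BIDIRECTIONAL),
        ("+", "-", CONVERGENT),
        ("+", "+", UNIDIRECTIONAL),
        ("-", "-", UNIDIRECTIONAL),
    ],
)
def test_classify_orientation(left_strand, right_strand, expected):
    left = make_gene("l", 0, 100, left_strand)
    right = make_gene("r", 200, 300, right_strand)
    assert classify_orientation(left, right) == expected


def test_classify_orientation_requires_same_chromosome():
    with pytest.raises(ValueError):
        classify_orientation(
            make_gene("l", 0, 100, chrom="chr1"),
            make_gene("r", 200, 300, chrom="chr2"),
        )


@pytest.mark.parametrize(
    "left,right,expected",
    [
        (("+", 0, 500), (("-"), 400, 900), OVERLAP_3P),
        (("-", 0, 500), (("+"), 400, 900), OVERLAP_5P),
        (("+", 0, 1000), (("-"), 200, 300), OVERLAP_CONTAINED),
        (("+", 0, 100), (("-"), 200, 300), OVERLAP_NONE),
    ],
)
def test_classify_overlap(left, right, expected):
    lg = make_gene("l", left[1], left[2], left[0])
    rg = make_gene("r", right[1], right[2], right[0])
    assert classify_overlap(lg, rg) == expected
    # symmetric under swapping gene order
    assert classify_overlap(rg, lg) == expected


def test_same_strand_overlap_is_unclassifiable(caplog):
    lg = make_gene("l", 0, 500, "+")
    rg = make_gene("r", 400, 900, "+")
    with caplog.at_level("WARNING"):
        assert classify_overlap(lg, rg) == OVERLAP_UNCLASSIFIABLE
    assert "unclassifiable" in caplog.text


@pytest.mark.parametrize(
    "left_coords,right_coords,expected",
    [((0, 100), (100, 200), 0), ((0, 100), (500, 700), 400), ((0, 100), (50, 200), -50)],
)
def test_intergenic_bp(left_coords, right_coords, expected):
    left = make_gene("l", *left_coords, "+")
    right = make_gene("r", *right_coords, "-")
    assert intergenic_bp(left, right) == expected


def test_intergenic_bp_requires_genomic_order():
    with pytest.raises(ValueError):
        intergenic_bp(make_gene("l", 500, 700), make_gene("r", 0, 100))


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def test_direct_pairs_blocked_by_noncoding_intervener():
    ann = Annotation.from_records(
        [
            make_gene("A", 0, 100),
            make_gene("B", 200, 300, biotype=OTHER),
            make_gene("C", 400, 500),
        ]
    )
    assert direct_neighbor_pairs(ann) == []


def test_direct_pairs_adjacency_and_boundary():
    ann = Annotation.from_records(
        [make_gene("A", 0, 100), make_gene("B", 200, 300), make_gene("C", 400, 500)]
    )
    pairs = direct_neighbor_pairs(ann)
    assert [p.pair_id for p in pairs] == ["A|B", "B|C"]
    assert all(p.n_intervening == 0 for p in pairs)

    single = Annotation.from_records([make_gene("A", 0, 100)])
    assert direct_neighbor_pairs(single) == []


def test_all_chromosome_pairs_four_gene_enumeration():
    ann = Annotation.from_records(
        [
            make_gene("A", 0, 100),
            make_gene("B", 200, 300),
            make_gene("C", 400, 500),
            make_gene("D", 600, 700),
        ]
    )
    pairs = all_chromosome_pairs(ann, max_intervening=3)
    got = {p.pair_id: p.n_intervening for p in pairs}
    assert got == {
        "A|B": 0, "B|C": 0, "C|D": 0, "A|C": 1, "B|D": 1, "A|D": 2,
    }
    assert got == {
        f"{a}|{b}": v for (a, b), v in brute_force_pair_index(ann).items()
    }


def test_all_chromosome_pairs_zero_matches_direct_on_all_coding():
    rng = np.random.default_rng(5)
    ann = random_annotation(rng, n_genes=30, noncoding_prob=0.0, overlap_prob=0.0)
    direct = {p.pair_id for p in direct_neighbor_pairs(ann)}
    all0 = {p.pair_id for p in all_chromosome_pairs(ann, max_intervening=0)}
    # direct adjacency is exactly the zero-intervener set when genes
    # cannot nest (no overlaps, all coding)
    assert direct == all0


def test_all_chromosome_pairs_no_cross_chromosome():
    ann = Annotation.from_records(
        [make_gene("A", 0, 100, chrom="chr1"), make_gene("B", 0, 100, chrom="chr2")]
    )
    assert all_chromosome_pairs(ann, max_intervening=5) == []


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _simple_pairs():
    ann = Annotation.from_records(
        [
            make_gene("A", 0, 100),
            make_gene("B", 200, 300),
            make_gene("C", 500, 600),
            make_gene("N", 550, 650, biotype=OTHER),  # overlaps C
        ]
    )
    return ann, direct_neighbor_pairs(ann)


def test_filter_overlapping_genes_removes_pairs_with_overlapped_member():
    ann, pairs = _simple_pairs()
    assert [p.pair_id for p in pairs] == ["A|B", "B|C"]
    kept = filter_overlapping_genes(pairs, ann)
    assert [p.pair_id for p in kept] == ["A|B"]  # C overlaps non-coding N


def test_filter_overlapping_genes_identity_without_overlaps():
    ann = Annotation.from_records(
        [make_gene("A", 0, 100), make_gene("B", 200, 300)]
    )
    pairs = direct_neighbor_pairs(ann)
    assert filter_overlapping_genes(pairs, ann) == pairs


def test_filter_overlapping_genes_removes_mutually_overlapping_pair():
    ann = Annotation.from_records(
        [make_gene("A", 0, 500, "+"), make_gene("B", 400, 900, "-")]
    )
    pairs = direct_neighbor_pairs(ann)
    assert pairs[0].overlap_class == OVERLAP_3P
    assert filter_overlapping_genes(pairs, ann) == []


def test_filter_tandem_duplicates():
    ann = Annotation.from_records(
        [make_gene("A", 0, 100), make_gene("B", 200, 300), make_gene("C", 400, 500)]
    )
    pairs = direct_neighbor_pairs(ann)
    kept = filter_tandem_duplicates(pairs, [("B", "A", 0.01), ("B", "C", 0.5)])
    assert [p.pair_id for p in kept] == ["B|C"]  # E=0.01 removed, E=0.5 kept
    assert filter_tandem_duplicates(pairs, []) == pairs


def test_exclude_gene_list():
    ann = Annotation.from_records(
        [make_gene("A", 0, 100), make_gene("B", 200, 300), make_gene("C", 400, 500)]
    )
    pairs = direct_neighbor_pairs(ann)
    assert [p.pair_id for p in exclude_gene_list(pairs, ["A"])] == ["B|C"]
    assert exclude_gene_list(pairs, []) == pairs
    assert exclude_gene_list(pairs, ["ZZZ"]) == pairs


# ---------------------------------------------------------------------------
# Properties on random annotations
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_pair_invariants_and_oracle_on_random_annotations(seed):
    """Every emitted pair re-validates its invariants, and intervening
    counts match exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    ann = random_annotation(rng, n_genes=25)
    oracle = brute_force_pair_index(ann)
    pairs = all_chromosome_pairs(ann, max_intervening=30)
    got = {(p.left.gene_id, p.right.gene_id): p.n_intervening for p in pairs}
    expected = {k: v for k, v in oracle.items() if v <= 30}
    assert got == expected
    counts = orientation_counts(pairs)
    assert sum(counts.values()) == len(pairs)
    for p in pairs:
        assert p.left.chrom == p.right.chrom
        assert p.left.tx_start <= p.right.tx_start
        assert (p.overlap_class == OVERLAP_NONE) == (p.intergenic_bp >= 0)
        assert p.n_intervening >= 0
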