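"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from coexpair.genome import (
    OTHER,
    PROTEIN_CODING,
    Annotation,
    GeneRecord,
)


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    chrom: str = "chr1",
    biotype: str = PROTEIN_CODING,
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=start, tx_end=end, biotype=biotype,
    )


def random_annotation(
    rng: np.random.Generator,
    n_genes: int = 50,
    noncoding_prob: float = 0.2,
    overlap_prob: float = 0.15,
    n_chrom: int = 2,
) -> Annotation:
    """Random annotation with occasional overlaps and non-coding genes."""
    records = []
    for c in range(n_chrom):
        pos = 0
        n = int(rng.integers(0, n_genes + 1))
        for i in range(n):
            length = int(rng.integers(100, 2000))
            if rng.random() < overlap_prob and pos > 400:
                gap = int(rng.integers(-400, 0))  # force an overlap
            else:
                gap = int(rng.integers(0, 1500))
            start = max(0, pos + gap)
            records.append(
                GeneRecord(
                    gene_id=f"R{c}_{i}",
                    chrom=f"chr{c + 1}",
                    strand="+" if rng.random() < 0.5 else "-",
                    tx_start=start,
                    tx_end=start + length,
                    biotype=PROTEIN_CODING if rng.random() > noncoding_prob else OTHER,
                )
            )
            pos = start + length
    return Annotation.from_records(records)


def brute_force_pair_index(ann: Annotation) -> dict[tuple[str, str], int]:
    """Exhaustive intervening-transcript counts for every same-chromosome
    protein-coding pair, by direct triple enumeration of the definition."""
    out: dict[tuple[str, str], int] = {}
    for chrom in ann.chromosomes:
        genes = ann.genes_by_chrom[chrom]
        n = len(genes)
        for i in range(n):
            for j in range(i + 1, n):
                left, right = genes[i], genes[j]
                if left.biotype != PROTEIN_CODING or right.biotype != PROTEIN_CODING:
                    continue
                n_between = sum(
                    1
                    for k in range(n)
                    if k != i
                    and k != j
                    and genes[k].tx_start >= left.tx_end
                    and genes[k].tx_end <= right.tx_start
                )
                out[(left.gene_id, right.gene_id)] = n_between
    return out


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r straight from the covariance/variance definition."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / (vx * vy) ** 0.5


def exhaustive_rank_sum_p(a, b, alternative: str = "two_sided") -> float:
    """Exact rank-sum p-value by enumerating all assignments of the pooled
    values to the two groups (valid without ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in group_a for y in group_b)

    observed = u_stat(a, b)
    us = []
    idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n_a):
        sel = set(comb)
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx - sel]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    eps = 1e-9
    p_greater = float(np.mean(us >= observed - eps))
    p_less = float(np.mean(us <= observed + eps))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset reused across tests (default mechanisms)."""
    import coexpair as cx

    cfg = cx.SimConfig(
        n_chrom=2, genes_per_chrom=100, n_experiments=300, seed=7
    )
    ann, mat, truth = cx.simulate(cfg)
    return cfg, ann, mat, truth
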