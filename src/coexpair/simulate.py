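"""Synthetic genome + expression generator with known ground truth.

Expression of gene *i* across experiments is a unit-variance Gaussian
factor model

    x_i = sqrt(a_i) * F_dom(i) + sqrt(b_i) * F_prom(i) + sqrt(1 - a_i - b_i) * eps_i

with independent standard-normal factors per experiment:

* ``F_dom`` — one chromatin-domain factor shared by all genes of a domain
  (non-overlapping blocks of ``domain_span`` consecutive genes per
  chromosome).  Baseline loading ``a``.
* ``F_prom`` — one shared-promoter factor per close (< ``close_threshold``
  bp) bi-directional direct neighbour pair; loading ``b`` for its two
  members, 0 elsewhere.
* transcriptional interference replaces a fraction ``delta`` of the
  chromatin variance share with independent noise (``a_i = a*(1-delta)``)
  for genes flanking a short intergenic region with their 3' end: both
  members of a close convergent pair, and the downstream member of a close
  uni-directional pair.

The expected Pearson correlation of any two genes is then the closed form

    E[r_ij] = sqrt(a_i a_j) * [same domain] + sqrt(b_i b_j) * [shared promoter]

which serves as the test oracle and as the ground truth the analysis
pipeline must recover.  With the default loadings (a=0.04, b=0.11,
delta=0.4) close divergent pairs sit at 0.15, distant divergent/convergent
pairs at 0.04, and close convergent pairs at 0.024 — the regime the
decomposition targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    BIDIRECTIONAL,
    CONVERGENT,
    PROTEIN_CODING,
    UNIDIRECTIONAL,
    Annotation,
    GeneRecord,
    NeighborPair,
    direct_neighbor_pairs,
    write_gff3,
)
from .expression import ExpressionMatrix, write_matrix

MIN_GENE_LENGTH = 200


@dataclass
class SimConfig:
    """Generator parameters.

    Genome defaults emulate a compact plant genome scaled down for speed:
    five chromosomes of 1,000 genes, ~2 kb genes, log-normal intergenic
    gaps with a ~400 bp median so that short (< 400 bp) and long pairs are
    roughly balanced.  The variance-share defaults are the regime the
    decomposition operates in: chromatin share a=0.04, promoter share
    b=0.11 (close divergent pairs at a+b=0.15), interference delta=0.4.
    """

    n_chrom: int = 5
    genes_per_chrom: int = 1000
    gene_length_mean: float = 2000.0
    gene_length_sd: float = 500.0
    gap_meanlog: float = 6.0   # log-bp; median gap exp(6.0) ~ 403 bp
    gap_sdlog: float = 0.9
    strand_model: str = "random"  # or "fixed_pattern"
    strand_pattern: str = "+-"    # cycled when strand_model == "fixed_pattern"
    n_experiments: int = 1436
    a: float = 0.04
    b: float = 0.11
    delta: float = 0.4
    domain_span: int = 2
    close_threshold: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b >= 1:
            raise ValueError("require a >= 0, b >= 0 and a + b < 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if self.gene_length_mean <= 0:
            raise ValueError("gene_length_mean must be positive")
        if self.domain_span < 1:
            raise ValueError("domain_span must be >= 1")
        if self.strand_model not in ("random", "fixed_pattern"):
            raise ValueError(f"unknown strand_model {self.strand_model!r}")
        if self.strand_model == "fixed_pattern" and not set(self.strand_pattern) <= {"+", "-"}:
            raise ValueError("strand_pattern must consist of + and -")


@dataclass
class Geometry:
    """Domain assignment of the simulated genes (chromosome block tiling)."""

    domain_of: dict[str, str]
    gene_order: list[str]

    def same_domain(self, gene_a: str, gene_b: str) -> bool:
        return self.domain_of[gene_a] == self.domain_of[gene_b]


@dataclass
class GroundTruth:
    """Per-gene factor assignments and per-pair expected correlations."""

    cfg: SimConfig
    genes: pd.DataFrame = field(repr=False)  # gene_id, domain, promoter_group, a_eff, b_eff, interfered
    pairs: pd.DataFrame = field(repr=False)  # direct pairs with expected_r

    def _gene(self, gene_id: str) -> pd.Series:
        try:
            return self.genes.loc[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in ground truth") from None

    def expected_pair_correlation(self, gene_a: str, gene_b: str) -> float:
        """Closed-form expected Pearson r for any simulated gene pair."""
        ga, gb = self._gene(gene_a), self._gene(gene_b)
        r = 0.0
        if ga["domain"] == gb["domain"]:
            r += math.sqrt(ga["a_eff"] * gb["a_eff"])
        if ga["promoter_group"] >= 0 and ga["promoter_group"] == gb["promoter_group"]:
            r += math.sqrt(ga["b_eff"] * gb["b_eff"])
        return r


def expected_pair_correlation(
    truth: GroundTruth, pair: NeighborPair | tuple[str, str]
) -> float:
    """Module-level convenience wrapper around the ground-truth oracle."""
    if isinstance(pair, NeighborPair):
        a, b = pair.gene_ids
    else:
        a, b = pair
    return truth.expected_pair_correlation(a, b)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig) -> tuple[Annotation, Geometry]:
    """Place genes left to right with log-normal gaps; assign strands and
    chromatin domains.  Deterministic under ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 0])
    records: list[GeneRecord] = []
    domain_of: dict[str, str] = {}
    order: list[str] = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        n = cfg.genes_per_chrom
        lengths = np.maximum(
            rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, size=n),
            MIN_GENE_LENGTH,
        ).astype(int)
        gaps = rng.lognormal(cfg.gap_meanlog, cfg.gap_sdlog, size=n).astype(int)
        if cfg.strand_model == "random":
            strands = rng.choice(["+", "-"], size=n)
        else:
            pat = cfg.strand_pattern
            strands = [pat[i % len(pat)] for i in range(n)]
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            gene_id = f"SIM{c + 1:02d}G{i + 1:05d}"
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=str(strands[i]),
                    tx_start=pos,
                    tx_end=pos + int(lengths[i]),
                    biotype=PROTEIN_CODING,
                )
            )
            domain_of[gene_id] = f"{chrom}:D{i // cfg.domain_span}"
            order.append(gene_id)
            pos += int(lengths[i])
    return Annotation.from_records(records), Geometry(domain_of, order)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _assign_mechanisms(
    cfg: SimConfig, ann: Annotation, geometry: Geometry
) -> tuple[pd.DataFrame, list[NeighborPair]]:
    """Per-gene effective loadings and promoter groups from pair geometry."""
    pairs = direct_neighbor_pairs(ann)
    promoter_group = {g: -1 for g in geometry.gene_order}
    interfered = {g: False for g in geometry.gene_order}
    for k, p in enumerate(pairs):
        close = 0 <= p.intergenic_bp < cfg.close_threshold
        if not close:
            continue
        if p.orientation == BIDIRECTIONAL:
            promoter_group[p.left.gene_id] = k
            promoter_group[p.right.gene_id] = k
        elif p.orientation == CONVERGENT:
            # both 3' ends face the short intergenic region: termination
            # read-through interferes with both members
            interfered[p.left.gene_id] = True
            interfered[p.right.gene_id] = True
        elif p.orientation == UNIDIRECTIONAL:
            # read-through hits the member downstream of the other's 3' end
            downstream = p.right if p.left.strand == "+" else p.left
            interfered[downstream.gene_id] = True
    rows = []
    for g in geometry.gene_order:
        a_eff = cfg.a * (1.0 - cfg.delta) if interfered[g] else cfg.a
        b_eff = cfg.b if promoter_group[g] >= 0 else 0.0
        rows.append(
            {
                "gene_id": g,
                "domain": geometry.domain_of[g],
                "promoter_group": promoter_group[g],
                "a_eff": a_eff,
                "b_eff": b_eff,
                "interfered": interfered[g],
            }
        )
    genes = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return genes, pairs


def simulate_expression(
    cfg: SimConfig, ann: Annotation, geometry: Geometry
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the factor-model expression matrix and its ground truth.

    Factors, promoter factors and noise come from independent child
    streams of ``cfg.seed``, so the matrix is reproducible byte for byte.
    """
    genes, pairs = _assign_mechanisms(cfg, ann, geometry)
    n_exp = cfg.n_experiments
    rng = np.random.default_rng([cfg.seed, 1])

    domains = list(dict.fromkeys(genes["domain"]))
    dom_index = {d: i for i, d in enumerate(domains)}
    f_dom = rng.standard_normal((len(domains), n_exp))

    groups = sorted(g for g in set(genes["promoter_group"]) if g >= 0)
    grp_index = {g: i for i, g in enumerate(groups)}
    f_prom = rng.standard_normal((len(groups), n_exp)) if groups else np.empty((0, n_exp))

    eps = rng.standard_normal((len(genes), n_exp))

    a_eff = genes["a_eff"].to_numpy()
    b_eff = genes["b_eff"].to_numpy()
    dom_rows = f_dom[[dom_index[d] for d in genes["domain"]]]
    prom_rows = np.zeros((len(genes), n_exp))
    has_prom = genes["promoter_group"].to_numpy() >= 0
    if groups:
        prom_rows[has_prom] = f_prom[
            [grp_index[g] for g in genes.loc[has_prom, "promoter_group"]]
        ]
    values = (
        np.sqrt(a_eff)[:, None] * dom_rows
        + np.sqrt(b_eff)[:, None] * prom_rows
        + np.sqrt(1.0 - a_eff - b_eff)[:, None] * eps
    )
    frame = pd.DataFrame(
        values,
        index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=[f"E{j + 1:04d}" for j in range(n_exp)],
    )
    mat = ExpressionMatrix(frame)

    truth_rows = []
    truth = GroundTruth(cfg=cfg, genes=genes, pairs=pd.DataFrame())
    for p in pairs:
        truth_rows.append(
            {
                "pair_id": p.pair_id,
                "left_id": p.left.gene_id,
                "right_id": p.right.gene_id,
                "orientation": p.orientation,
                "intergenic_bp": p.intergenic_bp,
                "close": bool(0 <= p.intergenic_bp < cfg.close_threshold),
                "domain_shared": geometry.same_domain(*p.gene_ids),
                "promoter_shared": (
                    genes.loc[p.left.gene_id, "promoter_group"] >= 0
                    and genes.loc[p.left.gene_id, "promoter_group"]
                    == genes.loc[p.right.gene_id, "promoter_group"]
                ),
                "expected_r": truth.expected_pair_correlation(*p.gene_ids),
            }
        )
    truth.pairs = pd.DataFrame(truth_rows)
    return mat, truth


def simulate(cfg: SimConfig) -> tuple[Annotation, ExpressionMatrix, GroundTruth]:
    """Genome and expression in one call."""
    ann, geometry = simulate_genome(cfg)
    mat, truth = simulate_expression(cfg, ann, geometry)
    return ann, mat, truth


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def write_fixture(
    ann: Annotation,
    mat: ExpressionMatrix,
    outdir: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write GFF3 + matrix TSV (+ ground-truth JSON) fixture files.

    The files round-trip losslessly through
    :func:`~coexpair.genome.read_gff3` / :func:`~coexpair.expression.read_matrix`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "genes.gff3",
        "matrix": outdir / "expression.tsv",
    }
    write_gff3(ann, paths["annotation"])
    write_matrix(mat, paths["matrix"])
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        payload = {
            "config": asdict(truth.cfg),
            "genes": truth.genes.drop(columns=["gene_id"]).reset_index().to_dict(
                orient="records"
            ),
            "pairs": truth.pairs.to_dict(orient="records"),
        }
        with paths["ground_truth"].open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
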