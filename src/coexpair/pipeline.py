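"""End-to-end analysis pipeline: annotation + matrix in, one JSON report out.

The report collects every headline statistic of the analysis — orientation
counts, distance profiles, orientation x distance group means with
rank-sum p-values against the random background, anti-correlated
fractions, the opposite-strand overlap groups, and the
chromatin/promoter/interference decomposition — plus per-stage filter
bookkeeping, and echoes every threshold for provenance.  Identical config
and inputs produce a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, decomposition, expression, genome

logger = logging.getLogger(__name__)

OVERLAP_GROUPS = (
    genome.OVERLAP_3P,
    genome.OVERLAP_5P,
    genome.OVERLAP_CONTAINED,
)


@dataclass
class RunConfig:
    """Paths, thresholds and flags of one analysis run."""

    annotation: str
    matrix: str
    outdir: str
    similarity_table: str | None = None
    exclusion_list: str | None = None
    split_bp: int = 400
    bin_width: int = 100
    max_bp: int = 2000
    max_intervening: int = 10
    min_obs: int = expression.DEFAULT_MIN_OBS
    evalue_threshold: float = 0.2
    n_random: int = 100_000
    tandem_filter: bool = False
    exclusion_filter: bool = False
    rounding: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_bp", "bin_width", "max_bp", "n_random"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if self.rounding not in decomposition.ROUNDING_MODES:
            raise ValueError(f"rounding must be one of {decomposition.ROUNDING_MODES}")
        if self.tandem_filter and not self.similarity_table:
            raise ValueError("tandem_filter requires a similarity_table path")
        if self.exclusion_filter and not self.exclusion_list:
            raise ValueError("exclusion_filter requires an exclusion_list path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_similarity_table(path: str | Path) -> list[tuple[str, str, float]]:
    """3-column TSV (id_a, id_b, evalue), with or without a header line."""
    rows: list[tuple[str, str, float]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                evalue = float(fields[2])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise
            rows.append((fields[0], fields[1], evalue))
    return rows


def read_gene_list(path: str | Path) -> list[str]:
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def build_pair_set(cfg: RunConfig, ann: genome.Annotation):
    """Direct neighbour pairs split into the non-overlapping analysis set
    and the opposite-strand overlap set, with stage bookkeeping."""
    stages: dict[str, int] = {}
    direct = genome.direct_neighbor_pairs(ann)
    stages["direct_pairs"] = len(direct)
    overlap_set = [p for p in direct if p.overlap_class in OVERLAP_GROUPS]
    stages["overlapping_pairs"] = len(overlap_set)
    stages["unclassifiable_overlap_pairs"] = sum(
        1 for p in direct if p.overlap_class == genome.OVERLAP_UNCLASSIFIABLE
    )
    pairs = genome.filter_overlapping_genes(direct, ann)
    stages["non_overlapping_pairs"] = len(pairs)
    if cfg.tandem_filter:
        sim = read_similarity_table(cfg.similarity_table)
        pairs = genome.filter_tandem_duplicates(pairs, sim, cfg.evalue_threshold)
        stages["after_tandem_filter"] = len(pairs)
    if cfg.exclusion_filter:
        pairs = genome.exclude_gene_list(pairs, read_gene_list(cfg.exclusion_list))
        stages["after_exclusion_list"] = len(pairs)
    return pairs, overlap_set, stages


def _profile_records(profile: pd.DataFrame) -> list[dict]:
    # to_dict keeps full float precision (to_json truncates to 10 digits)
    return profile.to_dict(orient="records")


def analyze(cfg: RunConfig) -> dict:
    """Run the full pipeline and write report.json plus human-readable TSVs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ann = genome.read_gff3(cfg.annotation)
    mat = expression.read_matrix(cfg.matrix)
    logger.info("loaded %d genes, matrix %s", len(ann), mat.shape)

    pairs, overlap_set, stages = build_pair_set(cfg, ann)

    values, coexp_report = expression.coexpress_pairs(mat, pairs, cfg.min_obs)
    joined = analysis.join_pairs(pairs, values)
    # %.17g keeps the TSV exactly consistent with the in-memory values
    joined.to_csv(
        outdir / "pairs_coexpression.tsv", sep="\t", index=False,
        float_format="%.17g",
    )

    background = analysis.random_background(
        mat, ann, n_pairs=cfg.n_random, seed=cfg.seed
    )

    # distance profile over intervening genes uses the all-pairs set,
    # overlap-filtered like the direct pairs
    all_pairs = genome.all_chromosome_pairs(ann, cfg.max_intervening)
    all_pairs = genome.filter_overlapping_genes(all_pairs, ann)
    stages["all_pairs_within_max_intervening"] = len(all_pairs)
    if cfg.tandem_filter:
        sim = read_similarity_table(cfg.similarity_table)
        all_pairs = genome.filter_tandem_duplicates(
            all_pairs, sim, cfg.evalue_threshold
        )
    all_values, _ = expression.coexpress_pairs(mat, all_pairs, cfg.min_obs)
    all_joined = analysis.join_pairs(all_pairs, all_values)
    prof_intervening = analysis.profile_by_intervening(all_joined, cfg.max_intervening)
    prof_intervening.to_csv(outdir / "profile_intervening.tsv", sep="\t", index=False)

    prof_bp = analysis.profile_by_bp(joined, cfg.bin_width, cfg.max_bp)
    for orientation, prof in prof_bp.items():
        prof.to_csv(outdir / f"profile_bp_{orientation}.tsv", sep="\t", index=False)

    groups = analysis.group_means(joined, cfg.split_bp, background)
    groups.to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
    overall = analysis.group_means(joined, float("inf"), background)

    decomp = decomposition.decompose(groups, background, rounding=cfg.rounding)

    # opposite-strand overlap groups (sense-antisense pairs)
    overlap_values, _ = expression.coexpress_pairs(mat, overlap_set, cfg.min_obs)
    overlap_joined = analysis.join_pairs(overlap_set, overlap_values)
    overlap_report = {}
    for group in OVERLAP_GROUPS:
        sel = overlap_joined[overlap_joined["overlap_class"] == group]
        gene_ids = sorted(set(sel["left_id"]) | set(sel["right_id"]))
        abundance = expression.mean_abundance(mat, gene_ids)
        entry = {
            "n": int(len(sel)),
            "mean_r": float(sel["r"].mean()) if len(sel) else None,
            "mean_abundance": float(abundance.mean()) if len(abundance) else None,
            "p_vs_random": (
                analysis.rank_sum_test(sel["r"].to_numpy(), background.values)
                if len(sel)
                else None
            ),
        }
        overlap_report[group] = entry

    # transitive expectation: observed r at one intervening gene vs the
    # product of the direct-neighbour correlation with itself
    transitive = {}
    d0 = prof_intervening[prof_intervening["bin_lo"] == 0]
    d1 = prof_intervening[prof_intervening["bin_lo"] == 1]
    if len(d0) and len(d1):
        r0 = float(d0.iloc[0]["mean_r"])
        transitive = {
            "mean_r_d0": r0,
            "expected_r_d1": analysis.transitive_expected_r(r0, r0),
            "observed_r_d1": float(d1.iloc[0]["mean_r"]),
        }

    neighbor_r = joined["r"].to_numpy()
    report = {
        "config": asdict(cfg),
        "stages": stages,
        "coexpression": coexp_report,
        "orientation_counts": genome.orientation_counts(pairs),
        "overall_group_stats": overall.drop(columns=["distance_class"]).to_dict(
            orient="records"
        ),
        "group_stats": groups.to_dict(orient="records"),
        "profile_intervening": _profile_records(prof_intervening),
        "profile_bp": {o: _profile_records(p) for o, p in prof_bp.items()},
        "random_background": {
            "n_pairs": background.n_pairs,
            "seed": background.seed,
            "mean_r": background.mean_r,
            "sem_r": background.sem_r,
            "n_undefined": background.n_undefined,
        },
        "anticorrelated_fraction": {
            "neighbors": (
                analysis.anticorrelated_fraction(neighbor_r) if len(neighbor_r) else None
            ),
            "random": analysis.anticorrelated_fraction(background.values),
        },
        "overlap_groups": overlap_report,
        "transitive_expectation": transitive,
        "decomposition": decomp.to_dict(),
    }
    write_report(report, outdir / "report.json")
    return report


def write_report(report: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_pair_table(pairs, path: str | Path) -> None:
    """Pair table TSV: pair_id, chrom, members, orientation, overlap, distances."""
    rows = [
        {
            "pair_id": p.pair_id,
            "chrom": p.chrom,
            "left_id": p.left.gene_id,
            "right_id": p.right.gene_id,
            "orientation": p.orientation,
            "overlap_class": p.overlap_class,
            "intergenic_bp": p.intergenic_bp,
            "n_intervening": p.n_intervening,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pair_id", "chrom", "left_id", "right_id", "orientation",
            "overlap_class", "intergenic_bp", "n_intervening",
        ],
    ).to_csv(path, sep="\t", index=False)
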