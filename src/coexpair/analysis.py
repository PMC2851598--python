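"""Aggregate statistics over pairwise co-expression values.

Distance profiles (intervening-gene and base-pair binned), orientation x
distance group means, the random-pair background, Wilcoxon rank-sum
comparisons, the anti-correlated fraction, and the transitive expectation
for indirect correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ORIENTATIONS, PROTEIN_CODING, Annotation, NeighborPair
from .expression import CoexpressionValue, ExpressionMatrix, correlate_index_pairs

logger = logging.getLogger(__name__)

SHORT, LONG = "short", "long"

PROFILE_COLUMNS = ["bin_lo", "bin_hi", "mean_r", "sem_r", "n"]


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean: sample sd / sqrt(n); NaN for n < 2."""
    n = len(values)
    if n < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(n))


def join_pairs(
    pairs: list[NeighborPair], values: list[CoexpressionValue]
) -> pd.DataFrame:
    """One row per pair with a defined co-expression value.

    Columns: pair_id, chrom, left_id, right_id, orientation, overlap_class,
    intergenic_bp, n_intervening, r, n_obs.
    """
    by_id = {p.pair_id: p for p in pairs}
    rows = []
    for v in values:
        if not v.ok:
            continue
        p = by_id[v.pair_id]
        rows.append(
            {
                "pair_id": p.pair_id,
                "chrom": p.chrom,
                "left_id": p.left.gene_id,
                "right_id": p.right.gene_id,
                "orientation": p.orientation,
                "overlap_class": p.overlap_class,
                "intergenic_bp": p.intergenic_bp,
                "n_intervening": p.n_intervening,
                "r": v.r,
                "n_obs": v.n_obs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "chrom", "left_id", "right_id", "orientation",
            "overlap_class", "intergenic_bp", "n_intervening", "r", "n_obs",
        ],
    )


# ---------------------------------------------------------------------------
# Distance profiles
# ---------------------------------------------------------------------------

def profile_by_intervening(joined: pd.DataFrame, max_d: int) -> pd.DataFrame:
    """Mean/SEM/count of r per number of intervening genes d in [0, max_d].

    Empty distance bins are omitted (and logged).
    """
    rows = []
    for d in range(max_d + 1):
        sel = joined.loc[joined["n_intervening"] == d, "r"].to_numpy()
        if len(sel) == 0:
            logger.info("intervening-gene bin d=%d empty, omitted", d)
            continue
        rows.append(
            {"bin_lo": d, "bin_hi": d, "mean_r": sel.mean(), "sem_r": _sem(sel),
             "n": len(sel)}
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def profile_by_bp(
    joined: pd.DataFrame,
    bin_width: int = 100,
    max_bp: int = 2000,
) -> dict[str, pd.DataFrame]:
    """Per-orientation profiles over half-open bins [k*w, (k+1)*w) of
    intergenic distance, for direct non-overlapping neighbours in [0, max_bp).
    """
    if (joined["intergenic_bp"] < 0).any():
        raise ValueError(
            "profile_by_bp expects non-overlapping pairs (intergenic_bp >= 0); "
            "route overlapping pairs to the overlap analysis"
        )
    out: dict[str, pd.DataFrame] = {}
    for orientation in ORIENTATIONS:
        sub = joined[joined["orientation"] == orientation]
        rows = []
        for lo in range(0, max_bp, bin_width):
            hi = lo + bin_width
            sel = sub.loc[
                (sub["intergenic_bp"] >= lo) & (sub["intergenic_bp"] < hi), "r"
            ].to_numpy()
            if len(sel) == 0:
                continue
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "mean_r": sel.mean(),
                 "sem_r": _sem(sel), "n": len(sel)}
            )
        out[orientation] = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return out


# ---------------------------------------------------------------------------
# Orientation x distance-class group means
# ---------------------------------------------------------------------------

def group_means(
    joined: pd.DataFrame,
    split_bp: float = 400,
    background: "RandomBackground | None" = None,
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Mean co-expression per orientation x {short, long} distance class.

    short: intergenic_bp < split_bp; long: intergenic_bp >= split_bp (the
    split value itself is assigned to the long class).  With
    ``split_bp=inf`` this degenerates to single per-orientation means.
    When a background is supplied, each group gets a Wilcoxon rank-sum
    p-value against the background values.
    """
    rows = []
    for orientation in ORIENTATIONS:
        sub = joined[joined["orientation"] == orientation]
        for klass in (SHORT, LONG):
            if klass == SHORT:
                sel = sub.loc[sub["intergenic_bp"] < split_bp, "r"].to_numpy()
            else:
                sel = sub.loc[sub["intergenic_bp"] >= split_bp, "r"].to_numpy()
            if np.isinf(split_bp) and klass == LONG:
                continue
            row = {
                "orientation": orientation,
                "distance_class": klass,
                "mean_r": sel.mean() if len(sel) else float("nan"),
                "sem_r": _sem(sel),
                "n": len(sel),
                "p_vs_random": float("nan"),
            }
            if background is not None and len(sel):
                row["p_vs_random"] = rank_sum_test(
                    sel, background.values, alternative=alternative
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random-pair background
# ---------------------------------------------------------------------------

@dataclass
class RandomBackground:
    """Co-expression of randomly drawn distinct protein-coding gene pairs."""

    n_pairs: int
    seed: int
    values: np.ndarray = field(repr=False)
    mean_r: float = float("nan")
    n_undefined: int = 0

    @property
    def sem_r(self) -> float:
        return _sem(self.values)


def random_background(
    mat: ExpressionMatrix,
    ann: Annotation,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> RandomBackground:
    """Draw ``n_pairs`` unordered distinct protein-coding gene pairs
    uniformly (with replacement across draws) and correlate them.

    Reproducible given ``seed``; undefined correlations are dropped and
    counted.
    """
    genes = [g for g in ann.gene_ids(biotype=PROTEIN_CODING) if g in mat]
    if len(genes) < 2:
        raise ValueError("need at least 2 measured protein-coding genes")
    rng = np.random.default_rng(seed)
    idx = np.array([mat.row_index(g) for g in genes])
    a = rng.integers(0, len(genes), size=n_pairs)
    b = rng.integers(0, len(genes), size=n_pairs)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, len(genes), size=int(clash.sum()))
        clash = a == b
    rs = correlate_index_pairs(mat, idx[a], idx[b])
    defined = rs[~np.isnan(rs)]
    n_undef = int(np.isnan(rs).sum())
    if n_undef:
        logger.info("random background: %d undefined pairs dropped", n_undef)
    return RandomBackground(
        n_pairs=n_pairs,
        seed=seed,
        values=defined,
        mean_r=float(defined.mean()),
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# Tests and summary statistics
# ---------------------------------------------------------------------------

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}

#: above this combined sample size the normal approximation (with tie
#: correction) is used instead of exact enumeration
EXACT_MAX_N = 50


def rank_sum_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alternative: str = "two_sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null enumeration for small untied samples, normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=_ALTERNATIVES[alternative], method=method)
    return float(res.pvalue)


def anticorrelated_fraction(values: np.ndarray) -> float:
    """Fraction of co-expression values below zero."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("anticorrelated_fraction of empty input")
    return float(np.mean(v < 0))


def transitive_expected_r(r_ab: float, r_bc: float) -> float:
    """Expected indirect correlation of A and C given A~B and B~C.

    Without a direct A-C interaction the shared variance multiplies:
    R_ac^2 = R_ab^2 * R_bc^2, so r_ac = r_ab * r_bc (sign = product of
    signs).
    """
    for r in (r_ab, r_bc):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation out of [-1, 1]: {r}")
    return r_ab * r_bc
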