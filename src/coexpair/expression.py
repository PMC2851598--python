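"""Expression matrix I/O and pairwise Pearson co-expression.

The matrix holds log2 signal intensities, genes in rows and hybridisation
experiments in columns.  Missing cells are allowed; correlations are then
computed over pairwise-complete experiments, subject to a minimum-observation
threshold.  Complete matrices take a vectorised fast path via row
standardisation, which is what makes large random-pair backgrounds cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 10


@dataclass(frozen=True)
class CoexpressionValue:
    """Pearson correlation of one gene pair across experiments.

    ``ok`` is False when the correlation is undefined (too few complete
    observations or a zero-variance vector); such pairs are dropped from
    downstream averages, never substituted by 0.
    """

    pair_id: str
    r: float
    n_obs: int
    ok: bool = True

    def __post_init__(self) -> None:
        if self.ok and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: {self.r}")


class ExpressionMatrix:
    """Genes x experiments log2 expression values with missing support."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in matrix: {dup!r}")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise ValueError(f"duplicate experiment id in matrix: {dup!r}")
        self._frame = frame.astype(float)
        self._index = {g: i for i, g in enumerate(frame.index)}
        self._values = self._frame.to_numpy()
        self._complete = not np.isnan(self._values).any()
        self._z: np.ndarray | None = None  # standardized rows, lazy

    # -- basic container protocol -----------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def vector(self, gene_id: str) -> np.ndarray:
        try:
            return self._values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    # -- standardized rows (complete-matrix fast path) ---------------------
    def _standardized(self) -> np.ndarray:
        """Rows centred and scaled so that z_a @ z_b is pearson r.

        Zero-variance rows become NaN rows, so their correlations are NaN
        and get flagged undefined downstream.
        """
        if self._z is None:
            x = self._values
            centred = x - x.mean(axis=1, keepdims=True)
            norm = np.sqrt((centred**2).sum(axis=1, keepdims=True))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(norm > 0, centred / norm, np.nan)
            self._z = z
        return self._z

    def row_index(self, gene_id: str) -> int:
        return self._index[gene_id]


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = experiment ids, first column
    = gene id).  Empty cells become missing values; ragged rows or duplicate
    gene ids are errors."""
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[""], float_precision="round_trip"
    )
    non_numeric = frame.select_dtypes(exclude=[np.number]).columns
    if len(non_numeric):
        try:
            frame = frame.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in matrix column {non_numeric[0]!r}") from exc
    return ExpressionMatrix(frame)


def write_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    # 17 significant digits: lossless float64 round-trip through text
    mat.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def pearson(
    mat: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    min_obs: int = DEFAULT_MIN_OBS,
) -> CoexpressionValue:
    """Pearson correlation of two genes over pairwise-complete experiments.

    Pairs with fewer than ``min_obs`` complete observations, or with a
    zero-variance vector on the complete subset, come back flagged
    ``ok=False`` rather than with an arbitrary value.
    """
    x = mat.vector(gene_a)
    y = mat.vector(gene_b)
    pair_id = f"{gene_a}|{gene_b}"
    mask = ~(np.isnan(x) | np.isnan(y))
    n_obs = int(mask.sum())
    if n_obs < max(min_obs, 2):
        return CoexpressionValue(pair_id, float("nan"), n_obs, ok=False)
    xs, ys = x[mask], y[mask]
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0.0:
        return CoexpressionValue(pair_id, float("nan"), n_obs, ok=False)
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    return CoexpressionValue(pair_id, r, n_obs)


def correlate_index_pairs(
    mat: ExpressionMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Vectorised correlations for row-index pairs of a complete matrix.

    NaN where undefined (zero variance).  Falls back to per-pair
    pairwise-complete computation when the matrix has missing values.
    """
    if mat._complete:
        z = mat._standardized()
        return np.einsum("ij,ij->i", z[idx_a], z[idx_b])
    genes = mat.gene_ids
    out = np.empty(len(idx_a))
    for k, (i, j) in enumerate(zip(idx_a, idx_b)):
        v = pearson(mat, genes[i], genes[j], min_obs=2)
        out[k] = v.r if v.ok else np.nan
    return out


def coexpress_pairs(
    mat: ExpressionMatrix,
    pairs: Sequence,
    min_obs: int = DEFAULT_MIN_OBS,
) -> tuple[list[CoexpressionValue], dict[str, int]]:
    """Per-pair co-expression for :class:`~coexpair.genome.NeighborPair` s.

    Returns the values for pairs with both genes measured, plus a report
    dict counting pairs dropped for unmeasured genes and pairs flagged
    undefined.
    """
    values: list[CoexpressionValue] = []
    n_unmeasured = 0
    n_undefined = 0
    measurable = []
    for p in pairs:
        a, b = p.gene_ids
        if a not in mat or b not in mat:
            n_unmeasured += 1
            continue
        measurable.append(p)
    if mat._complete and mat.shape[1] >= max(min_obs, 2) and measurable:
        idx_a = np.array([mat.row_index(p.gene_ids[0]) for p in measurable])
        idx_b = np.array([mat.row_index(p.gene_ids[1]) for p in measurable])
        rs = correlate_index_pairs(mat, idx_a, idx_b)
        n_exp = mat.shape[1]
        for p, r in zip(measurable, rs):
            if np.isnan(r):
                n_undefined += 1
                values.append(CoexpressionValue(p.pair_id, float("nan"), n_exp, ok=False))
            else:
                values.append(CoexpressionValue(p.pair_id, float(np.clip(r, -1, 1)), n_exp))
    else:
        for p in measurable:
            v = pearson(mat, *p.gene_ids, min_obs=min_obs)
            if not v.ok:
                n_undefined += 1
            values.append(v)
    report = {
        "n_pairs_in": len(pairs),
        "n_dropped_unmeasured": n_unmeasured,
        "n_undefined": n_undefined,
        "n_values": sum(1 for v in values if v.ok),
    }
    if n_unmeasured:
        logger.info("%d pairs dropped: gene not in matrix", n_unmeasured)
    return values, report


def mean_abundance(mat: ExpressionMatrix, gene_ids: Iterable[str]) -> pd.Series:
    """Per-gene mean log2 signal over non-missing experiments.

    Genes absent from the matrix are dropped with a warning.
    """
    ids = list(gene_ids)
    present = [g for g in ids if g in mat]
    missing = len(ids) - len(present)
    if missing:
        logger.warning("%d genes not in matrix dropped from abundance", missing)
    if not present:
        return pd.Series(dtype=float)
    rows = np.array([mat.vector(g) for g in present])
    with np.errstate(invalid="ignore"):
        means = np.nanmean(rows, axis=1)
    return pd.Series(means, index=present, name="mean_log2")
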