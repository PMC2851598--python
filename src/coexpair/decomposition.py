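"""Decomposition of neighbour co-expression into chromatin, shared-promoter,
and transcriptional-interference components.

The logic: beyond the promoter-sharing range (~400 bp) divergent and
convergent pairs show the same co-expression, which can only come from a
shared chromatin environment.  Averaging those two long-distance means and
subtracting the random-pair baseline gives the chromatin effect c.
Close divergent pairs add promoter sharing on top of c; close convergent
pairs fall below c through interference at the 3' ends.

    c   = (m_bd_long + m_cv_long) / 2 - r0
    pf  = (m_bd_short - c) / m_bd_short      share of close bi-directional
                                             co-expression from the promoter
    if  = (c - m_cv_short) / c               relative loss in close
                                             convergent pairs

Uni-directional pairs are excluded from c: read-through can couple them
even at long range, so they are not a clean chromatin probe.

The interference formula compares a baseline-subtracted quantity (c) with a
raw group mean (m_cv_short); it is implemented exactly in that form, and a
self-consistent variant using (m_cv_short - r0) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .analysis import LONG, SHORT, RandomBackground
from .genome import BIDIRECTIONAL, CONVERGENT

ROUNDING_MODES = ("full", "printed")


def chromatin_effect(
    mean_bi_long: float, mean_conv_long: float, random_mean: float
) -> float:
    """Excess correlation from shared chromatin: mean of the long-distance
    divergent and convergent group means minus the random-pair mean."""
    return (mean_bi_long + mean_conv_long) / 2.0 - random_mean


def promoter_fraction(mean_bi_short: float, chromatin: float) -> float:
    """Share of close bi-directional co-expression attributable to the
    shared promoter: (m_bd_short - c) / m_bd_short.  NaN if the close
    bi-directional mean is not positive."""
    if mean_bi_short <= 0:
        return float("nan")
    return (mean_bi_short - chromatin) / mean_bi_short


def interference_fraction(chromatin: float, mean_conv_short: float) -> float:
    """Relative reduction of chromatin-mediated co-expression in close
    convergent pairs: (c - m_cv_short) / c.  NaN if c is not positive."""
    if chromatin <= 0:
        return float("nan")
    return (chromatin - mean_conv_short) / chromatin


@dataclass
class DecompositionResult:
    chromatin_effect: float
    promoter_fraction: float
    interference_fraction: float
    variant_interference_fraction: float
    inputs_used: dict[str, float] = field(default_factory=dict)
    rounding: str = "full"
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict[str, Any]:
        return {
            "chromatin_effect": self.chromatin_effect,
            "promoter_fraction": self.promoter_fraction,
            "interference_fraction": self.interference_fraction,
            "variant_interference_fraction": self.variant_interference_fraction,
            "inputs_used": self.inputs_used,
            "rounding": self.rounding,
            "flags": self.flags,
        }


def decompose_from_means(
    mean_bi_long: float,
    mean_conv_long: float,
    random_mean: float,
    mean_bi_short: float,
    mean_conv_short: float,
    rounding: str = "full",
) -> DecompositionResult:
    """Chain the three decomposition formulas from the five feeding means.

    ``rounding="printed"`` first rounds the inputs to reporting precision
    (long means and the random mean to 3 decimals, the chromatin effect and
    the close bi-directional mean to 2, the close convergent mean to 3), so
    that desk arithmetic on published tables is reproduced digit for digit.
    """
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}")
    raw = {
        "mean_bi_long": mean_bi_long,
        "mean_conv_long": mean_conv_long,
        "random_mean": random_mean,
        "mean_bi_short": mean_bi_short,
        "mean_conv_short": mean_conv_short,
    }
    if rounding == "printed":
        mean_bi_long = round(mean_bi_long, 3)
        mean_conv_long = round(mean_conv_long, 3)
        random_mean = round(random_mean, 3)
        mean_bi_short = round(mean_bi_short, 2)
        mean_conv_short = round(mean_conv_short, 3)
    c = chromatin_effect(mean_bi_long, mean_conv_long, random_mean)
    if rounding == "printed":
        c = round(c, 2)
    pf = promoter_fraction(mean_bi_short, c)
    itf = interference_fraction(c, mean_conv_short)
    variant = interference_fraction(c, mean_conv_short - random_mean)
    flags = []
    if math.isnan(pf):
        flags.append("promoter_fraction undefined: mean_bi_short <= 0")
    if math.isnan(itf):
        flags.append("interference_fraction undefined: chromatin_effect <= 0")
    return DecompositionResult(
        chromatin_effect=c,
        promoter_fraction=pf,
        interference_fraction=itf,
        variant_interference_fraction=variant,
        inputs_used=raw,
        rounding=rounding,
        flags=flags,
    )


def decompose(
    group_stats: pd.DataFrame,
    background: RandomBackground,
    rounding: str = "full",
) -> DecompositionResult:
    """Run the decomposition from a :func:`~coexpair.analysis.group_means`
    table and a random background."""

    def _mean(orientation: str, klass: str) -> float:
        sel = group_stats[
            (group_stats["orientation"] == orientation)
            & (group_stats["distance_class"] == klass)
        ]
        if sel.empty or sel.iloc[0]["n"] == 0:
            return float("nan")
        return float(sel.iloc[0]["mean_r"])

    return decompose_from_means(
        mean_bi_long=_mean(BIDIRECTIONAL, LONG),
        mean_conv_long=_mean(CONVERGENT, LONG),
        random_mean=background.mean_r,
        mean_bi_short=_mean(BIDIRECTIONAL, SHORT),
        mean_conv_short=_mean(CONVERGENT, SHORT),
        rounding=rounding,
    )
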