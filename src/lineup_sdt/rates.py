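"""Identification-rate estimators and chi-square condition comparisons.

The correct ID rate is the proportion of target-present lineups on which
the perpetrator was chosen.  With no designated innocent suspect, the
false ID rate is *estimated* by dividing the target-absent filler-ID
proportion by the lineup size ``k`` — the rate at which any one innocent
face is picked.  Condition contrasts use Pearson's chi-square on a 2x2
count table without continuity correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .data import LineupOutcomeTable, ValidationError

__all__ = [
    "Outcome",
    "RateResult",
    "ChiSquareResult",
    "correct_id_rate",
    "estimated_false_id_rate",
    "chisq_2x2",
    "compare_conditions",
]


class Outcome(str, enum.Enum):
    CORRECT_IDS = "correct_ids"
    TA_FALSE_ALARMS = "ta_false_alarms"


class UndefinedRateError(ZeroDivisionError):
    """Raised when a rate's denominator is zero."""


class DesignatedSuspectError(ValueError):
    """Raised when the estimated false ID rate is requested for a design
    with a designated innocent suspect (use the direct suspect-ID rate)."""


@dataclass(frozen=True)
class RateResult:
    """A proportion with its provenance: ``rate = numerator / denominator
    / divisor_k`` (``divisor_k`` is the lineup size for estimated false ID
    rates, 1 otherwise)."""

    numerator: int
    denominator: int
    divisor_k: int

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator / self.divisor_k

    def __float__(self) -> float:
        return self.rate


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def correct_id_rate(table: LineupOutcomeTable) -> RateResult:
    """Correct IDs divided by the number of target-present lineups."""
    if table.n_tp == 0:
        raise UndefinedRateError("no target-present lineups")
    return RateResult(
        numerator=sum(table.tp_suspect), denominator=table.n_tp, divisor_k=1
    )


def estimated_false_id_rate(
    table: LineupOutcomeTable, designated_suspect: bool = False
) -> RateResult:
    """TA filler IDs divided by the number of TA lineups and by ``k``."""
    if designated_suspect:
        raise DesignatedSuspectError(
            "design has a designated innocent suspect; report the direct "
            "innocent-suspect ID rate instead of the estimated rate"
        )
    if table.n_ta == 0:
        raise UndefinedRateError("no target-absent lineups")
    return RateResult(
        numerator=sum(table.ta_filler), denominator=table.n_ta, divisor_k=table.k
    )


def chisq_2x2(a: int, b: int, c: int, d: int) -> ChiSquareResult:
    """Pearson chi-square (df=1, no continuity correction) on [[a,b],[c,d]]."""
    counts = np.array([[a, b], [c, d]])
    if (counts < 0).any():
        raise ValidationError("counts must be nonnegative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValidationError(f"zero marginal in 2x2 table {counts.tolist()}")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(stat), df=int(df), p=float(p), table=((a, b), (c, d))
    )


def compare_conditions(
    table_a: LineupOutcomeTable,
    table_b: LineupOutcomeTable,
    outcome: Outcome | str,
) -> ChiSquareResult:
    """Chi-square comparison of one outcome's frequency between two cells.

    ``correct_ids`` compares TP suspect IDs against the remaining TP
    lineups; ``ta_false_alarms`` compares TA filler IDs against the
    remaining TA lineups.
    """
    outcome = Outcome(outcome)
    if outcome is Outcome.CORRECT_IDS:
        na, nb = table_a.n_tp, table_b.n_tp
        xa, xb = sum(table_a.tp_suspect), sum(table_b.tp_suspect)
    else:
        na, nb = table_a.n_ta, table_b.n_ta
        xa, xb = sum(table_a.ta_filler), sum(table_b.ta_filler)
    return chisq_2x2(xa, na - xa, xb, nb - xb)
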