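"""Confidence-based ROC analysis for lineup data.

Sweeping a confidence criterion from strict to lenient traces out
cumulative (false ID rate, correct ID rate) pairs: the point for bin ``j``
counts every identification made at confidence ``j`` or higher.  The
curves never reach (1, 1) — witnesses who reject the lineup contribute to
neither coordinate — so conditions are compared by the partial area under
the curve (pAUC) up to a false-ID-rate cutoff shared by both conditions:
the rightmost point of whichever condition responded more conservatively.
Standard errors come from a case bootstrap over lineups, and two pAUCs are
compared with Z = (pAUC1 - pAUC2) / sd(pAUC1* - pAUC2*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import BinningScheme, LineupOutcomeTable, bin_by_confidence, RAW_LEVELS

__all__ = [
    "ROCCurve",
    "PartialAUC",
    "PAUCComparison",
    "roc_points",
    "conservative_cutoff",
    "pauc",
    "bootstrap_pauc",
    "pauc_z_test",
]


@dataclass(frozen=True)
class ROCCurve:
    """Cumulative ROC points ordered from the (0, 0) anchor (strictest
    criterion) to the most lenient point, which equals the overall
    (estimated false ID rate, correct ID rate).  ``point_weights`` are the
    relative frequencies of the identifications contributing to each point
    (0 for the anchor)."""

    points: np.ndarray  # (P, 2) float
    point_weights: np.ndarray  # (P,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(
            self, "point_weights", np.asarray(self.point_weights, dtype=float)
        )
        if np.any(pts < -1e-12) or np.any(pts > 1 + 1e-12):
            raise ValueError("ROC coordinates must lie in [0, 1]")
        if np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12):
            raise ValueError("ROC coordinates must be nondecreasing")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def rightmost(self) -> tuple[float, float]:
        return float(self.points[-1, 0]), float(self.points[-1, 1])

    @property
    def degenerate(self) -> bool:
        """True when no identifications were made at all."""
        return bool(np.all(self.points == 0.0))


@dataclass(frozen=True)
class PartialAUC:
    """Trapezoidal area under an ROC up to a false-ID-rate cutoff.

    ``extrapolated`` is set when the cutoff lies beyond the curve's
    rightmost point and the final segment had to be extended linearly.
    """

    area: float
    cutoff: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.area


@dataclass(frozen=True)
class PAUCComparison:
    pauc_1: float
    pauc_2: float
    cutoff: float
    se_diff: float
    z: float
    p: float
    n_boot: int
    seed: int
    curve_1: ROCCurve = field(repr=False, default=None)
    curve_2: ROCCurve = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _cumulative_xy(
    tp_suspect: np.ndarray,
    ta_filler: np.ndarray,
    n_tp: int,
    n_ta: int,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulate counts from the highest confidence bin downwards and
    prepend the (0, 0) anchor.  Accepts stacked rows (..., m)."""
    cum_y = np.cumsum(tp_suspect[..., ::-1], axis=-1) / n_tp
    cum_x = np.cumsum(ta_filler[..., ::-1], axis=-1) / (n_ta * k)
    zeros = np.zeros(cum_x.shape[:-1] + (1,))
    return (
        np.concatenate([zeros, cum_x], axis=-1),
        np.concatenate([zeros, cum_y], axis=-1),
    )


def roc_points(binned: LineupOutcomeTable) -> ROCCurve:
    """ROC curve from a confidence-binned outcome table.

    Point ``j`` cumulates TP suspect IDs and TA filler IDs over bins
    ``>= j``; the false-ID coordinate divides by ``n_ta * k`` (estimated
    false ID rate), the correct-ID coordinate by ``n_tp``.
    """
    tp = np.asarray(binned.tp_suspect, dtype=float)
    ta = np.asarray(binned.ta_filler, dtype=float)
    x, y = _cumulative_xy(tp, ta, binned.n_tp, binned.n_ta, binned.k)
    total_ids = tp.sum() + ta.sum()
    if total_ids == 0:
        warnings.warn("no identifications at all: degenerate single-point ROC")
        weights = np.zeros_like(x)
    else:
        weights = np.concatenate([[0.0], (tp + ta)[::-1] / total_ids])
    return ROCCurve(points=np.column_stack([x, y]), point_weights=weights)


def conservative_cutoff(curve_a: ROCCurve, curve_b: ROCCurve) -> float:
    """False-ID-rate cutoff for pAUC comparison: the rightmost point of
    the more conservatively responding condition (the smaller maximum)."""
    cut = min(curve_a.rightmost[0], curve_b.rightmost[0])
    if cut == 0.0:
        warnings.warn("degenerate curve: conservative cutoff is 0")
    return cut


def _pauc_rows(xs: np.ndarray, ys: np.ndarray, cutoff: float) -> np.ndarray:
    """Vectorised trapezoidal pAUC for stacked curves.

    ``xs``/``ys`` have shape (R, P), each row a curve starting at the
    origin anchor with nondecreasing coordinates.  Integrates each row
    from x = 0 to ``cutoff``, interpolating linearly inside a segment and
    extrapolating along the last segment of positive width when the
    cutoff exceeds the rightmost point.
    """
    xs = np.atleast_2d(xs)
    ys = np.atleast_2d(ys)
    R, P = xs.shape
    area = np.zeros(R)
    last_slope = np.zeros(R)
    for j in range(P - 1):
        x0, x1 = xs[:, j], xs[:, j + 1]
        y0, y1 = ys[:, j], ys[:, j + 1]
        dx = x1 - x0
        pos = dx > 0
        slope = np.where(pos, (y1 - y0) / np.where(pos, dx, 1.0), 0.0)
        last_slope = np.where(pos, slope, last_slope)
        lo = np.minimum(x0, cutoff)
        hi = np.minimum(x1, cutoff)
        w = hi - lo
        y_lo = y0 + slope * (lo - x0)
        y_hi = y0 + slope * (hi - x0)
        area += w * (y_lo + y_hi) / 2.0
    over = cutoff - xs[:, -1]
    ext = over > 0
    if np.any(ext):
        y_end = ys[:, -1]
        area = np.where(
            ext, area + over * (y_end + (y_end + last_slope * over)) / 2.0, area
        )
    return area


def pauc(curve: ROCCurve, cutoff: float) -> PartialAUC:
    """Partial area under ``curve`` from false ID rate 0 to ``cutoff``."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    area = float(_pauc_rows(curve.x, curve.y, cutoff)[0])
    extrapolated = cutoff > curve.rightmost[0] + 1e-12
    if extrapolated:
        warnings.warn(
            f"cutoff {cutoff:g} exceeds the rightmost observed false ID rate "
            f"{curve.rightmost[0]:g}; pAUC extrapolates the final segment"
        )
    return PartialAUC(area=area, cutoff=float(cutoff), extrapolated=extrapolated)


def _ensure_binned(
    table: LineupOutcomeTable, scheme: BinningScheme
) -> LineupOutcomeTable:
    return bin_by_confidence(table, scheme) if table.levels == RAW_LEVELS else table


def _resample_curves(
    binned: LineupOutcomeTable, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Case bootstrap: lineups are resampled with replacement within each
    lineup type, i.e. multinomial draws over the outcome categories."""
    m = binned.n_levels
    tp_counts = np.concatenate(
        [binned.tp_suspect, binned.tp_filler, binned.tp_no_id]
    ).astype(float)
    ta_counts = np.concatenate([binned.ta_filler, binned.ta_no_id]).astype(float)
    tp_draw = rng.multinomial(binned.n_tp, tp_counts / binned.n_tp, size=n_boot)
    ta_draw = rng.multinomial(binned.n_ta, ta_counts / binned.n_ta, size=n_boot)
    return _cumulative_xy(
        tp_draw[:, :m].astype(float),
        ta_draw[:, :m].astype(float),
        binned.n_tp,
        binned.n_ta,
        binned.k,
    )


def bootstrap_pauc(
    table: LineupOutcomeTable,
    scheme: BinningScheme,
    cutoff: float,
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Bootstrap distribution of the pAUC for one condition.

    Target-present and target-absent lineups are resampled independently
    with replacement; the ROC and pAUC are recomputed per replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    binned = _ensure_binned(table, scheme)
    rng = np.random.default_rng(seed)
    xs, ys = _resample_curves(binned, n_boot, rng)
    out = _pauc_rows(xs, ys, cutoff)
    if np.ptp(out) == 0.0 and n_boot > 1:
        warnings.warn("bootstrap pAUC distribution is degenerate (SE = 0)")
    return out


def pauc_z_test(
    table_a: LineupOutcomeTable,
    table_b: LineupOutcomeTable,
    scheme: BinningScheme | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> PAUCComparison:
    """Two-sided bootstrap Z-test for a pAUC difference.

    The cutoff is set by :func:`conservative_cutoff`.  Replicates are
    paired across conditions (same replicate index, independent
    resampling per condition); Z divides the observed pAUC difference by
    the bootstrap standard deviation of the replicate differences, and p
    is two-sided from the standard normal.
    """
    scheme = scheme or BinningScheme()
    binned_a = _ensure_binned(table_a, scheme)
    binned_b = _ensure_binned(table_b, scheme)
    curve_a = roc_points(binned_a)
    curve_b = roc_points(binned_b)
    cutoff = conservative_cutoff(curve_a, curve_b)
    pauc_a = pauc(curve_a, cutoff)
    pauc_b = pauc(curve_b, cutoff)

    seq_a, seq_b = np.random.SeedSequence(seed).spawn(2)
    boot_a = bootstrap_pauc(table_a, scheme, cutoff, n_boot=n_boot, seed=seq_a)
    boot_b = bootstrap_pauc(table_b, scheme, cutoff, n_boot=n_boot, seed=seq_b)
    diffs = boot_a - boot_b
    se = float(np.std(diffs, ddof=1)) if n_boot > 1 else 0.0
    observed = pauc_a.area - pauc_b.area
    if se == 0.0:
        # Degenerate bootstrap: identical replicates throughout.
        z = 0.0 if observed == 0.0 else float(np.sign(observed) * np.inf)
        p = 1.0 if observed == 0.0 else 0.0
        warnings.warn("zero bootstrap variance of the pAUC difference")
    else:
        z = observed / se
        p = float(2.0 * norm.sf(abs(z)))
    return PAUCComparison(
        pauc_1=pauc_a.area,
        pauc_2=pauc_b.area,
        cutoff=cutoff,
        se_diff=se,
        z=float(z),
        p=p,
        n_boot=n_boot,
        seed=seed,
        curve_1=curve_a,
        curve_2=curve_b,
    )
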