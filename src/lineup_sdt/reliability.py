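"""Confidence-accuracy (CAC) and response-time-accuracy (RAC) curves.

Both analyses answer the courtroom question "given that this witness
identified the suspect, how likely is the identification to be correct?".
Suspect-ID accuracy in a bin is

    accuracy = CID / (CID + FID / k)

where CID counts suspect IDs from target-present lineups in the bin, FID
counts filler IDs from target-absent lineups in the bin, and the division
by the lineup size ``k`` converts filler IDs into an estimate of innocent-
suspect IDs.  CAC bins by confidence rating, RAC by response time.
Uncertainty is a 68% percentile bootstrap interval (+- 1 SE equivalent);
curves are compared by whether the error bars of two points overlap, not
by a p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import (
    BinningScheme,
    LineupOutcomeTable,
    LineupType,
    Response,
    TrialRecord,
    bin_by_confidence,
    RAW_LEVELS,
)

__all__ = [
    "AccuracyCurve",
    "cac",
    "rac",
    "bootstrap_accuracy_ci",
    "rebin_on_sparsity",
    "reliable_difference",
]


@dataclass(frozen=True)
class AccuracyCurve:
    """Suspect-ID accuracy per bin with bootstrap uncertainty.

    Bins with no identifications have accuracy NaN (undefined, not 0).
    ``unstable`` flags bins that were empty in more than half of the
    bootstrap replicates; their intervals should not be interpreted.
    """

    bin_labels: tuple[str, ...]
    accuracy: np.ndarray
    n_cid: np.ndarray
    n_fid: np.ndarray
    k: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    level: float | None = None
    unstable: np.ndarray | None = None
    n_excluded: int = 0

    @property
    def point_weights(self) -> np.ndarray:
        total = self.n_cid.sum() + self.n_fid.sum()
        if total == 0:
            return np.zeros_like(self.accuracy)
        return (self.n_cid + self.n_fid) / total

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.accuracy)


def _accuracy(cid: np.ndarray, fid: np.ndarray, k: int) -> np.ndarray:
    cid = np.asarray(cid, dtype=float)
    fid = np.asarray(fid, dtype=float)
    denom = cid + fid / k
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(denom > 0, cid / np.where(denom > 0, denom, 1.0), np.nan)
    return acc


def cac(table: LineupOutcomeTable, scheme: BinningScheme | None = None) -> AccuracyCurve:
    """Confidence-accuracy characteristic from an outcome table."""
    scheme = scheme or BinningScheme()
    binned = bin_by_confidence(table, scheme) if table.levels == RAW_LEVELS else table
    cid = np.asarray(binned.tp_suspect, dtype=float)
    fid = np.asarray(binned.ta_filler, dtype=float)
    acc = _accuracy(cid, fid, binned.k)
    if np.isnan(acc).any():
        warnings.warn(
            "confidence bin(s) with no identifications: accuracy undefined; "
            "consider rebin_on_sparsity"
        )
    return AccuracyCurve(
        bin_labels=binned.level_labels,
        accuracy=acc,
        n_cid=cid.astype(int),
        n_fid=fid.astype(int),
        k=binned.k,
    )


def _rt_bin_counts(
    records: list[TrialRecord], scheme: BinningScheme, k: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-RT-bin (CID, FID) counts; records without rt are dropped."""
    nbins = scheme.n_rt_bins
    cid = np.zeros(nbins)
    fid = np.zeros(nbins)
    n_excluded = 0
    for r in records:
        is_tp_suspect = (
            r.lineup_type is LineupType.TARGET_PRESENT
            and r.response is Response.SUSPECT_ID
        )
        is_ta_filler = (
            r.lineup_type is LineupType.TARGET_ABSENT
            and r.response is Response.FILLER_ID
        )
        if not (is_tp_suspect or is_ta_filler):
            continue
        if r.rt is None:
            n_excluded += 1
            continue
        b = scheme.rt_bin_index(r.rt)
        if is_tp_suspect:
            cid[b] += 1
        else:
            fid[b] += 1
    return cid, fid, n_excluded


def rac(
    records: list[TrialRecord], scheme: BinningScheme | None = None, k: int = 6
) -> AccuracyCurve:
    """Response-time-accuracy characteristic from trial-level records."""
    scheme = scheme or BinningScheme()
    cid, fid, n_excluded = _rt_bin_counts(list(records), scheme, k)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} identification(s) without response time")
    acc = _accuracy(cid, fid, k)
    if np.isnan(acc).any():
        warnings.warn(
            "response-time bin(s) with no identifications: accuracy undefined; "
            "consider rebin_on_sparsity"
        )
    return AccuracyCurve(
        bin_labels=scheme.rt_bin_labels(),
        accuracy=acc,
        n_cid=cid.astype(int),
        n_fid=fid.astype(int),
        k=k,
        n_excluded=n_excluded,
    )


def _bootstrap_curve_counts(
    tp_cats: np.ndarray,
    ta_cats: np.ndarray,
    n_bins: int,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Case bootstrap over lineups within each lineup type.

    ``tp_cats`` holds the TP outcome-category counts: one category per bin
    for suspect IDs, plus a final 'everything else' category (filler IDs
    and rejections pooled, which never enter the accuracy formula).
    Likewise ``ta_cats`` for TA filler IDs.  Returns per-replicate
    (CID, FID) count matrices of shape (n_boot, n_bins).
    """
    n_tp, n_ta = int(tp_cats.sum()), int(ta_cats.sum())
    cid = rng.multinomial(n_tp, tp_cats / n_tp, size=n_boot)[:, :n_bins]
    fid = rng.multinomial(n_ta, ta_cats / n_ta, size=n_boot)[:, :n_bins]
    return cid.astype(float), fid.astype(float)


def bootstrap_accuracy_ci(
    inputs: LineupOutcomeTable | list[TrialRecord],
    scheme: BinningScheme | None = None,
    n_boot: int = 10_000,
    level: float = 0.68,
    seed: int | np.random.SeedSequence = 0,
    k: int = 6,
) -> AccuracyCurve:
    """CAC or RAC with percentile bootstrap confidence intervals.

    Pass an outcome table for a CAC, or trial records (with response
    times) for a RAC.  Target-present and target-absent lineups are
    resampled with replacement independently; the interval per bin is the
    central ``level`` percentile range of the replicate accuracies (68%
    approximates +- 1 standard error).  Bins that were empty in more than
    half of the replicates are flagged unstable.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scheme = scheme or BinningScheme()
    rng = np.random.default_rng(seed)
    if isinstance(inputs, LineupOutcomeTable):
        point = cac(inputs, scheme)
        binned = (
            bin_by_confidence(inputs, scheme)
            if inputs.levels == RAW_LEVELS
            else inputs
        )
        n_bins = binned.n_levels
        tp_cats = np.append(
            np.asarray(binned.tp_suspect, float),
            binned.n_tp - sum(binned.tp_suspect),
        )
        ta_cats = np.append(
            np.asarray(binned.ta_filler, float),
            binned.n_ta - sum(binned.ta_filler),
        )
        k = binned.k
    else:
        records = list(inputs)
        point = rac(records, scheme, k=k)
        n_bins = scheme.n_rt_bins
        # Only identifications with an RT enter; the remainder of each
        # lineup type forms the pooled final category.
        n_tp = sum(1 for r in records if r.lineup_type is LineupType.TARGET_PRESENT)
        n_ta = sum(1 for r in records if r.lineup_type is LineupType.TARGET_ABSENT)
        tp_cats = np.append(point.n_cid.astype(float), n_tp - point.n_cid.sum())
        ta_cats = np.append(point.n_fid.astype(float), n_ta - point.n_fid.sum())

    cid_b, fid_b = _bootstrap_curve_counts(tp_cats, ta_cats, n_bins, n_boot, rng)
    acc_b = _accuracy(cid_b, fid_b, k)
    empty_frac = np.mean(np.isnan(acc_b), axis=0)
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        ci_low = np.nanpercentile(acc_b, lo_q, axis=0)
        ci_high = np.nanpercentile(acc_b, hi_q, axis=0)
    unstable = empty_frac > 0.5
    if unstable.any():
        warnings.warn(
            f"bin(s) {np.flatnonzero(unstable).tolist()} empty in >50% of "
            "bootstrap replicates: interval marked unstable"
        )
    return replace(
        point,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        unstable=unstable,
    )


def rebin_on_sparsity(
    counts: np.ndarray | list[int],
    scheme: BinningScheme | None = None,
    min_count: int = 10,
    axis: str = "rt",
) -> tuple[BinningScheme, list[str]]:
    """Merge adjacent sparse bins until each holds >= ``min_count`` IDs.

    ``counts`` are the identification counts (CID + FID) per bin of the
    given axis ("rt" or "confidence") of ``scheme``.  The smallest
    offending bin is repeatedly merged into its smaller neighbour.
    Returns the adjusted scheme and a log of the merges performed.
    """
    scheme = scheme or BinningScheme()
    counts = [int(c) for c in counts]
    expected = scheme.n_rt_bins if axis == "rt" else scheme.n_confidence_bins
    if len(counts) != expected:
        raise ValueError(f"{len(counts)} counts for {expected} {axis} bins")
    groups = [[i] for i in range(len(counts))]
    sums = list(counts)
    log: list[str] = []
    if sum(counts) < min_count:
        warnings.warn(
            f"total of {sum(counts)} identifications < min_count={min_count}: "
            "collapsing to a single bin"
        )
    while len(sums) > 1 and min(sums) < min_count:
        i = int(np.argmin(sums))
        if i == 0:
            j = 1
        elif i == len(sums) - 1:
            j = i - 1
        else:
            j = i - 1 if sums[i - 1] <= sums[i + 1] else i + 1
        a, b = sorted((i, j))
        log.append(
            f"merged {axis} bins {groups[a]} (n={sums[a]}) and "
            f"{groups[b]} (n={sums[b]})"
        )
        groups[a] = groups[a] + groups[b]
        sums[a] = sums[a] + sums[b]
        del groups[b], sums[b]
    if axis == "rt":
        # Keep only the edges separating surviving groups.
        edges = tuple(scheme.rt_bin_edges[g[-1]] for g in groups[:-1])
        if not edges:
            warnings.warn("all RT bins merged: single catch-all bin")
        return (
            BinningScheme(
                confidence_bins=scheme.confidence_bins, rt_bin_edges=edges
            ),
            log,
        )
    merged_bins = tuple(
        tuple(x for i in g for x in scheme.confidence_bins[i]) for g in groups
    )
    return (
        BinningScheme(confidence_bins=merged_bins, rt_bin_edges=scheme.rt_bin_edges),
        log,
    )


def reliable_difference(
    curve_a: AccuracyCurve, i: int, curve_b: AccuracyCurve, j: int
) -> bool:
    """True when the 68% error bars of the two points do not overlap.

    This is the graphical inference rule used for CAC/RAC comparisons; no
    p-value is attached.
    """
    for c in (curve_a, curve_b):
        if c.ci_low is None:
            raise ValueError("curves need bootstrap CIs; run bootstrap_accuracy_ci")
    lo_a, hi_a = curve_a.ci_low[i], curve_a.ci_high[i]
    lo_b, hi_b = curve_b.ci_low[j], curve_b.ci_high[j]
    if any(np.isnan(v) for v in (lo_a, hi_a, lo_b, hi_b)):
        return False
    return bool(hi_a < lo_b or hi_b < lo_a)
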