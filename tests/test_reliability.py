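"""CAC/RAC accuracy curves, bootstrap intervals and sparsity rebinning."""

import numpy as np
import pytest

from lineup_sdt import (
    BinningScheme,
    bin_by_confidence,
    bootstrap_accuracy_ci,
    cac,
    rac,
    rebin_on_sparsity,
    reliable_difference,
    roc_points,
)
from lineup_sdt.data import LineupOutcomeTable, TrialRecord


def _tiny_table(tp7=0, fid7=0):
    tp = [0] * 7
    fid = [0] * 7
    tp[6] = tp7
    fid[6] = fid7
    return LineupOutcomeTable(
        tp_suspect=tuple(tp),
        tp_filler=(0,) * 7,
        tp_no_id=(max(10 - tp7, 0), 0, 0, 0, 0, 0, 0),
        ta_filler=tuple(fid),
        ta_no_id=(max(10 - fid7, 0), 0, 0, 0, 0, 0, 0),
        n_tp=10,
        n_ta=10,
    )


def test_cac_high_confidence_bin_young_control(young_control, scheme):
    curve = cac(young_control, scheme)
    assert curve.accuracy[-1] == pytest.approx(80 / (80 + 5 / 6))
    assert curve.n_cid[-1] == 80 and curve.n_fid[-1] == 5
    assert curve.bin_labels == ("1-3", "4", "5", "6-7")


def test_cac_pure_bins():
    with pytest.warns(UserWarning):
        only_hits = cac(_tiny_table(tp7=5, fid7=0))
    assert only_hits.accuracy[-1] == 1.0
    with pytest.warns(UserWarning):
        only_fillers = cac(_tiny_table(tp7=0, fid7=5))
    assert only_fillers.accuracy[-1] == 0.0


def test_cac_empty_bin_is_undefined_not_zero():
    with pytest.warns(UserWarning, match="undefined"):
        curve = cac(_tiny_table(tp7=5, fid7=0))
    assert np.isnan(curve.accuracy[0])


def test_cac_matches_roc_point_increments(young_control, scheme):
    """Bin accuracy equals the positive predictive value implied by the
    ROC increment at the same bin (n_tp = n_ta here)."""
    curve = cac(young_control, scheme)
    roc = roc_points(bin_by_confidence(young_control, scheme))
    dy = np.diff(roc.y)[::-1]  # back to lowest..highest bin order
    dx = np.diff(roc.x)[::-1]
    expected = dy / (dy + dx)  # CID/(CID + FID/k) after the shared scaling
    assert curve.accuracy == pytest.approx(expected)


def _record(lineup, response, rt, conf=5, pid="p"):
    return TrialRecord(pid, "young", "control", lineup, response, conf, rt)


def test_rac_single_fast_suspect_id():
    with pytest.warns(UserWarning):
        curve = rac([_record("target_present", "suspect_id", 3.0)])
    assert curve.accuracy[0] == 1.0
    assert np.isnan(curve.accuracy[1:]).all()


def test_rac_fast_hits_slow_fillers():
    records = [
        _record("target_present", "suspect_id", 2.0, pid=f"a{i}") for i in range(5)
    ] + [_record("target_absent", "filler_id", 25.0, pid=f"b{i}") for i in range(5)]
    with pytest.warns(UserWarning):
        curve = rac(records)
    assert curve.accuracy[0] == 1.0
    assert curve.accuracy[-1] == 0.0


def test_rac_excludes_records_without_rt():
    records = [
        _record("target_present", "suspect_id", 3.0),
        _record("target_present", "suspect_id", None),
    ]
    with pytest.warns(UserWarning, match="excluded 1"):
        curve = rac(records)
    assert curve.n_excluded == 1
    assert curve.n_cid.sum() == 1


def test_bootstrap_ci_deterministic(young_control, scheme):
    a = bootstrap_accuracy_ci(young_control, scheme, n_boot=300, seed=9)
    b = bootstrap_accuracy_ci(young_control, scheme, n_boot=300, seed=9)
    assert np.array_equal(a.ci_low, b.ci_low)
    assert np.array_equal(a.ci_high, b.ci_high)
    assert np.all(a.ci_low[a.defined] <= a.accuracy[a.defined] + 1e-12)
    assert np.all(a.ci_high[a.defined] >= a.accuracy[a.defined] - 1e-12)


def test_bootstrap_ci_degenerate_zero_width():
    table = LineupOutcomeTable(
        tp_suspect=(0, 0, 0, 0, 0, 0, 10),
        tp_filler=(0,) * 7,
        tp_no_id=(0,) * 7,
        ta_filler=(0,) * 7,
        ta_no_id=(10, 0, 0, 0, 0, 0, 0),
        n_tp=10,
        n_ta=10,
    )
    curve = bootstrap_accuracy_ci(table, n_boot=100, seed=0)
    assert curve.ci_low[-1] == curve.ci_high[-1] == 1.0


def test_ci_width_shrinks_with_counts(young_control, scheme):
    big = LineupOutcomeTable(
        tp_suspect=tuple(4 * c for c in young_control.tp_suspect),
        tp_filler=tuple(4 * c for c in young_control.tp_filler),
        tp_no_id=tuple(4 * c for c in young_control.tp_no_id),
        ta_filler=tuple(4 * c for c in young_control.ta_filler),
        ta_no_id=tuple(4 * c for c in young_control.ta_no_id),
        n_tp=1000,
        n_ta=1000,
    )
    small = bootstrap_accuracy_ci(young_control, scheme, n_boot=2000, seed=2)
    bigc = bootstrap_accuracy_ci(big, scheme, n_boot=2000, seed=2)
    w_small = (small.ci_high - small.ci_low)[small.defined]
    w_big = (bigc.ci_high - bigc.ci_low)[bigc.defined]
    assert np.all(w_big < w_small)


def test_unstable_bin_flagged():
    table = _tiny_table(tp7=1, fid7=0)  # low bins always empty
    with pytest.warns(UserWarning):
        curve = bootstrap_accuracy_ci(table, n_boot=200, seed=0)
    assert curve.unstable[0]


def test_rebin_merges_sparse_tail():
    scheme, log = rebin_on_sparsity([50, 40, 3, 2], min_count=10, axis="rt")
    # last two bins fold together and, still sparse, into their neighbour
    assert scheme.rt_bin_edges == (6.0,)
    assert len(log) == 2


def test_rebin_noop_when_dense():
    scheme, log = rebin_on_sparsity([50, 40, 30, 20], min_count=10, axis="rt")
    assert scheme.rt_bin_edges == (6.0, 12.0, 18.0)
    assert log == []


def test_rebin_collapses_to_single_bin():
    with pytest.warns(UserWarning):
        scheme, log = rebin_on_sparsity([1, 1, 1, 1], min_count=10, axis="rt")
    assert scheme.rt_bin_edges == ()
    assert scheme.rt_bin_labels() == ("all",)


def test_rebin_confidence_axis(young_control):
    scheme, _ = rebin_on_sparsity(
        [13, 15, 43, 80], min_count=20, axis="confidence"
    )
    assert scheme.confidence_bins[0] == (1, 2, 3, 4)


def test_reliable_difference_predicate(young_control, scheme):
    curve = bootstrap_accuracy_ci(young_control, scheme, n_boot=2000, seed=4)
    # high-confidence accuracy is reliably above low-confidence accuracy
    assert reliable_difference(curve, 3, curve, 0)
    assert not reliable_difference(curve, 3, curve, 3)
    bare = cac(young_control, scheme)
    with pytest.raises(ValueError):
        reliable_difference(bare, 0, bare, 1)
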