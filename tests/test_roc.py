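"""ROC construction, pAUC quadrature and bootstrap inference."""

import numpy as np
import pytest

from lineup_sdt import (
    ROCCurve,
    bin_by_confidence,
    bootstrap_pauc,
    conservative_cutoff,
    pauc,
    pauc_z_test,
    roc_points,
)
from lineup_sdt.data import LineupOutcomeTable


def _curve(*pts):
    return ROCCurve(points=np.array(pts, float), point_weights=np.zeros(len(pts)))


def test_roc_points_young_control(young_control, scheme):
    curve = roc_points(bin_by_confidence(young_control, scheme))
    assert curve.points[0] == pytest.approx([0.0, 0.0])
    # strictest point: high-confidence bin only
    assert curve.points[1] == pytest.approx([5 / 1500, 80 / 250])
    # most lenient point equals the overall rates
    assert curve.rightmost == pytest.approx((0.056, 0.604))
    assert np.all(np.diff(curve.x) >= 0) and np.all(np.diff(curve.y) >= 0)


def test_roc_weights_sum_to_one(young_control, scheme):
    curve = roc_points(bin_by_confidence(young_control, scheme))
    assert curve.point_weights.sum() == pytest.approx(1.0)
    assert curve.point_weights[0] == 0.0


def test_degenerate_table_gives_origin_curve():
    empty = LineupOutcomeTable(
        tp_suspect=(0,) * 7,
        tp_filler=(0,) * 7,
        tp_no_id=(1, 0, 0, 0, 0, 0, 0),
        ta_filler=(0,) * 7,
        ta_no_id=(1, 0, 0, 0, 0, 0, 0),
        n_tp=1,
        n_ta=1,
    )
    with pytest.warns(UserWarning, match="degenerate"):
        curve = roc_points(empty)
    assert curve.degenerate
    assert np.all(curve.x == 0.0)


def test_conservative_cutoff_picks_smaller_rightmost(
    young_control, older_control, scheme
):
    a = roc_points(bin_by_confidence(young_control, scheme))
    b = roc_points(bin_by_confidence(older_control, scheme))
    assert b.rightmost[0] == pytest.approx(91 / 1500)
    assert conservative_cutoff(a, b) == pytest.approx(0.056)
    assert conservative_cutoff(a, a) == pytest.approx(0.056)


def test_pauc_triangle():
    assert pauc(_curve((0, 0), (0.1, 1.0)), 0.1).area == pytest.approx(0.05)


def test_pauc_hand_trapezoid():
    curve = _curve((0, 0), (0.02, 0.5), (0.06, 0.7))
    # full first segment (0.02 * 0.25) plus half of the second up to 0.04
    assert pauc(curve, 0.04).area == pytest.approx(0.02 * 0.25 + 0.02 * 0.55)


def test_pauc_additivity(young_control, scheme):
    curve = roc_points(bin_by_confidence(young_control, scheme))
    cutoff = 0.05
    total = pauc(curve, cutoff).area
    half = pauc(curve, cutoff / 2).area
    assert half + (total - half) == pytest.approx(total)
    assert pauc(curve, cutoff / 2).area <= total  # monotone in cutoff


def test_pauc_extrapolation_flagged():
    curve = _curve((0, 0), (0.02, 0.5), (0.04, 0.6))
    with pytest.warns(UserWarning, match="extrapolat"):
        res = pauc(curve, 0.06)
    assert res.extrapolated
    # linear extension of the last segment: slope 5
    assert res.area == pytest.approx(
        pauc(curve, 0.04).area + 0.02 * (0.6 + 0.7) / 2
    )


def test_pauc_requires_positive_cutoff(young_control, scheme):
    curve = roc_points(bin_by_confidence(young_control, scheme))
    with pytest.raises(ValueError):
        pauc(curve, 0.0)


def test_pauc_invariant_to_bin_split_below_cutoff(young_control, scheme):
    """Splitting a confidence bin adds an ROC point beyond the shared
    boundary; the pAUC up to any shared cumulative boundary is unchanged."""
    from lineup_sdt.data import BinningScheme

    finer = BinningScheme(confidence_bins=((1,), (2, 3), (4,), (5,), (6, 7)))
    a = roc_points(bin_by_confidence(young_control, scheme))
    b = roc_points(bin_by_confidence(young_control, finer))
    cutoff = a.x[2]  # boundary shared by both binnings
    assert pauc(b, cutoff).area == pytest.approx(pauc(a, cutoff).area)


def test_bootstrap_pauc_deterministic_and_consistent(young_control, scheme):
    kw = dict(cutoff=0.056, n_boot=500, seed=11)
    one = bootstrap_pauc(young_control, scheme, **kw)
    two = bootstrap_pauc(young_control, scheme, **kw)
    assert np.array_equal(one, two)
    # bootstrap mean close to the point estimate
    point = pauc(roc_points(bin_by_confidence(young_control, scheme)), 0.056).area
    assert np.mean(one) == pytest.approx(point, rel=0.05)


def test_bootstrap_se_shrinks_with_sample_size(young_control, scheme):
    big = LineupOutcomeTable(
        tp_suspect=tuple(4 * c for c in young_control.tp_suspect),
        tp_filler=tuple(4 * c for c in young_control.tp_filler),
        tp_no_id=tuple(4 * c for c in young_control.tp_no_id),
        ta_filler=tuple(4 * c for c in young_control.ta_filler),
        ta_no_id=tuple(4 * c for c in young_control.ta_no_id),
        n_tp=1000,
        n_ta=1000,
    )
    se_small = np.std(
        bootstrap_pauc(young_control, scheme, 0.056, n_boot=2000, seed=1), ddof=1
    )
    se_big = np.std(bootstrap_pauc(big, scheme, 0.056, n_boot=2000, seed=1), ddof=1)
    assert se_big / se_small == pytest.approx(0.5, abs=0.12)


def test_degenerate_bootstrap_has_zero_se():
    # every TP lineup a high-confidence hit, every TA lineup a rejection
    table = LineupOutcomeTable(
        tp_suspect=(0, 0, 0, 0, 0, 0, 10),
        tp_filler=(0,) * 7,
        tp_no_id=(0,) * 7,
        ta_filler=(0,) * 7,
        ta_no_id=(10, 0, 0, 0, 0, 0, 0),
        n_tp=10,
        n_ta=10,
    )
    from lineup_sdt.data import BinningScheme

    with pytest.warns(UserWarning):
        dist = bootstrap_pauc(table, BinningScheme(), cutoff=0.01, n_boot=50, seed=0)
    assert np.ptp(dist) == 0.0


def test_z_test_table_against_itself(young_control, scheme):
    cmp = pauc_z_test(young_control, young_control, scheme, n_boot=400, seed=3)
    assert cmp.z == 0.0
    assert cmp.p == pytest.approx(1.0)


def test_z_test_directionality(young_control, older_control, scheme):
    cmp = pauc_z_test(young_control, older_control, scheme, n_boot=2000, seed=5)
    assert cmp.pauc_1 > cmp.pauc_2
    assert cmp.z > 0
    assert cmp.cutoff == pytest.approx(0.056)
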