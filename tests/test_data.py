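"""Data model, CSV IO, tabulation and confidence binning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineup_sdt import (
    BinningScheme,
    LineupOutcomeTable,
    TrialRecord,
    bin_by_confidence,
    expand,
    load_trials,
    read_frequency_csv,
    table2_fixture,
    tabulate,
    write_frequency_csv,
    write_trials,
)
from lineup_sdt.data import FormatError, ValidationError

CSV_HEADER = "participant_id,group,condition,lineup_type,response,confidence,rt\n"

TOY_ROWS = (
    "p1,young,control,target_present,suspect_id,7,4.2\n"
    "p2,young,control,target_present,filler_id,3,9.1\n"
    "p3,young,control,target_absent,filler_id,5,\n"
    "p4,young,control,target_absent,no_id,6,20.5\n"
)


def test_load_trials_parses_each_response_type(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(CSV_HEADER + TOY_ROWS)
    records = load_trials(path)
    assert len(records) == 4
    assert records[0].response.value == "suspect_id"
    assert records[2].rt is None
    assert records[3].confidence == 6


def test_load_trials_empty_file_gives_empty_collection(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(CSV_HEADER)
    assert load_trials(path) == []


def test_load_trials_rejects_out_of_range_confidence(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(CSV_HEADER + "p1,young,control,target_present,suspect_id,9,1.0\n")
    with pytest.raises(ValidationError, match="line 2"):
        load_trials(path)


def test_load_trials_rejects_missing_column(tmp_path):
    path = tmp_path / "cols.csv"
    path.write_text("participant_id,group,condition\n")
    with pytest.raises(FormatError, match="confidence"):
        load_trials(path)


def test_trials_csv_round_trip(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(CSV_HEADER + TOY_ROWS)
    records = load_trials(path)
    out = tmp_path / "copy.csv"
    write_trials(records, out)
    assert load_trials(out) == records


def test_suspect_id_impossible_on_target_absent():
    with pytest.raises(ValidationError, match="target-absent"):
        TrialRecord("p1", "young", "control", "target_absent", "suspect_id", 5)


def test_tabulate_counts_and_totals():
    records = [
        TrialRecord(f"p{i}", "young", "control", "target_present", "suspect_id", 7)
        for i in range(2)
    ]
    table = tabulate(records)
    assert table.count("target_present", "suspect_id", 7) == 2
    assert table.n_tp == 2 and table.n_ta == 0


def test_tabulate_rejects_mixed_cells():
    records = [
        TrialRecord("p1", "young", "control", "target_present", "no_id", 1),
        TrialRecord("p2", "older", "control", "target_present", "no_id", 1),
    ]
    with pytest.raises(ValidationError, match="cells"):
        tabulate(records)


@pytest.mark.parametrize("group", ["young", "older"])
@pytest.mark.parametrize("condition", ["control", "experimental"])
def test_tabulate_expand_round_trip(group, condition):
    table = table2_fixture(group, condition)
    again = tabulate(expand(table, seed=0))
    assert again.tp_suspect == table.tp_suspect
    assert again.tp_filler == table.tp_filler
    assert again.tp_no_id == table.tp_no_id
    assert again.ta_filler == table.ta_filler
    assert again.ta_no_id == table.ta_no_id
    assert (again.n_tp, again.n_ta) == (250, 250)


# Published identification rates per cell: (correct, estimated false).
PRINTED_RATES = {
    ("young", "control"): (0.604, 0.056),
    ("young", "experimental"): (0.440, 0.031),
    ("older", "control"): (0.368, 0.061),
    ("older", "experimental"): (0.200, 0.036),
}


@pytest.mark.parametrize("cell", sorted(PRINTED_RATES))
def test_fixture_row_sums_match_printed_rates(cell):
    table = table2_fixture(*cell)
    correct, false = PRINTED_RATES[cell]
    assert round(sum(table.tp_suspect) / 250, 3) == pytest.approx(correct)
    assert round(sum(table.ta_filler) / 1500, 3) == pytest.approx(false)
    assert table.n_tp == table.n_ta == 250 and table.k == 6


def test_fixture_spot_counts(young_control, older_experimental):
    assert young_control.tp_suspect == (0, 2, 11, 15, 43, 37, 43)
    assert young_control.ta_filler == (2, 3, 21, 18, 35, 3, 2)
    assert older_experimental.tp_suspect == (0, 1, 5, 8, 18, 11, 7)


def test_default_binning_on_young_control(young_control, scheme):
    binned = bin_by_confidence(young_control, scheme)
    assert binned.tp_suspect == (13, 15, 43, 80)
    assert binned.level_labels == ("1-3", "4", "5", "6-7")


def test_single_bin_sums_everything(young_control):
    one = BinningScheme(confidence_bins=((1, 2, 3, 4, 5, 6, 7),))
    binned = bin_by_confidence(young_control, one)
    assert binned.tp_suspect == (151,)


def test_identity_binning_is_noop(young_control):
    ident = BinningScheme(confidence_bins=tuple((i,) for i in range(1, 8)))
    binned = bin_by_confidence(young_control, ident)
    assert binned.tp_suspect == young_control.tp_suspect
    assert binned.ta_filler == young_control.ta_filler


def test_non_partition_scheme_rejected():
    with pytest.raises(ValidationError):
        BinningScheme(confidence_bins=((1, 2), (4,), (5,), (6, 7)))
    with pytest.raises(ValidationError):
        BinningScheme(rt_bin_edges=(6.0, 6.0))


@st.composite
def partitions(draw):
    cuts = draw(st.sets(st.integers(min_value=1, max_value=6), max_size=6))
    edges = [0, *sorted(cuts), 7]
    return tuple(
        tuple(range(a + 1, b + 1)) for a, b in zip(edges, edges[1:]) if b > a
    )


@settings(derandomize=True, max_examples=30, deadline=None)
@given(bins=partitions())
def test_binning_conserves_totals(bins):
    table = table2_fixture("older", "control")
    binned = bin_by_confidence(table, BinningScheme(confidence_bins=bins))
    for row in ("tp_suspect", "tp_filler", "tp_no_id", "ta_filler", "ta_no_id"):
        assert sum(getattr(binned, row)) == sum(getattr(table, row))


def test_frequency_csv_round_trip(tmp_path, older_control):
    path = tmp_path / "freq.csv"
    write_frequency_csv(older_control, path)
    again = read_frequency_csv(path)
    assert again.tp_suspect == older_control.tp_suspect
    assert again.ta_no_id == older_control.ta_no_id
    assert (again.n_tp, again.n_ta, again.k) == (250, 250, 6)


def test_table_invariant_enforced():
    with pytest.raises(ValidationError, match="n_tp"):
        LineupOutcomeTable(
            tp_suspect=(1,) * 7,
            tp_filler=(0,) * 7,
            tp_no_id=(0,) * 7,
            ta_filler=(0,) * 7,
            ta_no_id=(0,) * 7,
            n_tp=99,
            n_ta=0,
        )


def test_rt_boundary_goes_to_upper_bin(scheme):
    assert scheme.rt_bin_index(5.999) == 0
    assert scheme.rt_bin_index(6.0) == 1
    assert scheme.rt_bin_index(18.0) == 3
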