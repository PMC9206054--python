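"""Core data model for simultaneous-lineup identification experiments.

A witness sees a lineup of ``k`` faces (here six, arranged as two rows of
three) that either contains the perpetrator (target-present, TP) or only
fillers (target-absent, TA).  The witness identifies one member or rejects
the lineup ("not present"), and rates confidence on a 7-point scale
(1 = guessing, 7 = certain).  All analyses in this package start from either
trial-level records (:class:`TrialRecord`) or aggregated frequency tables
(:class:`LineupOutcomeTable`) of the kind published for the verbal
overshadowing study packaged here as :func:`table2_fixture`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Condition",
    "LineupType",
    "Response",
    "TrialRecord",
    "LineupOutcomeTable",
    "BinningScheme",
    "DEFAULT_CONFIDENCE_BINS",
    "DEFAULT_RT_EDGES",
    "FormatError",
    "ValidationError",
    "load_trials",
    "write_trials",
    "tabulate",
    "bin_by_confidence",
    "table2_fixture",
    "read_frequency_csv",
    "write_frequency_csv",
]

N_CONFIDENCE_LEVELS = 7


class Group(str, enum.Enum):
    YOUNG = "young"
    OLDER = "older"


class Condition(str, enum.Enum):
    CONTROL = "control"
    EXPERIMENTAL = "experimental"


class LineupType(str, enum.Enum):
    TARGET_PRESENT = "target_present"
    TARGET_ABSENT = "target_absent"


class Response(str, enum.Enum):
    SUSPECT_ID = "suspect_id"
    FILLER_ID = "filler_id"
    NO_ID = "no_id"


class FormatError(ValueError):
    """Raised when an input file does not have the expected columns."""


class ValidationError(ValueError):
    """Raised when a record violates the data model's invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One witness's lineup decision.

    ``rt`` is the response time in seconds from lineup onset to button
    press; it may be ``None`` for datasets that did not record it.
    Confidence is recorded for every response type, including rejections.
    """

    participant_id: str
    group: Group
    condition: Condition
    lineup_type: LineupType
    response: Response
    confidence: int
    rt: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "lineup_type", LineupType(self.lineup_type))
        object.__setattr__(self, "response", Response(self.response))
        object.__setattr__(self, "confidence", int(self.confidence))
        if not (1 <= int(self.confidence) <= N_CONFIDENCE_LEVELS):
            raise ValidationError(
                f"confidence must be in 1..{N_CONFIDENCE_LEVELS}, got {self.confidence}"
            )
        if (
            self.lineup_type is LineupType.TARGET_ABSENT
            and self.response is Response.SUSPECT_ID
        ):
            # No designated innocent suspect: every TA identification is a
            # filler identification by construction.
            raise ValidationError(
                "suspect_id is impossible on a target-absent lineup "
                "without a designated innocent suspect"
            )
        if self.rt is not None and not self.rt > 0:
            raise ValidationError(f"rt must be positive, got {self.rt}")


def _as_level_tuple(levels: Sequence) -> tuple[tuple[int, ...], ...]:
    out = []
    for lv in levels:
        if isinstance(lv, (int, np.integer)):
            out.append((int(lv),))
        else:
            out.append(tuple(int(x) for x in lv))
    return tuple(out)


RAW_LEVELS = tuple((i,) for i in range(1, N_CONFIDENCE_LEVELS + 1))


@dataclass(frozen=True)
class LineupOutcomeTable:
    """Counts of lineup outcomes per response category and confidence level.

    Rows are stored as five nonnegative integer vectors over ``levels``
    (confidence levels, or confidence bins after :func:`bin_by_confidence`):
    TP suspect IDs (correct IDs), TP filler IDs, TP rejections, TA filler
    IDs and TA rejections.  ``n_tp`` / ``n_ta`` are the numbers of
    target-present / target-absent lineups and must equal the corresponding
    row sums.  ``k`` is the lineup size.
    """

    tp_suspect: tuple[int, ...]
    tp_filler: tuple[int, ...]
    tp_no_id: tuple[int, ...]
    ta_filler: tuple[int, ...]
    ta_no_id: tuple[int, ...]
    n_tp: int
    n_ta: int
    k: int = 6
    levels: tuple[tuple[int, ...], ...] = RAW_LEVELS
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", _as_level_tuple(self.levels))
        m = len(self.levels)
        for name in ("tp_suspect", "tp_filler", "tp_no_id", "ta_filler", "ta_no_id"):
            row = tuple(int(x) for x in getattr(self, name))
            object.__setattr__(self, name, row)
            if len(row) != m:
                raise ValidationError(f"{name} has {len(row)} entries for {m} levels")
            if any(x < 0 for x in row):
                raise ValidationError(f"{name} contains negative counts")
        if self.k < 2:
            raise ValidationError(f"lineup size k must be >= 2, got {self.k}")
        tp_total = sum(self.tp_suspect) + sum(self.tp_filler) + sum(self.tp_no_id)
        ta_total = sum(self.ta_filler) + sum(self.ta_no_id)
        if tp_total != self.n_tp:
            raise ValidationError(
                f"target-present counts sum to {tp_total}, but n_tp = {self.n_tp}"
            )
        if ta_total != self.n_ta:
            raise ValidationError(
                f"target-absent counts sum to {ta_total}, but n_ta = {self.n_ta}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def level_labels(self) -> tuple[str, ...]:
        return tuple(
            str(lv[0]) if len(lv) == 1 else f"{lv[0]}-{lv[-1]}" for lv in self.levels
        )

    def count(self, lineup_type: LineupType, response: Response, level: int) -> int:
        """Count for a single raw confidence level (1..7)."""
        idx = next(i for i, lv in enumerate(self.levels) if level in lv)
        row = self._row(lineup_type, response)
        return row[idx]

    def _row(self, lineup_type: LineupType, response: Response) -> tuple[int, ...]:
        lt = LineupType(lineup_type)
        resp = Response(response)
        if lt is LineupType.TARGET_PRESENT:
            return {
                Response.SUSPECT_ID: self.tp_suspect,
                Response.FILLER_ID: self.tp_filler,
                Response.NO_ID: self.tp_no_id,
            }[resp]
        if resp is Response.SUSPECT_ID:
            raise ValidationError("no suspect_id row on target-absent lineups")
        return {
            Response.FILLER_ID: self.ta_filler,
            Response.NO_ID: self.ta_no_id,
        }[resp]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frequency table (one row per cell with a count)."""
        rows = []
        for lt, resp, vec in (
            (LineupType.TARGET_PRESENT, Response.SUSPECT_ID, self.tp_suspect),
            (LineupType.TARGET_PRESENT, Response.FILLER_ID, self.tp_filler),
            (LineupType.TARGET_PRESENT, Response.NO_ID, self.tp_no_id),
            (LineupType.TARGET_ABSENT, Response.FILLER_ID, self.ta_filler),
            (LineupType.TARGET_ABSENT, Response.NO_ID, self.ta_no_id),
        ):
            for label, count in zip(self.level_labels, vec):
                rows.append(
                    {
                        "lineup_type": lt.value,
                        "response": resp.value,
                        "confidence": label,
                        "count": count,
                    }
                )
        return pd.DataFrame(rows)

    def with_meta(self, **meta: str) -> "LineupOutcomeTable":
        return replace(self, meta={**dict(self.meta), **meta})


@dataclass(frozen=True)
class BinningScheme:
    """Confidence bins (an ordered partition of 1..7, lowest to highest)
    and response-time bin edges (seconds, strictly increasing; edges
    ``(6, 12, 18)`` define the intervals < 6 s, 6-12 s, 12-18 s, > 18 s,
    each half-open ``[low, high)``)."""

    confidence_bins: tuple[tuple[int, ...], ...] = (
        (1, 2, 3),
        (4,),
        (5,),
        (6, 7),
    )
    rt_bin_edges: tuple[float, ...] = (6.0, 12.0, 18.0)

    def __post_init__(self) -> None:
        bins = _as_level_tuple(self.confidence_bins)
        object.__setattr__(self, "confidence_bins", bins)
        flat = [x for b in bins for x in b]
        if sorted(flat) != list(range(1, N_CONFIDENCE_LEVELS + 1)):
            raise ValidationError(
                f"confidence bins must partition 1..{N_CONFIDENCE_LEVELS}, got {bins}"
            )
        if flat != sorted(flat):
            raise ValidationError("confidence bins must be ordered lowest to highest")
        edges = tuple(float(e) for e in self.rt_bin_edges)
        object.__setattr__(self, "rt_bin_edges", edges)
        if any(b >= a for b, a in zip(edges, edges[1:])):
            raise ValidationError(f"rt bin edges must be strictly increasing: {edges}")

    @property
    def n_confidence_bins(self) -> int:
        return len(self.confidence_bins)

    @property
    def n_rt_bins(self) -> int:
        return len(self.rt_bin_edges) + 1

    def rt_bin_labels(self) -> tuple[str, ...]:
        e = self.rt_bin_edges
        if not e:
            return ("all",)

        def fmt(x: float) -> str:
            return f"{x:g}"

        labels = [f"<{fmt(e[0])}s"]
        labels += [f"{fmt(a)}-{fmt(b)}s" for a, b in zip(e, e[1:])]
        labels.append(f">{fmt(e[-1])}s")
        return tuple(labels)

    def rt_bin_index(self, rt: float) -> int:
        """Bin index for a response time; boundary values go to the upper bin."""
        return int(np.searchsorted(self.rt_bin_edges, rt, side="right"))


#: Binning used throughout the published analysis: low (1-3), medium-low (4),
#: medium-high (5) and high (6-7) confidence.
DEFAULT_CONFIDENCE_BINS = BinningScheme().confidence_bins
#: Response-time bin edges after re-binning for bootstrap feasibility.
DEFAULT_RT_EDGES = BinningScheme().rt_bin_edges


REQUIRED_COLUMNS = (
    "participant_id",
    "group",
    "condition",
    "lineup_type",
    "response",
    "confidence",
    "rt",
)


def load_trials(path: str | Path) -> list[TrialRecord]:
    """Read trial-level records from a comma-separated UTF-8 file.

    The header must name the columns ``participant_id, group, condition,
    lineup_type, response, confidence, rt``; ``rt`` entries may be empty.
    Malformed rows raise :class:`ValidationError` naming the line number.
    """
    path = Path(path)
    records: list[TrialRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rt_raw = (row.get("rt") or "").strip()
                records.append(
                    TrialRecord(
                        participant_id=row["participant_id"],
                        group=Group(row["group"].strip().lower()),
                        condition=Condition(row["condition"].strip().lower()),
                        lineup_type=LineupType(row["lineup_type"].strip().lower()),
                        response=Response(row["response"].strip().lower()),
                        confidence=int(row["confidence"]),
                        rt=float(rt_raw) if rt_raw else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.group.value,
                    r.condition.value,
                    r.lineup_type.value,
                    r.response.value,
                    r.confidence,
                    "" if r.rt is None else f"{r.rt:.6g}",
                ]
            )


def tabulate(records: Iterable[TrialRecord], k: int = 6) -> LineupOutcomeTable:
    """Aggregate trial records into a :class:`LineupOutcomeTable`.

    All records must come from a single (group, condition) cell; group the
    records first to tabulate a full factorial design.
    """
    records = list(records)
    cells = {(r.group, r.condition) for r in records}
    if len(cells) > 1:
        raise ValidationError(
            f"records span multiple (group, condition) cells: {sorted(cells)}; "
            "group records before tabulating"
        )
    rows = {
        (LineupType.TARGET_PRESENT, Response.SUSPECT_ID): np.zeros(7, dtype=int),
        (LineupType.TARGET_PRESENT, Response.FILLER_ID): np.zeros(7, dtype=int),
        (LineupType.TARGET_PRESENT, Response.NO_ID): np.zeros(7, dtype=int),
        (LineupType.TARGET_ABSENT, Response.FILLER_ID): np.zeros(7, dtype=int),
        (LineupType.TARGET_ABSENT, Response.NO_ID): np.zeros(7, dtype=int),
    }
    for r in records:
        rows[(r.lineup_type, r.response)][r.confidence - 1] += 1
    n_tp = sum(
        int(rows[(LineupType.TARGET_PRESENT, resp)].sum()) for resp in Response
    )
    n_ta = sum(
        int(rows[(LineupType.TARGET_ABSENT, resp)].sum())
        for resp in (Response.FILLER_ID, Response.NO_ID)
    )
    meta = {}
    if cells:
        (group, condition), = cells
        meta = {"group": group.value, "condition": condition.value}
    return LineupOutcomeTable(
        tp_suspect=tuple(rows[(LineupType.TARGET_PRESENT, Response.SUSPECT_ID)]),
        tp_filler=tuple(rows[(LineupType.TARGET_PRESENT, Response.FILLER_ID)]),
        tp_no_id=tuple(rows[(LineupType.TARGET_PRESENT, Response.NO_ID)]),
        ta_filler=tuple(rows[(LineupType.TARGET_ABSENT, Response.FILLER_ID)]),
        ta_no_id=tuple(rows[(LineupType.TARGET_ABSENT, Response.NO_ID)]),
        n_tp=n_tp,
        n_ta=n_ta,
        k=k,
        meta=meta,
    )


def bin_by_confidence(
    table: LineupOutcomeTable, scheme: BinningScheme
) -> LineupOutcomeTable:
    """Sum counts within the scheme's confidence bins; totals are conserved.

    The table must still be at raw 7-level resolution.
    """
    if table.levels != RAW_LEVELS:
        raise ValidationError("table is already binned; bin from the raw table")

    def binned(vec: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(sum(vec[lv - 1] for lv in b) for b in scheme.confidence_bins)

    return replace(
        table,
        tp_suspect=binned(table.tp_suspect),
        tp_filler=binned(table.tp_filler),
        tp_no_id=binned(table.tp_no_id),
        ta_filler=binned(table.ta_filler),
        ta_no_id=binned(table.ta_no_id),
        levels=scheme.confidence_bins,
    )


# Published outcome frequencies for the four (age group x description
# condition) cells: counts at confidence 1..7, with 250 target-present and
# 250 target-absent lineups of size 6 per cell.  Row sums reproduce every
# published identification rate (e.g. young-control correct IDs
# 151/250 = 0.604, target-absent filler IDs 84/1500 = 0.056).
_TABLE2 = {
    (Group.YOUNG, Condition.CONTROL): dict(
        tp_suspect=(0, 2, 11, 15, 43, 37, 43),
        tp_filler=(2, 1, 2, 5, 10, 2, 1),
        tp_no_id=(0, 1, 8, 12, 31, 16, 8),
        ta_filler=(2, 3, 21, 18, 35, 3, 2),
        ta_no_id=(3, 5, 19, 24, 60, 34, 21),
    ),
    (Group.YOUNG, Condition.EXPERIMENTAL): dict(
        tp_suspect=(0, 2, 7, 21, 39, 27, 14),
        tp_filler=(0, 2, 5, 11, 4, 2, 0),
        tp_no_id=(2, 5, 10, 23, 40, 20, 16),
        ta_filler=(2, 6, 7, 12, 17, 3, 0),
        ta_no_id=(3, 7, 24, 22, 59, 55, 33),
    ),
    (Group.OLDER, Condition.CONTROL): dict(
        tp_suspect=(0, 4, 2, 19, 35, 20, 12),
        tp_filler=(2, 3, 3, 14, 18, 6, 0),
        tp_no_id=(3, 1, 9, 22, 40, 29, 8),
        ta_filler=(1, 8, 10, 23, 37, 10, 2),
        ta_no_id=(3, 5, 9, 27, 45, 47, 23),
    ),
    (Group.OLDER, Condition.EXPERIMENTAL): dict(
        tp_suspect=(0, 1, 5, 8, 18, 11, 7),
        tp_filler=(0, 4, 9, 3, 8, 3, 1),
        tp_no_id=(3, 10, 8, 35, 48, 41, 27),
        ta_filler=(1, 4, 5, 16, 23, 4, 1),
        ta_no_id=(1, 5, 12, 27, 58, 50, 43),
    ),
}


def table2_fixture(
    group: Group | str, condition: Condition | str
) -> LineupOutcomeTable:
    """Published outcome-frequency table for one study cell.

    Returns the frequencies of correct identifications, filler
    identifications and rejections at each confidence level for the given
    age group and description condition (n_tp = n_ta = 250, k = 6).
    """
    key = (Group(group), Condition(condition))
    return LineupOutcomeTable(
        **_TABLE2[key],
        n_tp=250,
        n_ta=250,
        k=6,
        meta={"group": key[0].value, "condition": key[1].value},
    )


def write_frequency_csv(table: LineupOutcomeTable, path: str | Path) -> None:
    df = table.to_frame()
    df.attrs = {}
    header = f"# n_tp={table.n_tp} n_ta={table.n_ta} k={table.k}\n"
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_frequency_csv(path: str | Path) -> LineupOutcomeTable:
    """Read an aggregated frequency table written by :func:`write_frequency_csv`.

    The file holds one row per (lineup_type, response, confidence) with a
    count column, preceded by a comment line carrying n_tp, n_ta and k.
    Only raw 7-level tables are supported.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing '# n_tp=... n_ta=... k=...' header")
        meta = dict(tok.split("=") for tok in first[1:].split())
        df = pd.read_csv(fh)
    missing = {"lineup_type", "response", "confidence", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows = {}
    for key in (
        (LineupType.TARGET_PRESENT, Response.SUSPECT_ID),
        (LineupType.TARGET_PRESENT, Response.FILLER_ID),
        (LineupType.TARGET_PRESENT, Response.NO_ID),
        (LineupType.TARGET_ABSENT, Response.FILLER_ID),
        (LineupType.TARGET_ABSENT, Response.NO_ID),
    ):
        lt, resp = key
        sub = df[(df.lineup_type == lt.value) & (df.response == resp.value)]
        vec = np.zeros(N_CONFIDENCE_LEVELS, dtype=int)
        for _, row in sub.iterrows():
            vec[int(row["confidence"]) - 1] = int(row["count"])
        rows[key] = tuple(vec)
    return LineupOutcomeTable(
        tp_suspect=rows[(LineupType.TARGET_PRESENT, Response.SUSPECT_ID)],
        tp_filler=rows[(LineupType.TARGET_PRESENT, Response.FILLER_ID)],
        tp_no_id=rows[(LineupType.TARGET_PRESENT, Response.NO_ID)],
        ta_filler=rows[(LineupType.TARGET_ABSENT, Response.FILLER_ID)],
        ta_no_id=rows[(LineupType.TARGET_ABSENT, Response.NO_ID)],
        n_tp=int(meta["n_tp"]),
        n_ta=int(meta["n_ta"]),
        k=int(meta["k"]),
    )
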