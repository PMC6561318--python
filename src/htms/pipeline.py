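"""Glue between count tables, per-pair statistics, and screen aggregation."""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from htms.odds_ratio import (
    DEFAULT_MIN_UNTREATED_READS,
    ContingencyTable,
    NullSpec,
    ORResult,
    Status,
    UNDEFINED,
    evaluate_sample_pair,
)
from htms.screen_analysis import MouseDesign, ScreenTable
from htms.trigger_counts import SamplePairCounts, TriggerReference

__all__ = ["evaluate_screen", "results_to_frame", "screen_table_from_frames"]


def evaluate_screen(
    pairs: Iterable[SamplePairCounts],
    reference: TriggerReference,
    null: NullSpec = NullSpec(),
    min_untreated_reads: int = DEFAULT_MIN_UNTREATED_READS,
    gavage_timepoint: float = 0.0,
) -> ScreenTable:
    """Run the odds-ratio stage on every sample pair and assemble the
    screen table, deriving the design from the pairs themselves."""
    entries = {}
    mouse_tps: dict[str, tuple[str, set[float]]] = {}
    for pair in pairs:
        group, tps = mouse_tps.setdefault(pair.mouse_id, (pair.group, set()))
        tps.add(pair.timepoint)
        for r in evaluate_sample_pair(pair, reference, null, min_untreated_reads):
            entries[(r.trigger_id, pair.mouse_id, pair.timepoint)] = r
    design = [
        MouseDesign(mouse, group, tuple(sorted(tps)))
        for mouse, (group, tps) in sorted(mouse_tps.items())
    ]
    return ScreenTable(entries, design, gavage_timepoint=gavage_timepoint)


def results_to_frame(table: ScreenTable) -> pd.DataFrame:
    """Long-format results table; UNDEFINED values serialize as NA."""
    rows = []
    for (tid, mouse, tp), r in sorted(table.entries.items()):
        t = r.table
        rows.append(
            (
                f"{mouse}_t{tp:g}",
                mouse,
                table.group_of(mouse),
                tp,
                tid,
                t.a,
                t.b,
                t.c,
                t.d,
                r.odds_ratio if r.odds_ratio is not UNDEFINED else None,
                r.p_value if r.p_value is not UNDEFINED else None,
                r.status.value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "mouse_id",
            "group",
            "timepoint",
            "trigger_id",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p_value",
            "status",
        ],
    )


def screen_table_from_frames(
    results: pd.DataFrame,
    design: Optional[pd.DataFrame] = None,
    gavage_timepoint: float = 0.0,
) -> ScreenTable:
    """Rebuild a :class:`ScreenTable` from a results frame (as written by
    :func:`results_to_frame` / the ``htms stats`` command) plus an optional
    design frame with columns mouse_id, group, timepoint."""
    entries = {}
    for row in results.itertuples(index=False):
        or_ = None if pd.isna(row.odds_ratio) else float(row.odds_ratio)
        p = None if pd.isna(row.p_value) else float(row.p_value)
        entries[(row.trigger_id, str(row.mouse_id), float(row.timepoint))] = ORResult(
            trigger_id=row.trigger_id,
            odds_ratio=or_,
            p_value=p,
            status=Status(row.status),
            table=ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d)),
        )
    if design is None:
        design = results[["mouse_id", "group", "timepoint"]].drop_duplicates()
    mice = []
    for mouse, sub in design.groupby("mouse_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"mouse {mouse!r} assigned to multiple groups: {groups}")
        mice.append(
            MouseDesign(str(mouse), str(groups[0]), tuple(sorted(sub["timepoint"].astype(float))))
        )
    return ScreenTable(entries, mice, gavage_timepoint=gavage_timepoint)
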