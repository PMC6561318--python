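"""Screen-level aggregation: hit calls, rankings, responder classes, ROC.

A screen is a grid of odds-ratio results indexed by trigger x mouse x
time point, with a designated gavage time point (t = 0, the administered
library suspension) serving as the pre-exposure baseline.  This module
turns per-cell results into:

* hit calls — the conjunctive criterion OR >= 0.02 and p < 0.05;
* per-trigger summaries — percentage of positive time points, pooled over
  evaluable (VALID) mouse x time-point cells;
* in-vivo-responder classification — off at gavage (OR < 0.02), on at
  >= 1 fecal time point;
* group-differential scores — positive fraction in the treated (e.g. DSS
  colitis) group minus the control group;
* ROC calibration of the odds-ratio cutoff against plate-derived memory
  state labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from htms.odds_ratio import NullSpec, ORResult, Status

__all__ = [
    "NOT_EVALUABLE",
    "MouseDesign",
    "ScreenTable",
    "TriggerSummary",
    "ROCResult",
    "call_hit",
    "summarize_trigger",
    "classify_in_vivo_responder",
    "differential_response",
    "rank_differential",
    "roc_calibrate",
    "render_heatmap_table",
    "summaries_frame",
]


class _NotEvaluable:
    """Sentinel for a quantity that cannot be evaluated (e.g. a hit call on
    an INSUFFICIENT_COVERAGE cell — a blank in the heat map)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_EVALUABLE"

    def __bool__(self) -> bool:
        raise TypeError("NOT_EVALUABLE has no truth value; compare with 'is'")


NOT_EVALUABLE = _NotEvaluable()


@dataclass(frozen=True)
class MouseDesign:
    mouse_id: str
    group: str  # "control" or "treated"
    timepoints: tuple[float, ...]


@dataclass
class ScreenTable:
    """All ORResults of one screen plus its experimental design.

    ``entries`` maps (trigger_id, mouse_id, timepoint) to an
    :class:`~htms.odds_ratio.ORResult`; ``design`` lists each mouse with its
    group and time points.  ``gavage_timepoint`` flags the baseline sample
    (default 0.0); gavage cells are excluded from positive-time-point
    fractions but required for responder classification.
    """

    entries: dict[tuple[str, str, float], ORResult]
    design: list[MouseDesign]
    gavage_timepoint: float = 0.0

    def __post_init__(self) -> None:
        designed = {
            (m.mouse_id, tp) for m in self.design for tp in m.timepoints
        }
        for (_, mouse, tp) in self.entries:
            if (mouse, tp) not in designed:
                raise ValueError(
                    f"entry for mouse {mouse!r} at timepoint {tp} not in design"
                )

    @property
    def trigger_ids(self) -> list[str]:
        return sorted({t for (t, _, _) in self.entries})

    def group_of(self, mouse_id: str) -> str:
        for m in self.design:
            if m.mouse_id == mouse_id:
                return m.group
        raise KeyError(mouse_id)

    def cells(
        self,
        trigger_id: str,
        group: Optional[str] = None,
        post_gavage: bool = True,
    ) -> list[ORResult]:
        """Results for one trigger, optionally restricted to one group and
        (by default) to post-gavage time points."""
        out = []
        for (t, mouse, tp), r in self.entries.items():
            if t != trigger_id:
                continue
            if post_gavage and tp == self.gavage_timepoint:
                continue
            if group is not None and self.group_of(mouse) != group:
                continue
            out.append(r)
        return out

    def gavage_cells(self, trigger_id: str) -> list[ORResult]:
        return [
            r
            for (t, _, tp), r in self.entries.items()
            if t == trigger_id and tp == self.gavage_timepoint
        ]


@dataclass
class TriggerSummary:
    """Pooled positive-time-point statistics for one trigger.

    ``n_evaluable`` counts only VALID mouse x time-point cells after gavage;
    blank (insufficient-coverage) cells enter neither numerator nor
    denominator.  ``fraction_positive`` is None when nothing is evaluable.
    """

    trigger_id: str
    n_positive: int
    n_evaluable: int
    fraction_positive: Optional[float]
    n_mice_positive: int
    is_in_vivo_responder: bool
    mean_or: Optional[float] = None


@dataclass
class ROCResult:
    """Threshold sweep of the odds-ratio cutoff against truth labels."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    labels: dict[str, bool]
    youden_threshold: float = float("nan")


def call_hit(r: ORResult, null: NullSpec = NullSpec()):
    """True iff the cell is VALID with OR >= or_cutoff (inclusive) and
    p < alpha (strict); :data:`NOT_EVALUABLE` for any non-VALID cell."""
    if r.status is not Status.VALID:
        return NOT_EVALUABLE
    return r.odds_ratio >= null.or_cutoff and r.p_value < null.alpha


def _positive_counts(cells: Sequence[ORResult], null: NullSpec) -> tuple[int, int]:
    n_pos = 0
    n_eval = 0
    for r in cells:
        h = call_hit(r, null)
        if h is NOT_EVALUABLE:
            continue
        n_eval += 1
        n_pos += bool(h)
    return n_pos, n_eval


def summarize_trigger(
    table: ScreenTable, trigger_id: str, null: NullSpec = NullSpec()
) -> TriggerSummary:
    """Percentage-of-positive-time-points summary for one trigger, pooled
    over all mice's evaluable post-gavage cells."""
    cells = table.cells(trigger_id)
    if not cells and not table.gavage_cells(trigger_id):
        raise KeyError(f"trigger {trigger_id!r} not present in screen table")
    n_pos, n_eval = _positive_counts(cells, null)
    # mice with at least one positive time point
    mice_pos = set()
    for (t, mouse, tp), r in table.entries.items():
        if t != trigger_id or tp == table.gavage_timepoint:
            continue
        if call_hit(r, null) is True:
            mice_pos.add(mouse)
    valid_ors = [r.odds_ratio for r in cells if r.status is Status.VALID]
    responder = classify_in_vivo_responder(table, trigger_id, null)
    return TriggerSummary(
        trigger_id=trigger_id,
        n_positive=n_pos,
        n_evaluable=n_eval,
        fraction_positive=(n_pos / n_eval) if n_eval else None,
        n_mice_positive=len(mice_pos),
        is_in_vivo_responder=(responder is True),
        mean_or=float(np.mean(valid_ors)) if valid_ors else None,
    )


def classify_in_vivo_responder(
    table: ScreenTable, trigger_id: str, null: NullSpec = NullSpec()
):
    """True iff the trigger was off in the administered suspension and fired
    in the gut: every VALID gavage cell has OR < or_cutoff, and >= 1
    post-gavage cell is a hit.  :data:`NOT_EVALUABLE` when no gavage cell is
    VALID (the baseline state is unknown)."""
    gavage = [r for r in table.gavage_cells(trigger_id) if r.status is Status.VALID]
    if not gavage:
        return NOT_EVALUABLE
    if any(r.odds_ratio >= null.or_cutoff for r in gavage):
        return False
    return any(call_hit(r, null) is True for r in table.cells(trigger_id))


def differential_response(
    table: ScreenTable, trigger_id: str, null: NullSpec = NullSpec()
):
    """fraction_positive(treated) - fraction_positive(control), each pooled
    over that group's evaluable post-gavage cells; in [-1, 1].
    :data:`NOT_EVALUABLE` when either group has nothing evaluable."""
    fractions = {}
    for group in ("treated", "control"):
        n_pos, n_eval = _positive_counts(table.cells(trigger_id, group=group), null)
        if n_eval == 0:
            return NOT_EVALUABLE
        fractions[group] = n_pos / n_eval
    return fractions["treated"] - fractions["control"]


def rank_differential(
    table: ScreenTable, null: NullSpec = NullSpec()
) -> pd.DataFrame:
    """All triggers sorted by decreasing group difference (ties broken by
    trigger id); non-evaluable triggers are omitted."""
    rows = []
    for tid in table.trigger_ids:
        d = differential_response(table, tid, null)
        if d is NOT_EVALUABLE:
            continue
        rows.append((tid, d))
    df = pd.DataFrame(rows, columns=["trigger_id", "differential"])
    return df.sort_values(
        ["differential", "trigger_id"], ascending=[False, True]
    ).reset_index(drop=True)


def summaries_frame(
    table: ScreenTable, null: NullSpec = NullSpec()
) -> pd.DataFrame:
    """Per-trigger summaries as a DataFrame, ranked by fraction_positive
    (descending; ties by mean OR then id).  Triggers with nothing evaluable
    sort last."""
    rows = []
    for tid in table.trigger_ids:
        s = summarize_trigger(table, tid, null)
        rows.append(
            (
                s.trigger_id,
                s.n_positive,
                s.n_evaluable,
                s.fraction_positive,
                s.n_mice_positive,
                s.is_in_vivo_responder,
                s.mean_or,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "trigger_id",
            "n_positive",
            "n_evaluable",
            "fraction_positive",
            "n_mice_positive",
            "is_in_vivo_responder",
            "mean_or",
        ],
    )
    df["_frac"] = df["fraction_positive"].fillna(-1.0)
    df["_mor"] = df["mean_or"].fillna(-1.0)
    df = (
        df.sort_values(
            ["_frac", "_mor", "trigger_id"], ascending=[False, False, True]
        )
        .drop(columns=["_frac", "_mor"])
        .reset_index(drop=True)
    )
    return df


# ---------------------------------------------------------------------------
# ROC calibration against plate-derived memory state
# ---------------------------------------------------------------------------


def roc_calibrate(
    or_values: Mapping[str, float], labels: Mapping[str, bool]
) -> ROCResult:
    """ROC curve for the odds-ratio cutoff as a memory-state classifier.

    ``labels`` give the plate-assessed memory state (True = on) per trigger;
    every labeled trigger must have a defined OR and both classes must be
    present.  A trigger is called on at threshold t iff OR >= t; thresholds
    sweep {-inf} + sorted unique ORs + {+inf}, so the empirical 0.02 cutoff
    always lies on (or between points of) the curve.  AUC is the trapezoid
    integral over (FPR, TPR); the Youden-J-optimal threshold is reported
    because the field's cutoff was itself picked from such a sweep.
    """
    missing = [t for t in labels if t not in or_values]
    if missing:
        raise ValueError(f"no odds ratio for labeled triggers: {missing[:5]}")
    ids = sorted(labels)
    y = np.array([labels[t] for t in ids], dtype=bool)
    x = np.array([or_values[t] for t in ids], dtype=float)
    if not (y.any() and (~y).any()):
        raise ValueError("ROC requires at least one on and one off label")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    thresholds = np.concatenate([[-np.inf], np.unique(x), [np.inf]])
    tpr = np.array([(x[y] >= t).mean() for t in thresholds])
    fpr = np.array([(x[~y] >= t).mean() for t in thresholds])
    # sweep runs from threshold -inf (TPR=FPR=1) down to +inf (0, 0);
    # integrate in increasing (FPR, TPR) order so ties don't fold the curve
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = tpr - fpr
    best = int(np.argmax(j))
    finite = np.isfinite(thresholds)
    if not np.isfinite(thresholds[best]):
        # degenerate: all-on or threshold beyond data; fall back to best finite
        best = int(np.argmax(np.where(finite, j, -np.inf)))
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        labels=dict(labels),
        youden_threshold=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# Heat-map style export
# ---------------------------------------------------------------------------


def render_heatmap_table(
    table: ScreenTable,
    null: NullSpec = NullSpec(),
    top_k: Optional[int] = None,
) -> pd.DataFrame:
    """Odds-ratio matrix of the top triggers, one column per mouse x
    time point (gavage first), blanks (empty string) for non-evaluable
    cells.  Rows are ordered by fraction_positive with deterministic
    tie-breaks (mean OR, then id); re-running on identical input yields a
    byte-identical TSV.
    """
    ranked = summaries_frame(table, null)
    triggers = list(ranked["trigger_id"])
    if top_k is not None:
        triggers = triggers[:top_k]
    columns = []
    for m in table.design:
        for tp in sorted(m.timepoints):
            columns.append((m.mouse_id, tp))
    data = {}
    for mouse, tp in columns:
        col = []
        for tid in triggers:
            r = table.entries.get((tid, mouse, tp))
            if r is None or r.status is not Status.VALID:
                col.append("")
            else:
                col.append(f"{r.odds_ratio:.6g}")
        data[f"{mouse}_t{tp:g}"] = col
    out = pd.DataFrame(data, index=pd.Index(triggers, name="trigger_id"))
    return out


def plot_heatmap(
    table: ScreenTable,
    path,
    null: NullSpec = NullSpec(),
    top_k: int = 10,
) -> None:
    """PNG odds-ratio heat map of the top triggers (log color scale, gray
    for blanks)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = render_heatmap_table(table, null, top_k=top_k)
    vals = df.replace("", np.nan).astype(float)
    fig, ax = plt.subplots(
        figsize=(0.35 * len(df.columns) + 2, 0.35 * len(df) + 1.5)
    )
    masked = np.ma.masked_invalid(np.log10(vals.to_numpy() + 1e-6))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df)), df.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log10 odds ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(result: ROCResult, path) -> None:
    """PNG ROC curve with the AUC and Youden-optimal cutoff annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.lexsort((result.tpr, result.fpr))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.fpr[order], result.tpr[order], marker=".", lw=1)
    ax.plot([0, 1], [0, 1], ls="--", c="0.6", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(
        f"AUC = {result.auc:.3f}; cutoff = {result.youden_threshold:.3g}",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
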