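"""Calibration experiments run on the simulator.

These are the package's own validation studies: the false-positive rate of
the hit criterion under a true odds ratio equal to the null boundary, the
accuracy of odds-ratio recovery across memory-on fractions, end-to-end
recovery of planted responders from a full simulated screen, and ROC
calibration against known memory states.  Both the test suite and the
reproduction script run these; problem sizes are chosen so each completes
in seconds to a few minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from htms.odds_ratio import ContingencyTable, NullSpec, Status, compute_odds_ratio
from htms.pipeline import evaluate_screen
from htms.screen_analysis import (
    NOT_EVALUABLE,
    call_hit,
    classify_in_vivo_responder,
    rank_differential,
    roc_calibrate,
)
from htms.synthetic_screen import (
    ResponderSpec,
    SimConfig,
    default_config,
    simulate_screen,
    simulate_selection,
    simulate_sequencing,
)

__all__ = [
    "null_hit_rate",
    "or_recovery_medians",
    "ScreenRecovery",
    "end_to_end_recovery",
    "in_vitro_roc",
]


def null_hit_rate(
    seed: int,
    n_trigger_samples: int = 10_000,
    n_triggers: int = 20,
    depth: int = 20_000,
    null: NullSpec = NullSpec(),
) -> tuple[float, int]:
    """Hit-call rate when every strain's true memory-on fraction equals the
    null boundary (OR = psi0 exactly, by the no-escape cancellation).

    Returns (rate, number of evaluable trigger-samples).  The exact
    conditional test is conservative, so the rate should not exceed alpha
    beyond Monte-Carlo noise.
    """
    n_pairs = int(np.ceil(n_trigger_samples / n_triggers))
    n_mice = max(n_pairs // 2, 1)  # one fecal timepoint + gavage per mouse
    cfg = SimConfig(
        n_triggers=n_triggers,
        responder_spec=[
            ResponderSpec(t, "always_on", null.psi0)
            for t in SimConfig(n_triggers=n_triggers).trigger_ids
        ],
        dropout_per_transit=0.0,
        depth_untreated=depth,
        depth_selected=depth,
        n_mice=(n_mice + 1) // 2,
        timepoints=(1.0,),
        seed=seed,
    )
    res = simulate_screen(cfg)
    n_hits = 0
    n_eval = 0
    table = evaluate_screen(res.pairs, res.reference, null)
    for r in table.entries.values():
        h = call_hit(r, null)
        if h is NOT_EVALUABLE:
            continue
        n_eval += 1
        n_hits += bool(h)
        if n_eval >= n_trigger_samples:
            break
    return n_hits / n_eval, n_eval


def or_recovery_medians(
    seed: int,
    on_fractions: Sequence[float] = (0.05, 0.5, 0.9),
    depth: int = 1_000_000,
    n_reps: int = 200,
) -> dict[float, float]:
    """Median pipeline odds ratio per planted memory-on fraction.

    One trigger strain (abundance 0.7), one always-off filler (0.299) and
    the PNS spike (0.001) are selected and sequenced at the given depth;
    the trigger's OR is computed from the sampled counts exactly as the
    pipeline would.  With zero escape the estimand is the on-fraction
    itself.
    """
    rng = np.random.default_rng(seed)
    abundances = np.array([0.7, 0.299, 0.001])
    medians = {}
    for f in on_fractions:
        on = np.array([f, 0.0, 1.0])
        selected = simulate_selection(abundances, on, 0.93, 0.0)
        ors = []
        for _ in range(n_reps):
            u = simulate_sequencing(abundances, depth, rng)
            s = simulate_sequencing(selected, depth, rng)
            ors.append(
                compute_odds_ratio(
                    ContingencyTable(int(s[0]), int(s[2]), int(u[0]), int(u[2]))
                )
            )
        medians[f] = float(np.median(ors))
    return medians


@dataclass
class ScreenRecovery:
    """Outcome of the end-to-end planted-responder recovery experiment."""

    sensitivity: float
    specificity: float
    n_true_responders: int
    n_negatives: int
    disease_trigger_rank: int  # 1-based rank by differential response
    disease_trigger_id: str
    called_responders: list[str]


def end_to_end_recovery(seed: int, config: SimConfig | None = None) -> ScreenRecovery:
    """Simulate the default screen, run the full pipeline, and compare the
    responder calls and differential ranking with the planted truth."""
    cfg = default_config(seed=seed) if config is None else config
    res = simulate_screen(cfg)
    table = evaluate_screen(res.pairs, res.reference)
    truth_responders = {
        r.trigger_id
        for r in cfg.responder_spec
        if r.condition in ("in_vivo", "disease_only")
    }
    negatives = set(cfg.trigger_ids) - truth_responders
    called = {
        t
        for t in cfg.trigger_ids
        if classify_in_vivo_responder(table, t) is True
    }
    tp = len(called & truth_responders)
    fp = len(called & negatives)
    disease_ids = [
        r.trigger_id for r in cfg.responder_spec if r.condition == "disease_only"
    ]
    ranking = rank_differential(table)
    rank = (
        int(ranking.index[ranking["trigger_id"] == disease_ids[0]][0]) + 1
        if disease_ids
        else -1
    )
    return ScreenRecovery(
        sensitivity=tp / len(truth_responders),
        specificity=1.0 - fp / len(negatives),
        n_true_responders=len(truth_responders),
        n_negatives=len(negatives),
        disease_trigger_rank=rank,
        disease_trigger_id=disease_ids[0] if disease_ids else "",
        called_responders=sorted(called),
    )


def in_vitro_roc(
    seed: int,
    n_on: int = 22,
    n_off: int = 22,
    depth: int = 200_000,
) -> tuple[float, float]:
    """Pooled-growth ROC calibration against known memory states.

    Simulates one untreated/selected pair of a library whose strains are
    either firmly on (memory-on fractions 0.3-1.0) or firmly off, computes
    each strain's odds ratio, and sweeps the cutoff against the true
    states.  Returns (AUC, Youden-optimal cutoff).
    """
    rng = np.random.default_rng(seed)
    n = n_on + n_off
    ab = rng.dirichlet(np.full(n, 5.0)) * 0.999
    ab = np.concatenate([ab, [0.001]])
    f = np.concatenate(
        [rng.uniform(0.3, 1.0, size=n_on), np.zeros(n_off), [1.0]]
    )
    selected = simulate_selection(ab, f, 0.93, 0.0)
    u = simulate_sequencing(ab, depth, rng)
    s = simulate_sequencing(selected, depth, rng)
    ors = {}
    labels = {}
    for i in range(n):
        tid = f"strain_{i:03d}"
        ors[tid] = compute_odds_ratio(
            ContingencyTable(int(s[i]), int(s[-1]), int(u[i]), int(u[-1]))
        )
        labels[tid] = f[i] > 0
    res = roc_calibrate(ors, labels)
    return res.auc, res.youden_threshold
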