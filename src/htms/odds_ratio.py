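"""Spike-in-normalized odds ratios and the shifted-null Fisher exact test.

For each trigger x in a sample pair the 2x2 contingency table is

    ==============  ==========  ==========
    arm             trigger x   PNS
    ==============  ==========  ==========
    selected        a           b
    untreated       c           d
    ==============  ==========  ==========

and the odds ratio OR = (a/b)/(c/d) estimates the strain's memory-on
fraction: the PNS (positive normalization strain) is constitutively on, so
its selected:untreated ratio measures the selection's throughput, and
comparing each trigger only with itself between arms cancels per-trigger
amplification and length biases while the PNS normalization cancels depth
disparities between samples.

A trigger is only interesting if its memory-on fraction exceeds the
empirical on/off boundary OR = 0.02, so significance is assessed with a
one-tailed exact test of H0: OR = 0.02 against Ha: OR > 0.02.  Conditioning
on both table margins, the count a under H0: OR = psi follows Fisher's
noncentral hypergeometric distribution with noncentrality psi; the test is
the unique conditional exact generalization of Fisher's test to a non-unity
null and reduces to the classical one-sided test at psi = 1.  All pmf and
tail computations are done in log space so that read depths up to ~1e7 are
handled without overflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from htms.trigger_counts import SamplePairCounts, TriggerReference

__all__ = [
    "ContingencyTable",
    "ORResult",
    "NullSpec",
    "Status",
    "UNDEFINED",
    "compute_odds_ratio",
    "nchg_logpmf_support",
    "nchg_pmf",
    "fisher_test_greater",
    "evaluate_sample_pair",
    "apply_gavage_filter",
    "benjamini_hochberg",
]

#: Sentinel for an odds ratio or p-value that cannot be computed (serialized
#: as "NA" in result tables).  Distinct from an error: an undefined OR is a
#: legitimate outcome of zero PNS or zero untreated counts.
UNDEFINED = None

#: Default minimum untreated-arm reads for a trigger to be evaluable.
DEFAULT_MIN_UNTREATED_READS = 5
#: Default gavage-suspension read threshold (inclusive) below which a
#: trigger is discarded from the time course...
DEFAULT_MIN_GAVAGE_READS = 5
#: ...unless some later untreated sample exceeds this many reads (strict).
DEFAULT_RESCUE_READS = 20


class Status(enum.Enum):
    """Validity of one trigger's odds-ratio evaluation in one sample pair."""

    VALID = "VALID"
    INSUFFICIENT_COVERAGE = "INSUFFICIENT_COVERAGE"
    PNS_FAILURE = "PNS_FAILURE"


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 count table for one trigger in one sample pair.

    a = trigger reads, selected arm; b = PNS reads, selected arm;
    c = trigger reads, untreated arm; d = PNS reads, untreated arm.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be nonnegative")

    @property
    def m1(self) -> int:
        """Selected-arm margin a+b."""
        return self.a + self.b

    @property
    def n1(self) -> int:
        """Trigger margin a+c."""
        return self.a + self.c

    @property
    def N(self) -> int:
        """Grand total."""
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class NullSpec:
    """The shifted null and hit-calling thresholds.

    psi0 is the null odds ratio of the exact test; or_cutoff and alpha are
    the conjunctive hit criterion (OR >= or_cutoff and p < alpha) applied at
    hit calling.  The defaults encode the screen's empirical on/off boundary
    OR = 0.02 at the conventional 5% level.
    """

    psi0: float = 0.02
    alpha: float = 0.05
    or_cutoff: float = 0.02

    def __post_init__(self) -> None:
        if not self.psi0 > 0:
            raise ValueError("psi0 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.or_cutoff < 0:
            raise ValueError("or_cutoff must be nonnegative")


@dataclass
class ORResult:
    """Odds ratio, p-value and validity status for one trigger in one pair."""

    trigger_id: str
    odds_ratio: Optional[float]
    p_value: Optional[float]
    status: Status
    table: ContingencyTable

    def __post_init__(self) -> None:
        if self.status is Status.VALID:
            if self.odds_ratio is UNDEFINED or self.p_value is UNDEFINED:
                raise ValueError("VALID result requires defined odds_ratio and p_value")


def compute_odds_ratio(t: ContingencyTable) -> Optional[float]:
    """(a/b)/(c/d) = a*d / (b*c); no pseudocounts.

    Returns 0.0 when a = 0 (with b, c > 0) and :data:`UNDEFINED` when b = 0
    or c = 0 — a zero PNS count or zero untreated trigger count leaves the
    ratio without a denominator.
    """
    if t.b == 0 or t.c == 0:
        return UNDEFINED
    return (t.a * t.d) / (t.b * t.c)


# ---------------------------------------------------------------------------
# Fisher's noncentral hypergeometric distribution, log space
# ---------------------------------------------------------------------------


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def nchg_logpmf_support(
    m1: int, n1: int, N: int, psi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-pmf of Fisher's noncentral hypergeometric law.

    X is the count in cell (selected, trigger) of a 2x2 table with fixed
    margins: selected-arm total m1, trigger total n1, grand total N, and
    odds ratio (noncentrality) psi.  P(X=x) is proportional to
    C(n1, x) * C(N-n1, m1-x) * psi**x over the support
    max(0, m1+n1-N) <= x <= min(m1, n1), normalized by log-sum-exp.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    if not (0 <= m1 <= N and 0 <= n1 <= N):
        raise ValueError("margins must satisfy 0 <= m1, n1 <= N")
    lo = max(0, m1 + n1 - N)
    hi = min(m1, n1)
    x = np.arange(lo, hi + 1)
    logw = _log_binom(n1, x) + _log_binom(N - n1, m1 - x) + x * math.log(psi)
    return x, logw - logsumexp(logw)


def nchg_pmf(x: int, m1: int, n1: int, N: int, psi: float) -> float:
    """pmf of Fisher's noncentral hypergeometric distribution at x.

    Raises :class:`ValueError` when x lies outside the support.
    """
    support, logpmf = nchg_logpmf_support(m1, n1, N, psi)
    if x < support[0] or x > support[-1]:
        raise ValueError(
            f"x={x} outside support [{support[0]}, {support[-1]}] "
            f"for m1={m1}, n1={n1}, N={N}"
        )
    return float(np.exp(logpmf[x - support[0]]))


def fisher_test_greater(t: ContingencyTable, null: NullSpec = NullSpec()) -> float:
    """One-tailed exact p-value for Ha: OR > psi0, conditioning on margins.

    p = P(X >= a | margins, psi = psi0), summed in log space over the upper
    tail of the noncentral hypergeometric support.  Requires b > 0 and
    d > 0 (the PNS present in both arms); a failed PNS is a sample failure
    and is handled upstream as :attr:`Status.PNS_FAILURE`.
    """
    if t.b == 0 or t.d == 0:
        raise ValueError(
            "PNS reads are zero in one arm; the pair is a PNS failure and the "
            "test is not defined"
        )
    support, logpmf = nchg_logpmf_support(t.m1, t.n1, t.N, null.psi0)
    if t.a <= support[0]:  # whole support is >= a
        return 1.0
    tail = logpmf[support >= t.a]
    p = float(np.exp(logsumexp(tail)))
    return min(p, 1.0)


def evaluate_sample_pair(
    pair: SamplePairCounts,
    reference: TriggerReference,
    null: NullSpec = NullSpec(),
    min_untreated_reads: int = DEFAULT_MIN_UNTREATED_READS,
) -> list[ORResult]:
    """Odds ratio and p-value for every non-PNS trigger of one sample pair.

    Coverage rule: a trigger is evaluable only with >= ``min_untreated_reads``
    reads in the untreated arm (boundary inclusive); below that it gets
    :attr:`Status.INSUFFICIENT_COVERAGE` and no OR or p-value.  A zero PNS
    count in either arm marks every result :attr:`Status.PNS_FAILURE` — the
    PNS is a spiked control, so its absence signals a failed sample rather
    than any trigger's state.
    """
    pns = reference.pns_id
    b = pair.selected.counts.get(pns, 0)
    d = pair.untreated.counts.get(pns, 0)
    pns_failed = b == 0 or d == 0
    results = []
    for rec in reference.records:
        if rec.is_pns:
            continue
        tid = rec.trigger_id
        a = pair.selected.counts.get(tid, 0)
        c = pair.untreated.counts.get(tid, 0)
        table = ContingencyTable(a, b, c, d)
        if pns_failed:
            results.append(ORResult(tid, UNDEFINED, UNDEFINED, Status.PNS_FAILURE, table))
        elif c < min_untreated_reads:
            results.append(
                ORResult(tid, UNDEFINED, UNDEFINED, Status.INSUFFICIENT_COVERAGE, table)
            )
        else:
            or_ = compute_odds_ratio(table)
            p = fisher_test_greater(table, null)
            results.append(ORResult(tid, or_, p, Status.VALID, table))
    return results


def apply_gavage_filter(
    timecourse_counts: Mapping[str, Mapping[float, int]],
    gavage_timepoint: float = 0.0,
    min_gavage_reads: int = DEFAULT_MIN_GAVAGE_READS,
    rescue_reads: int = DEFAULT_RESCUE_READS,
) -> set[str]:
    """Retain triggers detectable in the administered library.

    ``timecourse_counts`` maps trigger id -> {timepoint: untreated reads},
    including the gavage suspension at ``gavage_timepoint``.  A trigger is
    retained iff its gavage count is >= ``min_gavage_reads`` (inclusive), or
    it registers strictly more than ``rescue_reads`` reads at any later
    time point — a strain absent at gavage but abundant later was evidently
    administered and merely under-sampled.
    """
    retained = set()
    for trigger_id, by_tp in timecourse_counts.items():
        if gavage_timepoint not in by_tp:
            raise ValueError(
                f"no gavage sample (timepoint {gavage_timepoint}) for trigger "
                f"{trigger_id!r}"
            )
        if by_tp[gavage_timepoint] >= min_gavage_reads:
            retained.add(trigger_id)
            continue
        if any(
            count > rescue_reads
            for tp, count in by_tp.items()
            if tp > gavage_timepoint
        ):
            retained.add(trigger_id)
    return retained


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in the
    pipeline, which applies the raw conjunctive hit criterion)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
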