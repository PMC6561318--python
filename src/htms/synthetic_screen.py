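"""Ground-truthed synthetic screens emulating the wet-lab protocol.

The generative model follows the experiment's structure step by step:

1. a library of trigger strains with random, seed-unique reference
   sequences and a gavage-suspension composition (Dirichlet or normalized
   lognormal abundances);
2. gut passage per mouse — per-strain Bernoulli dropout accumulating over
   transit days (defaults tuned so ~80-90% of strains survive a 5-7 day
   course) and day-to-day lognormal abundance jitter;
3. memory switching encoded directly as a per-condition memory-on fraction
   f for each strain (always_off, in_vivo, disease_only, always_on); at
   gavage (t = 0, before gut exposure) in_vivo and disease_only triggers
   are off;
4. the positive normalization strain (PNS) spiked in at 1:1,000 with
   on-fraction 1;
5. spectinomycin selection — a strain's selected weight is its abundance
   times (f * on_survival + (1 - f) * off_escape), with on_survival 0.93
   and off_escape 0 by default; the untreated half passes through
   unchanged, and post-selection overnight growth is modeled as
   composition-preserving;
6. sequencing as a single multinomial draw per arm at configurable depth,
   with optional per-trigger length-bias factors, and optionally explicit
   error-carrying reads in FASTQ form.

With zero escape the expected odds ratio of a strain equals its true
on-fraction — the selection survival cancels between strain and PNS — so
the truth table doubles as the analytic expectation for every pipeline
recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from htms.trigger_counts import (
    CountVector,
    SamplePairCounts,
    TriggerRecord,
    TriggerReference,
    write_count_table,
)

__all__ = [
    "ResponderSpec",
    "SimConfig",
    "SimResult",
    "default_config",
    "generate_reference",
    "library_composition",
    "simulate_composition",
    "simulate_selection",
    "simulate_sequencing",
    "simulate_reads",
    "simulate_screen",
]

Condition = Literal["always_off", "in_vivo", "disease_only", "always_on"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ResponderSpec:
    """Memory behaviour of one trigger strain.

    ``on_fraction`` is the strain's memory-on fraction whenever its
    condition is active: everywhere for ``always_on``; in the gut for
    ``in_vivo``; in the gut of treated (colitis-model) mice only for
    ``disease_only``.  ``always_off`` strains never switch.
    """

    trigger_id: str
    condition: Condition
    on_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError("on_fraction must be in [0, 1]")

    def on_fraction_for(self, group: str, in_gut: bool) -> float:
        if self.condition == "always_on":
            return self.on_fraction
        if self.condition == "always_off" or not in_gut:
            return 0.0
        if self.condition == "in_vivo":
            return self.on_fraction
        if self.condition == "disease_only":
            return self.on_fraction if group == "treated" else 0.0
        raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class SimConfig:
    """Full parameterization of one synthetic screen.

    Defaults encode the protocol's stated operating point: PNS spiked at
    1:1,000, spectinomycin recovering 93% of memory-on cells and 0% of
    memory-off cells, and per-day strain dropout of 3% so that 80-90% of
    the library survives a 5-7 day course.
    """

    n_triggers: int = 150
    trigger_len: int = 300
    responder_spec: list[ResponderSpec] = field(default_factory=list)
    abundance_distribution: Literal["dirichlet", "lognormal"] = "dirichlet"
    abundance_concentration: float = 5.0  # Dirichlet concentration per strain
    abundance_sigma: float = 1.0  # lognormal sigma (if lognormal)
    daily_jitter_sigma: float = 0.3  # day-to-day lognormal abundance jitter
    dropout_per_transit: float = 0.03  # per-strain, per-day loss probability
    pns_spike_fraction: float = 1.0 / 1000.0
    selection_on_survival: float = 0.93
    selection_off_escape: float = 0.0
    depth_untreated: int = 500_000
    depth_selected: int = 500_000
    read_len: int = 150
    seq_error_rate: float = 0.0
    n_mice: int = 3  # per group
    timepoints: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    gavage_timepoint: float = 0.0
    pns_id: str = "pns"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dropout_per_transit",
            "pns_spike_fraction",
            "selection_on_survival",
            "selection_off_escape",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_untreated <= 0 or self.depth_selected <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.n_triggers < 2:
            raise ValueError("need at least 2 triggers")

    @property
    def trigger_ids(self) -> list[str]:
        width = len(str(self.n_triggers))
        return [f"trig_{i + 1:0{width}d}" for i in range(self.n_triggers)]

    def responder_of(self, trigger_id: str) -> ResponderSpec:
        for r in self.responder_spec:
            if r.trigger_id == trigger_id:
                return r
        return ResponderSpec(trigger_id, "always_off", 0.0)


def default_config(seed: int = 0) -> SimConfig:
    """The default screen: 150 triggers, five in-vivo responders spanning
    on-fractions 0.1-0.8, and one disease-only responder (f = 0.5)."""
    cfg = SimConfig(seed=seed)
    ids = cfg.trigger_ids
    responders = [
        ResponderSpec(ids[9], "in_vivo", 0.10),
        ResponderSpec(ids[29], "in_vivo", 0.20),
        ResponderSpec(ids[49], "in_vivo", 0.30),
        ResponderSpec(ids[69], "in_vivo", 0.50),
        ResponderSpec(ids[89], "in_vivo", 0.80),
        ResponderSpec(ids[109], "disease_only", 0.50),
    ]
    return replace(cfg, responder_spec=responders)


@dataclass
class SimResult:
    """Everything a simulated screen emits: sample pairs, the design and
    ground-truth tables, and the trigger reference."""

    pairs: list[SamplePairCounts]
    design: pd.DataFrame  # mouse_id group timepoint pair_id
    truth: pd.DataFrame  # trigger_id mouse_id timepoint true_abundance true_on_fraction expected_or
    reference: TriggerReference
    config: SimConfig

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_count_table(self.pairs, out / "counts.tsv")
        self.design.to_csv(out / "design.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.reference.to_fasta(out / "ref.fa")


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    unique_k: int = 30,
    max_tries: int = 50,
) -> TriggerReference:
    """Random trigger sequences whose ``unique_k``-mers are pairwise
    disjoint (rejection sampling), so error-free reads of >= unique_k nt
    always assign uniquely.  Deterministic under the config seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = config.trigger_ids + [config.pns_id]
    seen: set[str] = set()
    records = []
    for tid in ids:
        for attempt in range(max_tries):
            seq = "".join(rng.choice(_BASES, size=config.trigger_len))
            kmers = {
                seq[i : i + unique_k] for i in range(len(seq) - unique_k + 1)
            }
            if not (kmers & seen):
                seen |= kmers
                records.append(TriggerRecord(tid, seq, is_pns=(tid == config.pns_id)))
                break
        else:
            raise RuntimeError(
                f"could not generate a {unique_k}-mer-unique sequence for "
                f"{tid!r} in {max_tries} tries"
            )
    return TriggerReference(records)


# ---------------------------------------------------------------------------
# Composition, selection, sequencing
# ---------------------------------------------------------------------------


def library_composition(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Gavage-suspension strain abundances (non-PNS), summing to 1."""
    n = config.n_triggers
    if config.abundance_distribution == "dirichlet":
        ab = rng.dirichlet(np.full(n, config.abundance_concentration))
    elif config.abundance_distribution == "lognormal":
        ab = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
        ab = ab / ab.sum()
    else:
        raise ValueError(f"unknown abundance model {config.abundance_distribution!r}")
    return ab


def _on_fractions(config: SimConfig, group: str, in_gut: bool) -> np.ndarray:
    return np.array(
        [
            config.responder_of(t).on_fraction_for(group, in_gut)
            for t in config.trigger_ids
        ]
    )


def simulate_composition(
    config: SimConfig,
    group: str,
    timepoint: float,
    rng: np.random.Generator,
    base_abundances: np.ndarray,
    present: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One sample's full composition and on-fractions, PNS last.

    ``base_abundances`` is the mouse's current library composition (after
    any dropout already applied via ``present``); the gavage time point
    uses the suspension directly with no jitter.  The PNS is appended at
    ``pns_spike_fraction`` with on-fraction 1, mirroring the spike-in
    happening at sample processing rather than in the gut.
    """
    in_gut = timepoint != config.gavage_timepoint
    ab = np.asarray(base_abundances, dtype=float).copy()
    if present is not None:
        ab = ab * present
    if in_gut and config.daily_jitter_sigma > 0:
        ab = ab * rng.lognormal(0.0, config.daily_jitter_sigma, size=ab.size)
    total = ab.sum()
    if total <= 0:
        raise RuntimeError(
            f"degenerate sample: every strain dropped out (group={group}, "
            f"timepoint={timepoint})"
        )
    ab = ab / total
    spike = config.pns_spike_fraction
    full_ab = np.concatenate([ab * (1.0 - spike), [spike]])
    full_on = np.concatenate([_on_fractions(config, group, in_gut), [1.0]])
    return full_ab, full_on


def simulate_selection(
    abundances: np.ndarray,
    on_fractions: np.ndarray,
    on_survival: float = 0.93,
    off_escape: float = 0.0,
) -> np.ndarray:
    """Composition after spectinomycin selection.

    Each strain's selected weight is abundance * (f * on_survival +
    (1 - f) * off_escape), renormalized.  With all strains fully on the
    survival factor cancels and the composition is unchanged.
    """
    ab = np.asarray(abundances, dtype=float)
    f = np.asarray(on_fractions, dtype=float)
    w = ab * (f * on_survival + (1.0 - f) * off_escape)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("degenerate selection: no memory-on cells anywhere")
    return w / total


def simulate_sequencing(
    composition: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    length_bias: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Multinomial read counts at the given depth.

    ``length_bias`` multiplies per-strain sampling weights (renormalized) to
    emulate amplicon-length effects; applied to both arms it cancels in the
    odds ratio.
    """
    comp = np.asarray(composition, dtype=float)
    if length_bias is not None:
        comp = comp * np.asarray(length_bias, dtype=float)
        comp = comp / comp.sum()
    if depth == 0:
        return np.zeros(comp.size, dtype=int)
    return rng.multinomial(depth, comp)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    counts: CountVector,
    reference: TriggerReference,
    read_len: int,
    seq_error_rate: float,
    rng: np.random.Generator,
    path: Union[str, Path],
) -> None:
    """Write a FASTQ realizing a count vector as uniform-start substrings.

    Each counted read is drawn from a uniform start on a uniform strand of
    its trigger, with iid substitution errors at ``seq_error_rate`` and a
    constant quality string.  Error-free reads re-counted by
    :func:`htms.trigger_counts.count_reads` reproduce ``counts`` exactly.
    """
    qual = "I" * read_len
    with open(path, "w") as fh:
        read_i = 0
        for tid in sorted(counts.counts):
            n = counts.counts[tid]
            if n == 0:
                continue
            seq = reference[tid].sequence
            if read_len > len(seq):
                raise ValueError(
                    f"read_len {read_len} exceeds trigger length {len(seq)}"
                )
            starts = rng.integers(0, len(seq) - read_len + 1, size=n)
            strands = rng.integers(0, 2, size=n)
            for s, rc in zip(starts, strands):
                read = seq[s : s + read_len]
                if rc:
                    read = read.translate(_COMPLEMENT)[::-1]
                if seq_error_rate > 0:
                    arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
                    errs = np.nonzero(rng.random(read_len) < seq_error_rate)[0]
                    for e in errs:
                        choices = [b for b in "ACGT" if b != arr[e]]
                        arr[e] = choices[rng.integers(0, len(choices))]
                    read = "".join(arr)
                fh.write(f"@{counts.sample_id}_{tid}_{read_i}\n{read}\n+\n{qual}\n")
                read_i += 1


# ---------------------------------------------------------------------------
# Whole-screen simulation
# ---------------------------------------------------------------------------


def simulate_screen(
    config: SimConfig,
    out_dir: Optional[Union[str, Path]] = None,
    emit_fastq: bool = False,
    length_bias: Optional[np.ndarray] = None,
) -> SimResult:
    """Simulate a full screen: control and treated mice, a gavage baseline
    per mouse (independent sequencing of the shared suspension), and the
    configured fecal time points; fully reproducible under ``config.seed``.

    Returns a :class:`SimResult`; with ``out_dir`` the count, design and
    truth TSVs plus the reference FASTA (and optional per-sample FASTQs)
    are written there.
    """
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    suspension = library_composition(config, rng)
    mice = [("control", f"control_{i + 1}") for i in range(config.n_mice)] + [
        ("treated", f"treated_{i + 1}") for i in range(config.n_mice)
    ]
    all_tps = [config.gavage_timepoint] + sorted(config.timepoints)
    pairs: list[SamplePairCounts] = []
    design_rows = []
    truth_rows = []
    ids_full = config.trigger_ids + [config.pns_id]
    fastq_dir = Path(out_dir) / "fastq" if (out_dir and emit_fastq) else None
    if fastq_dir:
        fastq_dir.mkdir(parents=True, exist_ok=True)
    for group, mouse in mice:
        present = np.ones(config.n_triggers, dtype=bool)
        prev_tp = config.gavage_timepoint
        for tp in all_tps:
            if tp != config.gavage_timepoint:
                # per-day Bernoulli survival over the transit interval
                n_days = int(round(tp - prev_tp))
                for _ in range(max(n_days, 0)):
                    present &= rng.random(config.n_triggers) >= config.dropout_per_transit
                prev_tp = tp
            full_ab, full_on = simulate_composition(
                config, group, tp, rng, suspension,
                present=None if tp == config.gavage_timepoint else present,
            )
            selected_comp = simulate_selection(
                full_ab,
                full_on,
                config.selection_on_survival,
                config.selection_off_escape,
            )
            pair_id = f"{mouse}_t{tp:g}"
            u_counts = simulate_sequencing(
                full_ab, config.depth_untreated, rng, length_bias
            )
            s_counts = simulate_sequencing(
                selected_comp, config.depth_selected, rng, length_bias
            )
            untreated = CountVector(
                f"{pair_id}_untreated", dict(zip(ids_full, map(int, u_counts)))
            )
            selected = CountVector(
                f"{pair_id}_selected", dict(zip(ids_full, map(int, s_counts)))
            )
            pairs.append(
                SamplePairCounts(pair_id, mouse, group, tp, untreated, selected)
            )
            design_rows.append((mouse, group, tp, pair_id))
            s = config.selection_on_survival
            e = config.selection_off_escape
            for i, tid in enumerate(config.trigger_ids):
                f = full_on[i]
                expected_or = f + (1.0 - f) * e / s if s > 0 else float("nan")
                truth_rows.append(
                    (tid, mouse, tp, full_ab[i], f, expected_or)
                )
            if fastq_dir:
                for arm, vec in (("untreated", untreated), ("selected", selected)):
                    simulate_reads(
                        vec,
                        reference,
                        config.read_len,
                        config.seq_error_rate,
                        rng,
                        fastq_dir / f"{pair_id}_{arm}.fastq",
                    )
    design = pd.DataFrame(
        design_rows, columns=["mouse_id", "group", "timepoint", "pair_id"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "trigger_id",
            "mouse_id",
            "timepoint",
            "true_abundance",
            "true_on_fraction",
            "expected_or",
        ],
    )
    result = SimResult(pairs, design, truth, reference, config)
    if out_dir is not None:
        result.write(out_dir)
    return result
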