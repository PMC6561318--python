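"""Trigger references, read assignment, and per-sample count tables.

The screen's sequencing unit is an amplicon read covering (part of) a
trigger region.  This module loads the trigger reference (one FASTA record
per library strain, including the spiked-in positive normalization strain),
assigns reads to triggers by unique best exact-seed containment on either
strand, and reads/writes the pipeline's canonical tab-separated count
tables.  Counting only uniquely assigned reads mirrors the screen's
analysis convention: ambiguous and unmapped reads are tallied but excluded
from every downstream statistic.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AMBIGUOUS",
    "UNMAPPED",
    "TriggerReference",
    "CountVector",
    "SamplePairCounts",
    "load_trigger_reference",
    "assign_read",
    "count_reads",
    "read_count_table",
    "write_count_table",
]

#: Sentinel returned for reads matching two or more triggers equally well.
AMBIGUOUS = "AMBIGUOUS"
#: Sentinel returned for reads with no qualifying match in any trigger.
UNMAPPED = "UNMAPPED"

_VALID_ALPHABET = set("ACGTN")

#: Default minimum exact-match seed length for unique assignment (nt).
DEFAULT_MIN_MATCH_LEN = 30


class ReferenceError(ValueError):
    """The trigger reference violates a structural invariant."""


class ConfigurationError(ValueError):
    """Screen configuration is inconsistent with the supplied data."""


class InputError(ValueError):
    """Malformed read or table input."""


@dataclass(frozen=True)
class TriggerRecord:
    trigger_id: str
    sequence: str
    is_pns: bool = False


@dataclass
class TriggerReference:
    """The named trigger sequences of one library, including the PNS.

    Invariants (enforced by :meth:`validate`, called on construction):
    trigger ids unique; exactly one record is the positive normalization
    strain; sequences nonempty, over {A,C,G,T,N}, and pairwise distinct
    (duplicate sequences would make reads unassignable by construction).
    """

    records: list[TriggerRecord]
    pns_id: str = field(init=False)

    def __post_init__(self) -> None:
        self.validate()
        self.pns_id = next(r.trigger_id for r in self.records if r.is_pns)

    def validate(self) -> None:
        if not self.records:
            raise ReferenceError("trigger reference is empty")
        ids = [r.trigger_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceError(f"duplicate trigger ids: {dupes}")
        n_pns = sum(r.is_pns for r in self.records)
        if n_pns != 1:
            raise ReferenceError(
                f"exactly one positive normalization strain required, found {n_pns}"
            )
        seqs: dict[str, str] = {}
        for r in self.records:
            if not r.sequence:
                raise ReferenceError(f"empty sequence for trigger {r.trigger_id!r}")
            bad = set(r.sequence) - _VALID_ALPHABET
            if bad:
                raise ReferenceError(
                    f"invalid characters {sorted(bad)} in trigger {r.trigger_id!r}"
                )
            if r.sequence in seqs:
                raise ReferenceError(
                    f"triggers {seqs[r.sequence]!r} and {r.trigger_id!r} share an "
                    "identical sequence; their reads can never be assigned uniquely"
                )
            seqs[r.sequence] = r.trigger_id

    @property
    def trigger_ids(self) -> list[str]:
        return [r.trigger_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, trigger_id: str) -> TriggerRecord:
        for r in self.records:
            if r.trigger_id == trigger_id:
                return r
        raise KeyError(trigger_id)

    def to_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.trigger_id}\n{r.sequence}\n")


@dataclass
class CountVector:
    """Uniquely-assigned read counts for one sequencing sample.

    ``total_assigned`` equals the sum of ``counts``; ambiguous and unmapped
    reads are recorded for bookkeeping but never enter a statistic.
    """

    sample_id: str
    counts: dict[str, int]
    total_assigned: int = -1
    n_ambiguous: int = 0
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.total_assigned < 0:
            self.total_assigned = total
        elif self.total_assigned != total:
            raise InputError(
                f"total_assigned={self.total_assigned} != sum of counts={total}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise InputError("negative read count")


@dataclass
class SamplePairCounts:
    """Counts for one sample's untreated and spectinomycin-selected halves.

    Each processed fecal/culture sample is split in two; one half is grown
    under spectinomycin so that only memory-on cells contribute reads.  The
    odds ratio for trigger x uses the four counts
    (untreated[x], selected[x], untreated[PNS], selected[PNS]).
    """

    pair_id: str
    mouse_id: str
    group: str  # "control" or "treated"
    timepoint: float
    untreated: CountVector
    selected: CountVector

    def __post_init__(self) -> None:
        if self.group not in ("control", "treated"):
            raise InputError(f"group must be 'control' or 'treated', got {self.group!r}")


def load_trigger_reference(path: Union[str, Path], pns_id: str) -> TriggerReference:
    """Load a trigger reference FASTA and designate the PNS record.

    Record ids are the FASTA header up to the first whitespace.  Raises
    :class:`ReferenceError` for an empty or structurally invalid file and
    :class:`ConfigurationError` when ``pns_id`` names no record.
    """
    records = []
    seen_pns = False
    for rec in SeqIO.parse(str(path), "fasta"):
        is_pns = rec.id == pns_id
        seen_pns = seen_pns or is_pns
        records.append(
            TriggerRecord(rec.id, str(rec.seq).upper(), is_pns=is_pns)
        )
    if not records:
        raise ReferenceError(f"no FASTA records in {path}")
    if not seen_pns:
        raise ConfigurationError(
            f"positive normalization strain {pns_id!r} not present in {path}"
        )
    return TriggerReference(records)


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------


class _SeedIndex:
    """k-mer index over both strands of every trigger, for seed-and-extend
    unique assignment.  Built lazily and cached on the reference object."""

    def __init__(self, reference: TriggerReference, k: int):
        self.k = k
        # kmer -> list of (record index, strand sequence, position)
        self.index: dict[str, list[tuple[int, str, int]]] = {}
        self.strands: list[list[str]] = []
        for i, rec in enumerate(reference.records):
            fwd = rec.sequence
            rev = str(Seq(fwd).reverse_complement())
            self.strands.append([fwd, rev])
            for seq in (fwd, rev):
                for pos in range(len(seq) - k + 1):
                    kmer = seq[pos : pos + k]
                    if "N" in kmer:
                        continue
                    self.index.setdefault(kmer, []).append((i, seq, pos))


def _get_seed_index(reference: TriggerReference, k: int) -> _SeedIndex:
    cache = getattr(reference, "_seed_index_cache", None)
    if cache is None or cache.k != k:
        cache = _SeedIndex(reference, k)
        reference._seed_index_cache = cache  # type: ignore[attr-defined]
    return cache


def assign_read(
    read_sequence: str,
    reference: TriggerReference,
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
) -> str:
    """Assign a read to the unique trigger with the longest exact match.

    For every trigger (both strands) the longest exact substring shared with
    the read is found by seed-and-extend with seed length ``min_match_len``.
    The read is assigned to the single trigger achieving the global maximum
    if that maximum is at least ``min_match_len``; ties return
    :data:`AMBIGUOUS` and no qualifying match returns :data:`UNMAPPED`.
    Deterministic for fixed inputs; seeds containing N never match, so bases
    flanked by N are only assignable through N-free seeds.
    """
    if not read_sequence:
        raise InputError("empty read")
    read = read_sequence.upper()
    k = min_match_len
    if len(read) < k:
        return UNMAPPED
    idx = _get_seed_index(reference, k)
    # best match length per trigger record index
    best: dict[int, int] = {}
    for i in range(len(read) - k + 1):
        seed = read[i : i + k]
        hits = idx.index.get(seed)
        if not hits:
            continue
        for rec_i, strand_seq, pos in hits:
            # extend the exact match left and right of the seed
            left = 0
            while i - left - 1 >= 0 and pos - left - 1 >= 0 and read[i - left - 1] == strand_seq[pos - left - 1]:
                left += 1
            right = 0
            while (
                i + k + right < len(read)
                and pos + k + right < len(strand_seq)
                and read[i + k + right] == strand_seq[pos + k + right]
            ):
                right += 1
            mlen = k + left + right
            if mlen > best.get(rec_i, 0):
                best[rec_i] = mlen
    if not best:
        return UNMAPPED
    top = max(best.values())
    winners = [rec_i for rec_i, m in best.items() if m == top]
    if len(winners) > 1:
        return AMBIGUOUS
    return reference.records[winners[0]].trigger_id


def count_reads(
    fastq_path: Union[str, Path],
    reference: TriggerReference,
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
    sample_id: str | None = None,
) -> CountVector:
    """Count uniquely assigned reads per trigger from a FASTQ file.

    Quality strings are ignored.  A malformed record raises
    :class:`InputError` naming the (0-based) record index.  The conservation
    invariant holds: total reads = assigned + ambiguous + unmapped.
    """
    counts = {t: 0 for t in reference.trigger_ids}
    n_ambiguous = 0
    n_unmapped = 0
    sample_id = sample_id if sample_id is not None else Path(fastq_path).stem
    with open(fastq_path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        i = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise InputError(f"malformed FASTQ record at index {i}: {exc}") from exc
            dest = assign_read(str(rec.seq), reference, min_match_len)
            if dest == AMBIGUOUS:
                n_ambiguous += 1
            elif dest == UNMAPPED:
                n_unmapped += 1
            else:
                counts[dest] += 1
            i += 1
    return CountVector(
        sample_id=sample_id,
        counts=counts,
        n_ambiguous=n_ambiguous,
        n_unmapped=n_unmapped,
    )


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["pair_id", "mouse_id", "group", "timepoint", "arm", "trigger_id", "count"]


def write_count_table(pairs: Iterable[SamplePairCounts], path: Union[str, Path]) -> None:
    """Write sample pairs to the canonical long-format count TSV."""
    rows = []
    for p in pairs:
        for arm_name, vec in (("untreated", p.untreated), ("selected", p.selected)):
            for trigger_id in sorted(vec.counts):
                rows.append(
                    (p.pair_id, p.mouse_id, p.group, p.timepoint, arm_name, trigger_id, vec.counts[trigger_id])
                )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: Union[str, Path]) -> list[SamplePairCounts]:
    """Read the canonical count TSV back into :class:`SamplePairCounts`.

    Round-trips exactly with :func:`write_count_table`.  A pair missing
    either arm, or any negative count, is an error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"count table missing columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0].iloc[0]
        raise InputError(
            f"negative count for trigger {bad['trigger_id']!r} in pair {bad['pair_id']!r}"
        )
    pairs = []
    for pair_id, sub in df.groupby("pair_id", sort=True):
        arms = {}
        for arm_name, arm_df in sub.groupby("arm"):
            arms[arm_name] = CountVector(
                sample_id=f"{pair_id}_{arm_name}",
                counts=dict(zip(arm_df["trigger_id"], arm_df["count"].astype(int))),
            )
        if set(arms) != {"untreated", "selected"}:
            raise InputError(
                f"pair {pair_id!r} must have exactly arms 'untreated' and 'selected', "
                f"found {sorted(arms)}"
            )
        meta = sub.iloc[0]
        pairs.append(
            SamplePairCounts(
                pair_id=str(pair_id),
                mouse_id=str(meta["mouse_id"]),
                group=str(meta["group"]),
                timepoint=float(meta["timepoint"]),
                untreated=arms["untreated"],
                selected=arms["selected"],
            )
        )
    return pairs
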