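import numpy as np
import pytest

from htms.trigger_counts import TriggerRecord, TriggerReference


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_reference() -> TriggerReference:
    """Three triggers (incl. the PNS) with disjoint 30-mer sets."""
    rng = np.random.default_rng(42)
    while True:
        seqs = [_random_seq(rng, 200) for _ in range(3)]
        kmer_sets = [
            {s[i : i + 30] for i in range(len(s) - 29)} for s in seqs
        ]
        if (
            not (kmer_sets[0] & kmer_sets[1])
            and not (kmer_sets[0] & kmer_sets[2])
            and not (kmer_sets[1] & kmer_sets[2])
        ):
            break
    return TriggerReference(
        [
            TriggerRecord("trigA", seqs[0]),
            TriggerRecord("trigB", seqs[1]),
            TriggerRecord("fabR_pns", seqs[2], is_pns=True),
        ]
    )
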