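# Methods

## The odds ratio and what it estimates

Each processed sample yields two sequencing libraries: an untreated half
and a spectinomycin-selected half in which only memory-on cells grow. With
the positive normalization strain (PNS) spiked into the sample at 1:1,000
before selection and constitutively memory-on, the counts for trigger *x*
form a 2×2 table

|            | trigger *x* | PNS |
|------------|-------------|-----|
| selected   | a           | b   |
| untreated  | c           | d   |

and OR = (a/b)/(c/d) = ad/bc. Write f for the strain's memory-on fraction,
s for the survival of memory-on cells through selection, and e for the
escape of memory-off cells. The expected selected:untreated enrichment of
the strain relative to the PNS is (f·s + (1−f)·e)/s, which is exactly f
when e = 0 — the survival factor cancels between strain and PNS. The same
cancellation removes any per-strain multiplicative factor applied to both
arms (amplicon length bias) and any per-arm depth factor. These two exact
invariances are property-tested.

Zero-count policy: a = 0 gives OR = 0 (no pseudocounts); b = 0 or c = 0
leaves the OR undefined. A zero PNS count in either arm (b = 0 or d = 0)
invalidates the entire sample pair (`PNS_FAILURE`) rather than a single
trigger, because the PNS is a spiked control whose absence signals a failed
sample, not a trigger state.

## The shifted-null exact test

The on/off boundary sits at OR ≈ 0.02, so the hypothesis of interest is
H₀: OR = 0.02 vs Hₐ: OR > 0.02, not the classical OR = 1. Conditioning on
both margins of the table, the count a under H₀: OR = ψ follows Fisher's
noncentral hypergeometric distribution,

P(X = x) ∝ C(n₁, x) · C(N−n₁, m₁−x) · ψˣ

over max(0, m₁+n₁−N) ≤ x ≤ min(m₁, n₁), with m₁ = a+b, n₁ = a+c,
N = a+b+c+d. This is the unique conditional exact test generalizing
Fisher's test to a non-unity null; at ψ = 1 it reduces to the classical
one-sided test, which is verified exhaustively against the central
hypergeometric for all margins N ≤ 60 and against `scipy.stats.fisher_exact`
on random tables. The one-tailed p-value is P(X ≥ a), computed entirely in
log space (log-gamma weights, log-sum-exp normalization) so tables with
margins up to ~10⁷ neither overflow nor lose the extreme tail —
double-precision survival functions underflow around p ≈ 1e-308, and real
screen tables routinely produce p-values far smaller. Agreement with an
independent scalar enumeration oracle is required to a relative 1e-9 at
screen-scale margins.

The test is exact for independent binomial rows with a common odds ratio;
multinomial sequencing counts conditioned on per-arm trigger+PNS totals
satisfy this. Because the statistic is discrete the test is conservative;
the simulated type-I error at the boundary runs at ~3–4% for nominal 5%.

## Filters and hit calling

* Per sample pair, a trigger is evaluable only with ≥ 5 reads in the
  untreated arm (boundary inclusive); below that the cell is
  `INSUFFICIENT_COVERAGE` — a blank, excluded from both numerator and
  denominator of every fraction.
* Time-course (gavage) filter: a trigger with < 5 reads in the gavage
  suspension is discarded unless some later untreated sample registers
  strictly more than 20 reads.
* Hit: `VALID` ∧ OR ≥ 0.02 (inclusive) ∧ p < 0.05 (strict). The OR cutoff
  is applied alongside the test even though the null already encodes the
  boundary, mirroring the screen's conjunctive criterion.
* In-vivo responder: every VALID gavage cell has OR < 0.02, and ≥ 1
  post-gavage cell is a hit. If no gavage cell is VALID the class is
  not evaluable.
* Differential response: positive-time-point fraction of the treated group
  minus the control group, each pooled over that group's evaluable cells;
  antisymmetric under group swap by construction.
* No multiple-testing correction is applied by default (the screen's
  criterion is per-cell); Benjamini–Hochberg is available as an explicit
  helper for users who want it.

Percentage-of-positive-time-points pools mouse × time-point cells within a
group rather than averaging per-mouse fractions; the pooled convention
matches the heat-map layout in which every cell carries equal weight, and
the denominator counts only evaluable cells so coverage dropouts are not
penalized. Ranking tie-breaks (mean OR, then trigger id) are arbitrary
choices fixed for byte-identical reruns.

## ROC calibration

Given per-trigger odds ratios from a pooled growth and plate-derived
memory-state labels, the cutoff sweep uses the positive-call convention
OR ≥ t over thresholds {−∞} ∪ {observed ORs} ∪ {+∞}, so the conventional
0.02 cutoff always lies on the sweep. AUC is the trapezoid integral after
sorting points by (FPR, TPR) — the secondary key keeps tied-FPR segments
from folding the curve — and equals the Mann–Whitney U statistic divided
by n₊·n₋ (tested by brute-force pair counting). The Youden-J-optimal
threshold is reported alongside because in separable data any threshold in
the gap is optimal and J picks one deterministically (the smallest OR
attaining maximal J).

## Read assignment

Reads are assigned by unique best exact-seed containment: a k-mer index
(k = `min_match_len`, default 30 nt) over both strands of every trigger,
seed-and-extend to the maximal exact match, assignment to the single
trigger achieving the global best match of length ≥ k. Ties are
`AMBIGUOUS`, no qualifying match is `UNMAPPED`; both are tallied and
excluded from statistics. Seeds containing N never match, so N bases are
only crossed by extension from N-free seeds. This deterministic counter is
designed for amplicon-like reads that are substrings of trigger regions;
it does not do quality-aware or gapped alignment, and users with real
aligner output can enter the pipeline at the count-table TSV instead.

## The simulator

The generator mirrors the protocol stage by stage:

* **Library & suspension** — per-strain gavage abundances from a symmetric
  Dirichlet (concentration 5 per strain, a moderately uneven library) or a
  normalized lognormal.
* **Gut passage** — per-strain, per-transit-day Bernoulli dropout at 3%
  per day, chosen to land in the observed 80–92% strain retention over
  5–7 day courses, plus day-to-day lognormal abundance jitter (σ = 0.3).
* **Memory switching** — encoded directly as a memory-on fraction f per
  condition (`always_off`, `in_vivo`, `disease_only`, `always_on`); no
  switch kinetics are modeled, since the screen measures f, not rates. At
  the gavage baseline (t = 0, before gut exposure) `in_vivo` and
  `disease_only` triggers are off.
* **Spike-in & selection** — PNS appended at 1:1,000 with f = 1; selected
  weight of a strain is abundance × (f·0.93 + (1−f)·0), i.e. 93% recovery
  of memory-on cells and zero escape of memory-off cells, the measured
  selection performance. Post-selection overnight growth is modeled as
  composition-preserving (equal growth rates); shared growth factors
  cancel in the OR anyway.
* **Sequencing** — one multinomial draw per arm at configurable depth,
  optional per-strain length-bias factors, and optionally explicit reads
  (uniform start, uniform strand, iid substitution errors) in FASTQ.

The default screen is 150 triggers of 300 nt (pairwise-disjoint 30-mers by
rejection sampling), five `in_vivo` responders at f = 0.1/0.2/0.3/0.5/0.8,
one `disease_only` responder at f = 0.5, three mice per group, time points
1–5 days plus gavage, and 5×10⁵ reads per arm. Every mouse carries a t = 0
sample pair drawn from the shared suspension composition (independent
sequencing replicates of one gavage suspension); responder classification
requires all VALID gavage cells below the cutoff. The truth table records
per-cell abundance, on-fraction, and the analytic expected OR
f + (1−f)·e/s.

What the simulator does **not** emulate: PCR duplicates and chimeras,
strain-specific fitness differences during outgrowth, colony-bottleneck
drift at low CFU, aligner-specific mapping artifacts, and any host/disease
biology beyond the condition labels. Passing recovery tests therefore
demonstrates the statistical pipeline is correct and well calibrated under
the protocol's stated noise structure, not that any particular biological
screen will be as clean.

## Problem sizes and numerical choices

The validation experiments (test suite and `scripts/acceptance.py`) use:
10,000 trigger-samples at 2×10⁴ reads/arm for the null false-positive
rate; 200 replicates per on-fraction at 10⁶ reads/arm for OR recovery
(median relative error < 10% required; observed ≈ 1%); the default screen
(5,400 trigger × mouse × time-point cells) for end-to-end responder
recovery; 44 strains for the ROC calibration. All randomness flows from a
single seed through `numpy.random.default_rng` / `SeedSequence`; nothing
is seeded from the clock. Tolerances: pmf normalization to 1e-12,
psi = 1 reduction to the central law at 1e-12 absolute, oracle agreement
of p-values at 1e-9 relative.

## Known limitations

* The exact test's conservatism means marginally-on strains near the
  boundary need either depth or repeated time points to reach
  significance; the screen design (multiple mice × days) is what supplies
  the power.
* `UNDEFINED` odds ratios (zero untreated reads with nonzero selected
  reads) are treated as insufficient coverage rather than as infinite
  enrichment; a strain that blooms only under selection would need the
  rescue rule at the time-course level to be noticed.
* The read counter's unique-containment rule is stricter than MAPQ-based
  uniqueness for highly similar trigger variants (e.g. RBS variants
  sharing a promoter): reads from the shared region count as ambiguous and
  are dropped, which lowers depth but not correctness.
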