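# Methods

This note documents the models, conventions, and design decisions behind
svensemble, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, what the simulator does and does not emulate, and
where the design was genuinely open.

## Refinement

Each caller VCF passes through four steps, in this order: annotation, size
exclusion, paired-record deduplication, and PASS filtering. The order
matters only mildly (size exclusion before dedup means a sub-50 bp pair is
removed by length, never by pairing), and the whole pipeline is idempotent:
refined output re-refines to itself.

**Annotation** resolves the SV type with a fixed priority: the INFO
`SVTYPE` key (with `TRA` mapped to CTX and subtype tokens like
`DUP:TANDEM` truncated at the colon); then a symbolic ALT token; then the
REF/ALT length difference of a sequence-resolved allele (net gain → INS,
net loss → DEL). Breakend records are classified from the junction
orientation of the ALT string: for a same-contig mate pair, a
sequence-then-`[` junction pointing at a larger coordinate (or its
`]`-then-sequence complement at the larger coordinate) is a deletion, the
converse layout a tandem duplication, and matching-side orientations an
inversion; an inter-contig mate makes the record a translocation (CTX).
Lengths are stored as absolute values (`|SVLEN|`, else `END − POS`, else
the REF/ALT length difference, else the mate distance for breakends); CTX
records carry no length. Records that cannot be classified (no type
information and a length-neutral non-symbolic ALT) are dropped with a
logged counter rather than failing the run — real caller output contains
exotic records, and a hard error would make the pipeline unusable on them.

**Size exclusion** removes calls *shorter than* `min_size` (default 50 bp),
so a 50 bp call survives. Calls whose length is unknowable — CTX, and
symbolic `<INS>` without `SVLEN` — are kept: dropping them would silently
discard true calls of unknown length. Such insertions are flagged
`SVLEN_UNKNOWN` on output.

**Deduplication** collapses records that jointly describe one SV. Links are
established by `MATEID`, by a shared `EVENT` (when exactly two records
share it), or by a shared ID stem with `_1`/`_2` suffixes. The stem rule
needs a guard: independent calls with sequential IDs (`call_1`, `call_2`)
must not be linked, so stem pairs only count when they look like the two
endpoints of one SV — breakend-derived, or same type with one record's
position equal to the other's end (or one of them lacking a resolved span).
Within a linked group the record with the smaller position survives; across
contigs the record on the earlier contig survives, using the VCF header's
contig order with a natural-sort fallback (deterministic and
reference-agnostic). A `MATEID` pointing at a missing record keeps the
survivor and counts a warning.

**PASS filtering** keeps records whose FILTER set is exactly `{PASS}`. A
missing FILTER (`.`) is *not* retained: an unfiltered record is not a
passing record, and fidelity beats leniency here.

Per-step removal counters are reported and must satisfy
`input = output + dropped + removed_size + removed_dedup + removed_filter`.

## Neighbor grouping

Pooled, caller-tagged calls are grouped per (contig, SV type). The calls
are sorted by position, with ties broken by caller label and then record
ID so grouping is a function of the call *set*, not the input order. A
left-to-right sweep then applies an **anchored** rule: the first call opens
a group and is its representative; each subsequent call joins the open
group iff `pos − representative.pos ≤ window` (500 bp default, inclusive),
otherwise it opens a new group.

Anchoring is an interpretation: grouping could also be transitive
single-linkage (join if within the window of *any* member). The anchored
reading is adopted because it guarantees the stated contract that every
member lies within the window of its representative — transitive chaining
can produce groups spanning many windows — and because the representative
is defined as the smallest-position member, which is exactly the anchor.
Same-caller calls may share a group; nothing in the scheme forbids
within-caller proximity, and the group-size tables surface it when it
happens.

Strategies over the groups: `multiple_agreement` emits representatives of
groups with ≥ `min_support` (default 2) distinct supporting callers;
`union` emits every representative; `direct_merge` bypasses grouping and
concatenates the pooled refined calls. Merged representatives carry
`caller=<comma list>`, `SUPP` (distinct caller count) and `GROUP_SIZE` in
INFO. Concordance tables count groups by their exact supporting-caller
subset and sum to the number of groups.

## Benchmarking

Matching is by position and type only — no length or sequence similarity.
A candidate pair is a same-contig, same-type (truth, test) pair with start
distance ≤ 500 bp inclusive. Assignment is one-to-one greedy by ascending
distance (ties by truth then test position): each truth and each test call
is consumed at most once, which is the only reading consistent with
`FP = |TEST| − TP` and `FN = |TRUTH| − TP`. On truth sets whose variants
are spaced more than twice the window apart, greedy assignment equals the
maximum bipartite matching (each call has at most one candidate partner);
on arbitrary instances it is a lower bound, verified against an exact
matcher in the tests. Deletions and insertions are always evaluated
separately.

Metrics use the 0/0 → 0 convention, so an empty call set scores 0 rather
than erroring. Reported tables carry both full-precision values and values
rounded half-up to two decimals (0.625 → 0.63). Combined metrics across
datasets are micro-averages of the summed counts, so a single-dataset
"combination" reproduces the per-dataset metrics exactly and duplicated
datasets leave the metrics unchanged.

An optional confident-region restriction keeps calls whose POS falls
inside a BED region, comparing POS directly on the BED half-open axis
(a call at a region's end coordinate is excluded). This is the adopted
boundary convention; it is off by default and unused in the synthetic
pipeline.

The counts-only mode (`svensemble tables`) recomputes all metric columns
from a `(dataset, callset, svtype, tp, fp, fn)` table after an internal
consistency audit (per-row `total = TP + FP`, constant truth totals within
a dataset, combined counts equal to per-dataset sums). The packaged
reference table (`svensemble/data/benchmark_counts.tsv`) holds published
benchmark counts for six callers and their III/V-panel combinations on
HG002 (GIAB v0.6 Tier 1) and HG00514/HG00733/NA19240 (HGSVC2), and serves
as an exact regression fixture for the formulas. The audit passes on all
90 rows; 268 of its 270 reported metric cells are reproduced exactly at
two decimals from the counts alone. The remaining two cells are misprints
in the source table itself — in both cases the counts, which are
internally consistent, imply a different rounded recall than the one
printed (0.33 vs 0.36, where a duplicate row elsewhere in the same source
prints 0.33; and 0.43 vs 0.44, a double-rounding artefact) — and the
recomputed values are treated as correct.

## The simulator

The simulator produces *call sets*, not reads: no alignment, sequence
context, genotypes, or coverage structure. It emulates the statistical
skeleton the analysis rests on, which is exactly what the refinement,
grouping, and matching stages consume.

**Truth sets.** `n_truth` deletions and `n_truth` insertions (default
2,000 each) on a two-contig 22 Mb genome, positions uniform subject to a
minimum inter-variant spacing of 1,001 bp — the exclusion rule
high-confidence SV benchmarks apply to nearby variant clusters, and the
rationale for the 500 bp matching window: spacing > 2·window makes every
evaluation unambiguous. Spacing is enforced by the order-statistics
construction (uniform draws on a compacted interval, sorted, re-inflated),
which samples uniformly among valid configurations without rejection.
Sizes are log-uniform on [50 bp, 10 kb], the range that dominates real SV
benchmarks. Types share one spacing pool, and counts are allocated to
contigs by largest-remainder proportional to usable length. Infeasible
packings raise immediately.

**Caller profiles.** Each simulated caller detects each truth variant of
type T independently with probability `recall[T]`, at a position offset by
discretized double-geometric jitter with mean absolute offset `s` bp
(heavier-tailed than uniform but concentrated at zero, consistent with the
small observed neighbor distances — medians of 0–10 bp — while still
producing occasional larger offsets). False positives are Poisson with
mean `fp_count[T]`, placed at least `window + 12·s + 1` bp from every
truth start so they can never match truth and, being placed independently
per caller on a large genome, essentially never agree across callers —
which is what makes the union-vs-agreement precision trade-off
reproducible in silico. Dialect quirks exercise the refinement stage:
`emits_paired_records` writes DEL/DUP/INV as two MATEID-linked breakend
lines; `sub50_fraction` and `nonpass_fraction` add decoy records (< 50 bp,
or FILTER `q5`) that refinement must remove; `detects_ins=False` models
callers that call no insertions at these sizes.

The five shipped default profiles approximate the measured HG002 behaviour
of Manta, DELLY, GRIDSS, LUMPY, and SvABA: DEL recalls 0.55 / 0.48 / 0.42 /
0.12 / 0.28, INS recall meaningful only for Manta (0.19), near zero for
DELLY and GRIDSS, and absent for LUMPY and SvABA; false-positive loads are
the measured per-caller FP counts scaled to a 2,000-variant truth set.
Profiles are configuration, not code.

**What passing tests do and do not show.** Because simulated callers err
independently, ensemble gains are larger than on real data, where callers
share alignment artefacts and repeat-driven errors: simulated union recall
(≈ 0.86 for the III panel) exceeds what correlated real callers achieve,
and simulated multiple-agreement precision is near 1. Passing tests
demonstrate that the machinery — refinement, grouping, strategy logic,
matching, metric algebra — is correct and that the qualitative ordering
(union maximises recall, agreement maximises precision, agreement call
sets are subsets of union call sets) holds; they do not certify
quantitative performance on real genomes.

## Numerical and reporting conventions

- Coordinates are VCF convention: 1-based POS, inclusive END.
- Quartiles (length summaries, neighbor-distance summaries) use linear
  interpolation; the median of an even-sized set is the mean of the two
  central values; IQR = Q3 − Q1.
- Display rounding is half-up to two decimals via decimal arithmetic, so
  binary-float artefacts cannot flip a boundary case.
- Contig order everywhere (sorting, inter-contig dedup) is header order
  when available, else natural sort (chr2 < chr10).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-caller and per-dataset streams are
  spawned, so adding a caller or dataset never perturbs the others, and
  full runs are byte-reproducible.

## Validation design

The test suite checks the grouping sweep against an independently written
anchored re-scan and the greedy matcher against exact maximum bipartite
matching (SciPy) on thousands of randomized small instances, alongside
unit tests of every documented example and property tests of the
invariants (partition, window span, union ⊇ agreement, micro-average
bounds).

Statistical parameter recovery runs 2,000 truth variants per type through
the full simulate → write-VCF → refine → match pipeline and asks whether
each profile recall lies in the exact 95% Clopper–Pearson interval of the
measured proportion and each FP count in the 95% Poisson interval of its
load. A single such check false-alarms on 5% of seeds by construction, and
twelve of them jointly on roughly a third of seeds, so the deterministic
test requires each quantity to lie inside its interval in a majority of
five independent replicates: family false-alarm ≈ 1%, while a real recall
bias of ~0.03 at this sample size still fails reliably. The intervals
themselves are the exact per-quantity 95% intervals throughout.

Problem sizes in the default test run and the reproduction script —
2,000 truth variants per type for recovery, 400 for the ten-seed strategy
ordering experiment, 120–500 for end-to-end runs — were chosen as the
smallest sizes at which the statistical assertions have the stated power;
the library handles larger runs linearly in the number of calls.

## Known limitations

- Caller errors are simulated as independent; correlated errors (shared
  repeat artefacts) are not modelled, so ensemble performance on synthetic
  data is optimistic.
- Matching is position+type only, by design; breakpoint-resolution or
  sequence-similarity scoring (Truvari-style) is out of scope.
- Genotypes and FORMAT fields are ignored throughout.
- Breakend classification assumes well-formed bracket ALTs; records whose
  mates are absent and that carry no other type information are dropped
  (and counted), not rescued.
- The simulator emits DEL and INS truth sets only, matching what SV truth
  sets provide; DUP/INV/CTX are exercised through the refinement and
  grouping stages but not benchmarked.
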