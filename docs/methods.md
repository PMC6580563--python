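# Methods

## Adapter alignment model

An adapter `A` (length `m`) is aligned to a read `R` (length `n`) under
unit-cost edit operations (mismatch, insertion, deletion each cost 1) with
free end gaps chosen by adapter kind:

* **3' adapter** — a *prefix* of the adapter must be aligned
  (`adapter_start = 0`); the alignment may lie anywhere in the read when
  the whole adapter is aligned, or end exactly at the read's 3' end when
  only a prefix is (`adapter_stop < m ⇒ read_stop = n`). Removal cuts from
  the match's read start through the read's 3' end.
* **5' adapter** — the mirror image: an adapter *suffix* aligned, partial
  matches only at the read's 5' end, removal from the 5' end through the
  match's read stop.
* **anywhere** — the union of the two candidate sets above. An adapter
  interior overhanging *both* read ends simultaneously (read strictly
  inside the adapter) is not a candidate; this matches the front-or-back
  semantics of comparable trimmers and keeps the removal rule (cut from
  the match's read start) meaningful. Removal follows the 3' rule.
* **anchored** (3' or 5') — the full adapter must abut the respective read
  end.

`N` matches nothing: aligned against any base it counts as a mismatch,
whether it occurs in the read or the adapter. For the same reason the
exact-substring fast path never fires on windows containing `N` (and is
skipped for anchored adapters, whose position constraint a mid-read hit
would violate).

**Acceptance thresholds.** A candidate with `E` errors over `k` aligned
adapter bases qualifies iff `E/k ≤ e` and `k ≥ O`. The DP prunes states
with more than `floor(e·m)` accumulated errors — lossless, because any
qualifying candidate satisfies `E ≤ e·k ≤ e·m` and path costs are
non-decreasing — while final acceptance always re-checks the rate against
the *aligned* length, which is the stricter condition for partial
overlaps.

**Objective and tie-breaks.** Among qualifying candidates the winner
maximises matched bases, then minimises errors, then takes the smallest
read start, then the smallest read stop, then the smallest adapter start.
The first three levels define "best"; the last two only exist to make the
result a total order (distinct alignments can tie on all of matches,
errors and read start, e.g. with a trailing indel), which is what lets an
independent exhaustive search reproduce the implementation's output
exactly. Across multiple adapters, ties after matches and errors go to
the adapter listed first by the caller.

**Implementation.** The DP is layered by exact error count
(`cost ∈ 0..floor(e·m)`); each cell of the adapter × read table stores,
per layer, the maximum match count and the preferred read start among its
maximisers. Rows beyond the deepest reachable row of the previous column
(+1, plus in-column deletion chains) are never touched, so on random
sequence the per-column work is proportional to the error budget rather
than to `m`. 5' adapters are aligned as reversed 3' problems with the
start preference flipped so that tie-breaking happens in original
coordinates. With `--no-indels`, alignment reduces to a per-shift Hamming
comparison over all placements permitted by the same boundary rules.
Lexicographic layering is what makes the per-cell greedy choice exact: a
higher-error alignment with more matches is kept in its own cost layer
rather than being shadowed by a cheaper, lower-match path.

Only the single best adapter occurrence is removed per read per pass; the
overlap histogram therefore counts one aligned length per adapter-
containing read.

## Quality end-trimming

For threshold `Q` (flag `-Q`), the 3' cut point is
`argmax_x Σ_{i=x}^{L-1} (Q − q_i)` provided the maximum is positive,
computed independently for each end (prefix sums for the 5' end); when
the two cuts cross, the read becomes empty. Equal maxima resolve toward
trimming more bases at both ends — the convention is arbitrary but frozen
and oracle-tested. This partial-sum rule (the one BWA's trimmer uses) can
cut past an isolated good base inside a bad tail, which a naive
strip-while-below-threshold loop cannot.

Stage order within a read: quality trim, then N end-trim, then adapter
removal, then filters. Filters see the fully trimmed read, and each
read's verdict records *all* failing criteria, so the report's `+`
category (failed ≥ 2 criteria) is exact rather than first-hit.

## Filter boundary conventions

* quality filter `-q q,f`: fail iff `#{q_i ≥ q}/L < f` — bases exactly at
  `q` count as good (the usual Q30 convention); at `L` = 100, `f` = 0.85,
  84 good bases fail and 85 pass.
* N ratio `-r r`: fail iff `#N/L > r` (strict); 2 Ns in 100 fail at
  r = 0.01, 1 in 100 passes.
* length: fail iff `L < m` (strict) or `L > M` (strict); a 20-base read
  passes `-m 20`.
* Empty-after-trim reads are not errors; they pass the quality and N
  filters vacuously and are caught by `-m` when it is set.
* Paired mode: mates are trimmed independently, then judged together;
  a passing read whose mate failed is discarded with its own
  `mate_failed` category (not folded into the mate's criterion).

## Parallel execution contract

The input stream is split into chunks (default 1,000 records; paired
chunks always contain whole pairs). Chunks may be processed by a thread
pool, but results are collected strictly in submission order and chunk
statistics are merged by component-wise addition, which is associative.
Consequently output FASTQ bytes and all reports are identical for any
thread count — verified byte-for-byte at 1/2/4 workers in the suite. The
gzip writer pins the header timestamp for the same reason. When split
output is requested (`--split k`), the record stream is buffered so the
contiguous block size `ceil(n/k)` is known; memory is proportional to
output size in that mode (and in threaded runs, which buffer passed
records before writing).

## Report definitions

Per-position quality summarises the score distribution at each 1-based
position as min, Q1, median, Q3, max and mean; quartiles use linear
interpolation on the empirical distribution (the numpy default), checked
against a sort-based oracle. Whiskers are plain min/max. Base
percentages use A/C/G/T/N counts over all bases; per-position
compositions are normalised by the number of reads covering the
position. The JSON document (schema in `report_schema.md`) carries the
raw count matrices as well as the derived summaries, so a re-parsed
report reconstructs the in-memory accumulators exactly; the HTML report
embeds that JSON verbatim in a `<script type="application/json">` block,
making numeric parity between formats mechanical. Charts are
dependency-free inline SVG; they aim at legibility, not at any particular
charting library's appearance.

## Synthetic data generator

`fixtures.generate` emulates the conditions the pipeline is meant for:
uniform-random background over {A,C,G,T}; per-position Gaussian quality
with the default profile declining linearly from mean 38 (5' end) to 30
(3' end), sd 3, rounded and clamped to [2, 40]; a fraction of reads
(default 0.10) carrying a 3' adapter written over the read suffix from a
uniformly drawn start in the last `m + 10` positions and truncated at the
read end — the read-through model, producing every overlap length for
the adapter histogram plus some fully internal matches — optionally with
substitutions injected inside the visible adapter bases; and a disjoint
fraction (default 0.05) carrying a planted N-run (length 5). Adapter and
N planting are mutually exclusive per read so each read's ground-truth
label is unambiguous. One integer seed makes output byte-identical.

What it does **not** model: quality-dependent substitution errors in the
insert, indel sequencing errors, duplicate structure, composition bias,
or adapter dimers. Tests passing on these fixtures therefore demonstrate
correctness of the algorithms under controlled truth, not performance on
any particular instrument's error profile.

## Problem sizes and numerical choices

The suite exercises the aligner against an exhaustive search on 2,000+
randomized cases (reads ≤ 30 nt, adapters ≤ 10 nt, e ∈ {0, 0.1, 0.2},
O ∈ {1, 3, 5}, with and without indels), the trimmer against brute force
on 5,000+ reads ≤ 50 nt, and the end-to-end pipeline on fixtures of
10,000 reads; `scripts/acceptance.py` uses 5,000 read pairs of 150 bp.
These sizes give stable percentages (binomial noise well under a
percentage point) while keeping a full run in tens of seconds.
Error-rate comparisons use the exact expression `errors ≤ e·k` in both
implementation and oracles, so no tolerance is involved anywhere in
matching decisions.

## Known limitations

Single adapter occurrence removed per read (no iterative re-scan);
interleaved FASTQ, FASTA, and BAM/SAM input are out of scope; quality
encoding is declared, never guessed; threading shares the Python
interpreter, so it bounds latency jitter rather than adding CPU
throughput — the contract it implements is determinism, not speed-up.
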