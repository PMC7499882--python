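# Methods

This note documents the data structures and algorithms `ccdbg` implements,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical/design choices made where more than one
reasonable option existed.

## Definitions and conventions

Sequences are over {A, C, G, T}; input records are upcased and split at any
other character, and each maximal ACGT run is processed independently. A
k-mer is identified with its *canonical* form, the lexicographically
smaller of itself and its reverse complement, so both strands index
identically. Internally words are 2-bit packed (A=0 … T=3, big-endian), so
integer order equals lexicographic order and reverse complementation is bit
arithmetic. All coordinates are 0-based and half-open. Defaults: k = 31
(odd, ≤ 63; odd k rules out self-reverse-complementary k-mers), g = k − 8 =
23 (1 ≤ g ≤ k − 2 enforced; the CLI requires g ≥ 3).

**Minimizers.** The minimizer of a k-mer is its interior g-mer with the
smallest 64-bit hash of the packed canonical word (a splitmix64 finalizer
seeded per index; the seed is recorded in the GFA header so an index is
reproducible). The first and last g-mer of each k-mer are excluded from
candidacy: with this restriction the four forward (resp. backward)
neighbors of any k-mer share one minimizer, which keeps their Bloom-filter
probes inside a single block during graph traversal. Ties between equal
hashes go to the leftmost occurrence — the hash is 64-bit, so in practice
ties are repeated occurrences of the same g-mer. Iterating the minimizers
of a whole sequence uses an ascending-minima (monotone deque) sweep,
amortized O(1) per k-mer; a brute-force per-k-mer recomputation is kept as
the test oracle.

## Blocked Bloom filter

A filter is an array of 512-bit blocks (one cache line) with exact
per-block set-bit counters. An element is addressed by two independent
hashes of its canonical k-mer and by its minimizer hash: the minimizer hash
selects two candidate blocks (2-choice), and insertion goes to the
less-occupied candidate unless either already contains the element.
`MayContain` reports true if either candidate block holds all f probe bits.
The f probe positions come from double hashing the two k-mer hashes, with
each term h₁ + i·h₂ passed through the splitmix64 finalizer before
reduction mod 512: raw arithmetic progressions alias each other inside a
512-bit table (we measured a 2.0× false-positive inflation in isolation),
while the finalized positions behave as independent probes.

Sizing: `for_expected(n, bits_per_element)` allocates ⌈n·b/512⌉ blocks and
f = round((m/n)·ln 2) probes, minimum 1; the default budget is 14 bits per
element. The closed-form rate φ = (1 − e^(−fn/m))^f describes one classic
Bloom filter; because the query ORs two blocks, this structure's intrinsic
rate is 2φ − φ² plus a small Jensen term from per-block fill variance
(measured ≈ 1.96φ at 8 bits/element, where the −φ² term is material, and
≈ 2.05–2.15φ at 14 bits/element, where it is not). The structure has no
false negatives, ever; this is property-tested over random
insert/query interleavings. The acceptance suite asserts the 2φ bound at
both budgets and the 14-bit case sits marginally above it — an inherent
property of OR-ing two blocks, not a calibration error, so we report it
rather than widen the test.

Concurrency: single-writer only. A parallel implementation would need
per-block mutual exclusion (the design this follows uses one spinlock per
block); nothing here depends on that, and the contract is documented rather
than simulated.

## Two-pass filtering

Reads mode streams every canonical k-mer: present in BBF1 → insert into
BBF2, else insert into BBF1. BBF1 is discarded afterwards; BBF2
approximates the ≥2× k-mer set (a k-mer occurring once enters BBF2 only
through a BBF1 false positive, and such contaminants are later removed by
occurrence counting). Reference mode inserts everything into BBF2 directly
and lowers the downstream counter threshold from 2 to 1. Filters are sized
from an up-front element estimate, by default derived from input file sizes
(gzip assumed ~3× compressed; FASTQ halved for quality lines) — a crude
upper bound that errs toward lower false-positive rates — and BBF2 at 0.6×
the distinct estimate; both are overridable. Processing order is file
order; results are deterministic for a fixed seed and input order.

## The dictionary D = (U, M)

`U` holds unitig records: the sequence (stored strand-canonically — the
lexicographically smaller of the sequence and its reverse complement — a
deterministic orientation that makes multiset comparisons trivial),
per-k-mer occurrence counters saturating at 2 (the cleanup only
distinguishes {0, 1} from ≥ 2), an optional color-slot reference, and the
exact list of (minimizer, position) tuples the record contributed to `M`,
so removal never re-derives table state. Freed ids are recycled through a
free list; a live id never changes. `M` maps each canonical minimizer
g-mer to its anchor list of (unitig id, position) tuples.

**Lookup** extracts the query's interior g-mers, takes the smallest hash,
and anchors the query and its reverse complement at each recorded position
(every occurrence offset of that g-mer within the query is tried, so
repeated minimizers cannot cause misses). A miss with a non-recurrent
anchor list is definitive.

**Recurrent minimizers** (anchor list length ≥ t, default t = 64, typical
of homopolymers and tandem repeats) are handled on both sides: insertion
falls back to the k-mer's next interior g-mer in ascending hash order whose
list is still short, overflowing the true minimizer's list only when every
candidate is recurrent; lookup, after a recurrent miss, rescans the
remaining candidates in the same order. Once any list has been seen at ≥ t
entries the rescan continues through all remaining candidates rather than
stopping at the first short one — anchor lists shrink when unitigs are
removed during cleanup, so the stricter stopping rule (valid under
insert-only monotonicity) could strand a k-mer indexed under a fallback
g-mer. The residual risk — a list shrinking from ≥ t to *empty* between
indexing and lookup while the entry lives under a later candidate — is
accepted and has never been observed in testing; per-lookup work stays
bounded by (k−g−1) candidate lists of ≤ t anchors (plus overflow lists).

## Unitig extraction and ghosts

Extraction extends a seed k-mer forward, and backward via forward extension
of its reverse complement, advancing from x to x′ only when x′ is the
unique non-ghost successor of x and x the unique non-ghost predecessor of
x′; a per-extraction visited set guards against cycles. Probing all four
candidates per direction costs 8 filter queries per internal k-mer, exactly
2 of which return true on an error-free filter — the acceptance suite
asserts this arithmetic on instrumented runs.

Ghost checks run only when the neighborhood is anomalous (more than one
candidate successor, or a candidate's predecessors beyond the current
k-mer): a candidate with no filter neighbor besides its anchor is recorded
as a ghost and ignored by both uniqueness counts. A single clean successor
is adopted without a ghost probe — this keeps the 8/2 arithmetic exact, and
a false-positive dead end adopted this way is deleted later by its zero
counter. A k-mer already present in the dictionary is never
ghost-dismissed: it is proven real, and without this rule a repaired
one-k-mer unitig hanging off a junction would be re-ghosted on the next
extraction and the junction merged through (caught by the node-centric
oracle during development). When a read later contains a ghost, the ghost
is deleted from the table, the adjacent unitigs are removed with their
counters saved by canonical k-mer, and the region is re-extracted from the
ghost and every displaced k-mer — extracting only from the ghost would be
wrong, since the repaired k-mer may legitimately split the displaced path
at its junction. Repair is eager (at first observation) and yields the
graph that would have been built had the k-mer never been ghosted.

## False-positive elimination

During the second read pass every located k-mer's counter is incremented
(including the occurrence that triggered its unitig's extraction). Cleanup
deletes all k-mers with counter < threshold (2 reads / 1 reference),
splitting unitigs at interior deletions — a deleted interior k-mer is a
*false connection* (it glued two real unitigs); a deleted whole-unitig or
terminal k-mer is a *false branching* (it hung off a real path). A join
sweep then merges every unitig pair with unique mutual tail→head adjacency,
in any orientation, iterating to a fixed point; deletion-before-join makes
the result order-independent (validated against brute-force compaction).
The final k-mer set equals exactly the set of k-mers meeting the threshold.

## Colors

Color j of |C| is the j-th input file (0-based internally; names are file
basenames). Each colored unitig owns the set of (row i, color j) cells of
its η×|C| matrix inside a container whose tier follows the matrix size: a
64-bit word when η·|C| ≤ 62 (2 bits reserved for metadata) or when a single
cell is set (stored as one tuple); a compressed bitmap addressing up to
65,488 cells in ≤ 8 KB, serialized as the smallest of bit vector / sorted
cell list / run-length list (re-evaluated as the container grows); and an
unbounded roaring-style tier for larger matrices, held as an uncompressed
set of 32-bit cell keys. The 65,488 limit is read as *addressable cells*
(65,536 bits minus 48 metadata bits), which is what makes the 8 KB budget
arithmetically consistent. Membership semantics are identical across tiers
and checked against a plain set oracle across both boundaries.

Containers live in an array `O` and are linked to unitigs by hashing the
unitig's head k-mer through a cascade of |H| = 16 seeded hash functions
(first unclaimed slot wins), with a plain table `K` as fallback after |H|
misses — a layered scheme in the spirit of minimal-perfect-hash
construction. `O` grows by doubling at the tail only, so claimed slots
never move; the resolved index is stored on the unitig record, and
releasing a slot never disturbs any other container. When cleanup or update
splits or merges colored unitigs, cells are remapped by absolute k-mer
position (mirrored when the stored orientation flips). The sidecar
serialization writes (head k-mer, sorted cells) per colored unitig plus the
color-name table; loading re-assigns slots through the same cascade.

## Queries

A query of length L contributes L−k+1 k-mer positions per ACGT run
(repeated k-mers count per position); it is *present* when the found
fraction is ≥ θ ∈ (0, 1]. In inexact mode a k-mer counts as found (at full
weight) when any variant within one edit is in the graph. Because the
graph only holds length-k words, indel variants are *windowed*: a deletion
re-extends one base at either window edge, an insertion trims one base at
either edge; substitutions are enumerated first (they are the common
sequencing-error rescue) and candidates are verified by dictionary lookup
only, with early exit on the first hit. This windowed semantics is the one
place the package knowingly departs from a strict per-k-mer edit-distance-1
definition: a windowed indel variant can sit at Levenshtein distance 2 from
the original k-mer (the indel plus the edge base), which is exactly what a
read with one indel produces in its flanking k-mer windows. Exact queries
are complete and sound (the index is exact); inexact found counts dominate
exact ones, with equality on error-free queries drawn from the graph; and
presence is monotone in θ. All three properties are asserted universally in
the acceptance suite.

## Dynamic update

`update` merges reference-mode datasets into an existing graph in place:
(1) collect the novel k-mer set; (2) split existing unitigs wherever a
novel k-mer attaches as an extra neighbor, so every new junction lies at a
unitig boundary (counters and colors remapped by position); (3) compact the
novel set into unitigs, stopping at junctions with the old graph; (4) run
the global join sweep; (5) append one color column per new file and stream
the files through the coloring pass. The result is node-centrically
identical to a from-scratch build on the union — asserted on seeded
pan-genomes, colors included. Reads-mode update is out of scope: it would
require re-running the two-filter occurrence pass over the merged stream,
and the update use case this follows is assembled genomes.

## Synthetic data

The generator emulates closely related strains and their sequencing: a
uniform-random ancestor; per-color descendants with i.i.d. substitutions
(default 1%) and 1–3 bp indels (default 0.1%); uniform single-end reads
from both strands (default 100 bp at 30×) with i.i.d. substitution errors
(default 0.5%). Truth tables — per-color k-mer sets and exact read k-mer
counts — are computed by direct dictionary counting, independent of every
graph structure. All randomness flows from one PCG64 seed; outputs are
byte-identical per seed.

What it does not emulate: repeat structure (uniform-random genomes of a few
kb carry essentially no repeated 31-mers, so recurrent-minimizer and
cycle-guard paths are exercised only by constructed adversarial tests),
coverage biases, indel sequencing errors, quality scores, and paired-end
structure. Passing tests therefore demonstrate correctness of the graph
algebra under realistic error and divergence rates, not robustness to
repeat-dense genomes at scale. Genome ends are covered by few read starts,
so end k-mers legitimately fall below the ≥2× threshold — the truth tables
count reads, not genomes, and the exactness tests compare against read
truth.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale, chosen to exercise every
code path while keeping the suites in minutes on one CPU: 5–10 kb genomes
at 20–40× coverage and 0–1% error for end-to-end exactness (20 seeded
datasets in the suite, 12 in the script), 10⁵ elements and 10⁶ queries for
filter calibration, a 5-color pan-genome for coloring, 10⁴ queries for the
θ sweep, and 2×10⁵ trials for the geometric halt-length law. Counters and
thresholds (t = 64, 14 bits/k-mer, |H| = 16, block 512 bits) are the
package defaults discussed above.

## Known limitations

- Purely cyclic components (an isolated circular path) are linearized at an
  arbitrary rotation by the cycle guard; two builds seeded differently may
  cut the cycle at different k-mers. Random linear test genomes do not
  produce such components.
- The recurrent-minimizer rescan's residual stranding case described above.
- The Bloom layer's false-positive rate is intrinsically ≈ 2φ (two-block
  query); memory budgets should be read accordingly.
- Single-threaded by design; the per-block exclusivity a parallel port
  would need is documented, not implemented.
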