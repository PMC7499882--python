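# ccdbg

Colored and compacted de Bruijn graphs, built directly from sequencing reads
or assembled genomes — without ever materializing the uncompacted graph.

## The problem

A de Bruijn graph over the k-mers of a read set is the workhorse of
assembly, pan-genomics and reference-free variant analysis, but storing one
vertex per k-mer is prohibitive: a human short-read dataset has billions of
distinct 31-mers. The *compacted* de Bruijn graph (cdBG) collapses every
maximal non-branching path of η vertices into a single *unitig* of length
k+η−1, typically shrinking the vertex count by orders of magnitude. The
catch is that standard compaction needs the uncompacted graph in memory
first. `ccdbg` avoids that via a probabilistic two-stage construction:

1. **Filtering.** All canonical k-mers of the input stream through two
   blocked Bloom filters: `BBF1` receives first occurrences, and a k-mer
   already in `BBF1` is promoted to `BBF2`. After one pass, `BBF2` holds the
   k-mers seen ≥ 2 times — single-occurrence k-mers, overwhelmingly
   sequencing errors, never enter the graph. (With assembled genomes every
   k-mer goes straight to `BBF2`.) Each filter is an array of 512-bit
   blocks; a k-mer's block is chosen from the hash of its *minimizer* (the
   smallest-hashing interior g-mer, g < k), so overlapping k-mers and all
   neighbors of a k-mer probe the same block, and 2-choice placement keeps
   block loads balanced.
2. **Extraction.** A second pass walks each read k-mer still in `BBF2` and
   extends it in both directions while the extension is the unique
   successor/predecessor under Bloom probes, spelling out a unitig. A
   Bloom false positive with probability p would halt extension with
   probability ≈ 6p per k-mer, capping unitigs at a geometric mean length
   of 1/(6p) (167 k-mers at p = 10⁻³); candidate neighbors with no other
   filter neighbor are therefore set aside as *ghost* k-mers and ignored,
   dropping the halt probability to ≈ 42p². Per-k-mer occurrence counters
   (saturating at 2) are filled during the pass, and k-mers below the
   threshold — Bloom artifacts — are deleted afterwards, splitting and
   re-joining unitigs until the graph is exactly the ≥2× k-mer set,
   maximally compacted.

The result is indexed by a dictionary D = (U, M): a unitig array plus a
hash table mapping minimizer g-mers to (unitig, position) anchors, giving
exact k-mer lookup (no false positives or negatives) and dynamic
editing. A color layer attaches an η×|C| presence matrix to each unitig —
bit (i, j) says k-mer i occurs in input dataset j — behind three container
tiers (64-bit word, ≤ 8 KB compressed bitmap, unbounded roaring-style set)
linked to unitigs by a BBHash-style layered hash so that graph edits never
move color data. Queries report, per input sequence, the fraction θ of its
k-mers present (optionally within edit distance 1) and their colors.

## Worked example

Simulate a 3-strain pan-genome (5 kb ancestor, ~1% divergence, 30× reads at
0.5% error), build its colored graph from the assemblies, and screen the
reads of strain 0 against it:

```console
$ ccdbg simulate -o sim --n-colors 3 --genome-len 5000 --seed 7
[simulate] 3 genomes, 4499 reads -> sim

$ ccdbg build sim/color_0*.fasta -o pan -k 31 -g 23 --mode reference --colors --seed 7 -v
[build] k-mers scanned: 14905  filtered: 0  unitigs extracted: 223  FP k-mers removed: 0  ghosts repaired: 0  joins: 0
[color] unitigs: 223  single-colorset: 1.0000  singleton/core/dispensable: 2999/2564/2107
[done] 223 unitigs, 7670 k-mers -> pan.gfa

$ ccdbg query pan.gfa sim/reads_00.fastq -e 0.9 -o hits.tsv
[query] 978/1500 queries present at theta=0.9

$ ccdbg query pan.gfa sim/reads_00.fastq -e 0.9 --inexact -o hits.tsv
[query] 1439/1500 queries present at theta=0.9
```

Reading the numbers: the three 5 kb strains share a graph of 7,670
canonical 31-mers in 223 unitigs; 2,564 k-mers occur in all three strains
(*core*), 2,999 in exactly one (*singleton*), the rest in two
(*dispensable*). At inclusion rate θ = 0.9 only 65% of the reads are
found exactly — a single sequencing error destroys 31 overlapping
k-mers, and at 0.5%/base a read of 100 bp carries ≥ 1 error 39% of the
time — while edit-distance-1 matching recovers them (96%). The graph is
written as GFA 1.0 (`pan.gfa`) with a binary color sidecar
(`pan.colors.bin`) and a readable per-k-mer color table
(`pan.colors.tsv`). `ccdbg update` adds datasets to an existing graph in
place; the result is node-centrically identical to rebuilding from
scratch.

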