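"""Two-pass read filtering: approximate the de Bruijn graph in a BBF.

Reads mode inserts every canonical k-mer of the input into ``BBF1`` on first
sight; a k-mer already present in ``BBF1`` is promoted into ``BBF2``.  After
the pass ``BBF1`` holds k-mers seen at least once and ``BBF2`` k-mers seen
twice or more — single-occurrence k-mers, which are overwhelmingly
sequencing errors, are filtered out.  ``BBF1`` is then discarded and ``BBF2``
is the (approximate, false-positive-bearing) de Bruijn graph handed to
unitig extraction.  A k-mer occurring once lands in ``BBF2`` only through a
``BBF1`` false positive; no k-mer occurring twice is ever missed.

Reference mode (assembled genomes, where single-copy k-mers are real)
inserts every k-mer directly into ``BBF2``; the downstream counter threshold
drops from 2 to 1 accordingly.

Filter sizing needs an up-front estimate of the element count; by default it
is taken from the input file sizes (bases on disk upper-bound distinct
k-mers) and can be overridden.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .bbf import DEFAULT_BITS_PER_ELEMENT, BlockedBloomFilter, BoundKmerFilter
from .io import read_seqs
from .kmers import _kmer_minimizer_stream, acgt_runs, splitmix64

READS_MODE = "reads"
REFERENCE_MODE = "reference"


@dataclass
class FilterStats:
    n_sequences: int = 0
    n_kmers: int = 0
    n_promoted: int = 0  # insertions into BBF2


@dataclass
class FilterResult:
    """BBF2 plus the parameters needed to probe it downstream."""

    bbf2: BlockedBloomFilter
    k: int
    g: int
    seed: int
    mode: str
    stats: FilterStats = field(default_factory=FilterStats)

    def bound(self) -> BoundKmerFilter:
        """The BBF bound to (k, g, seed) for k-mer-string probing."""
        return BoundKmerFilter(self.bbf2, self.k, self.g, self.seed)

    @property
    def counter_threshold(self) -> int:
        """Occurrence count a k-mer must reach to survive FP elimination."""
        return 2 if self.mode == READS_MODE else 1


def estimate_kmers(paths: Sequence) -> int:
    """Crude distinct-k-mer estimate from file sizes (gzip assumed ~3x)."""
    total = 0
    for p in paths:
        p = Path(p)
        size = os.path.getsize(p)
        if p.suffix.lower() == ".gz":
            size *= 3
        if _is_fastq(p):
            size //= 2  # half of a FASTQ is quality strings and headers
        total += size
    return max(1024, total)


def _is_fastq(p: Path) -> bool:
    sfx = [s.lower() for s in p.suffixes if s.lower() != ".gz"]
    return bool(sfx) and sfx[-1] in {".fq", ".fastq"}


def filter_reads(
    read_files: Sequence,
    k: int,
    g: int,
    seed: int = 0,
    expected_kmers: Optional[int] = None,
    bits_per_kmer: float = DEFAULT_BITS_PER_ELEMENT,
) -> FilterResult:
    """Reads-mode two-pass filter; returns BBF2 (k-mers occurring >= 2x).

    Deterministic for a fixed seed and input file order: reads are processed
    in the order given and the BBFs are seeded from ``seed``.
    """
    if expected_kmers is None:
        expected_kmers = estimate_kmers(read_files)
    bbf1 = BlockedBloomFilter.for_expected(
        expected_kmers, bits_per_kmer, seed=splitmix64(seed ^ 0xB1)
    )
    # >= 2x k-mers are roughly the genomic fraction of the distinct set
    bbf2 = BlockedBloomFilter.for_expected(
        max(1024, int(expected_kmers * 0.6)), bits_per_kmer, seed=splitmix64(seed ^ 0xB2)
    )
    stats = FilterStats()
    for _rid, seq in _iter_records(read_files, stats):
        for _start, run in acgt_runs(seq):
            for _pos, canon, mh, _mp, _mc in _kmer_minimizer_stream(run, k, g, seed):
                stats.n_kmers += 1
                if bbf1.may_contain(canon, mh):
                    bbf2.insert(canon, mh)
                    stats.n_promoted += 1
                else:
                    bbf1.insert(canon, mh)
    del bbf1  # discarded: the graph is built from BBF2 alone
    bbf2.n_queries = bbf2.n_positive = 0
    return FilterResult(bbf2, k, g, seed, READS_MODE, stats)


def reference_mode_filter(
    ref_files: Sequence,
    k: int,
    g: int,
    seed: int = 0,
    expected_kmers: Optional[int] = None,
    bits_per_kmer: float = DEFAULT_BITS_PER_ELEMENT,
) -> FilterResult:
    """Reference-mode filter: every k-mer goes straight into BBF2."""
    if expected_kmers is None:
        expected_kmers = estimate_kmers(ref_files)
    bbf2 = BlockedBloomFilter.for_expected(
        expected_kmers, bits_per_kmer, seed=splitmix64(seed ^ 0xB2)
    )
    stats = FilterStats()
    for _rid, seq in _iter_records(ref_files, stats):
        for _start, run in acgt_runs(seq):
            for _pos, canon, mh, _mp, _mc in _kmer_minimizer_stream(run, k, g, seed):
                stats.n_kmers += 1
                bbf2.insert(canon, mh)
                stats.n_promoted += 1
    bbf2.n_queries = bbf2.n_positive = 0
    return FilterResult(bbf2, k, g, seed, REFERENCE_MODE, stats)


def _iter_records(paths: Sequence, stats: FilterStats):
    for p in paths:
        for rid, seq in read_seqs(p):
            stats.n_sequences += 1
            yield rid, seq
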