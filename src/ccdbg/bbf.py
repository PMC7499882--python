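"""Blocked Bloom Filter with double hashing and 2-choice block placement.

A blocked Bloom filter (BBF) is an array of small Bloom filters ("blocks"),
each sized to one CPU cache line (512 bits here), so that all probes of one
element touch a single block.  Which block an element lands in is driven by
the hash of its *minimizer*: overlapping k-mers sharing a minimizer, and all
forward/backward neighbors of a k-mer (neighbor hashing), therefore probe the
same block.  Two candidate blocks are derived from the minimizer hash
(2-choice hashing) and an element is inserted into the less-occupied one,
which balances block load and lowers the false-positive rate.

The f probe positions of an element inside a block come from double hashing
two independent 64-bit hashes of the canonical k-mer:
``probe_i = (h1 + i*h2) mod block_bits``.

Single-writer contract: this implementation is not safe for concurrent
mutation; a parallel implementation would need per-block exclusivity
(the original design uses one spinlock per block).
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from typing import Iterable, Set, Tuple

from .kmers import _MASK64, canonical, splitmix64

BLOCK_BITS_DEFAULT = 512
DEFAULT_BITS_PER_ELEMENT = 14  # target phi ~ 0.7^14 ~ 0.7%

_MAGIC = b"CCBF\x01"


def optimal_f(m: int, n: int) -> int:
    """Optimal number of hash probes for m bits and n elements: (m/n)ln2, >= 1."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return max(1, round((m / n) * math.log(2)))


def expected_fpr(m: int, n: int, f: int) -> float:
    """Expected false-positive rate (1 - e^(-fn/m))^f of a classic Bloom filter."""
    if m <= 0 or n <= 0 or f <= 0:
        raise ValueError("m, n, f must be positive")
    return (1.0 - math.exp(-f * n / m)) ** f


def approx_fpr(m: int, n: int) -> float:
    """The 0.7^(m/n) rule-of-thumb approximation, exposed for reporting."""
    return 0.7 ** (m / n)


class BlockedBloomFilter:
    """Array of 512-bit Bloom blocks with 2-choice minimizer-directed placement.

    Elements are passed as ``(kmer_hash_key, minimizer_hash)`` pairs where
    ``kmer_hash_key`` is any stable integer identity of the canonical k-mer
    (the 2-bit packed canonical word in this package).
    """

    def __init__(
        self,
        nb_blocks: int,
        f: int,
        seed: int = 0,
        block_bits: int = BLOCK_BITS_DEFAULT,
    ) -> None:
        if nb_blocks < 1 or f < 1 or block_bits < 8:
            raise ValueError("invalid BBF geometry")
        self.nb_blocks = nb_blocks
        self.f = f
        self.block_bits = block_bits
        self.seed = seed & _MASK64
        # independent sub-seeds: two for block choice, two for probe bits
        s = self.seed
        self._sb1 = splitmix64(s ^ 0x9E2F)
        self._sb2 = splitmix64(s ^ 0x51D3)
        self._sp1 = splitmix64(s ^ 0xA7C1)
        self._sp2 = splitmix64(s ^ 0x30B9)
        self.blocks = [0] * nb_blocks  # one Python int per 512-bit block
        self.occupancy = [0] * nb_blocks  # exact per-block set-bit counts
        self.n_queries = 0
        self.n_positive = 0

    # -- sizing -----------------------------------------------------------

    @classmethod
    def for_expected(
        cls,
        n_elements: int,
        bits_per_element: float = DEFAULT_BITS_PER_ELEMENT,
        seed: int = 0,
        block_bits: int = BLOCK_BITS_DEFAULT,
    ) -> "BlockedBloomFilter":
        """Size a filter for ``n_elements`` at ``bits_per_element`` (m/n)."""
        n_elements = max(1, n_elements)
        nb = max(2, math.ceil(n_elements * bits_per_element / block_bits))
        f = optimal_f(nb * block_bits, n_elements)
        return cls(nb, f, seed=seed, block_bits=block_bits)

    @property
    def m(self) -> int:
        """Total bits."""
        return self.nb_blocks * self.block_bits

    # -- hashing ----------------------------------------------------------

    def _candidate_blocks(self, min_hash: int) -> Tuple[int, int]:
        return (
            splitmix64(min_hash ^ self._sb1) % self.nb_blocks,
            splitmix64(min_hash ^ self._sb2) % self.nb_blocks,
        )

    def _probe_mask(self, key: int) -> int:
        # double hashing over two 64-bit hashes of the canonical k-mer;
        # the i-th probe term h1 + i*h2 is passed through the finalizer
        # before the mod: raw arithmetic progressions alias each other in a
        # 512-bit block (measured ~2x false-positive inflation), while the
        # finalized positions behave as independent probes
        h1 = splitmix64(key ^ self._sp1)
        h2 = splitmix64(key ^ self._sp2) | 1
        mask = 0
        bb = self.block_bits
        for i in range(self.f):
            mask |= 1 << (splitmix64((h1 + i * h2) & _MASK64) % bb)
        return mask

    # -- operations -------------------------------------------------------

    def insert(self, key: int, min_hash: int) -> int:
        """Insert; returns the block id holding the element afterwards.

        If either candidate block already contains the element no write
        occurs (insertion is idempotent at the bit level).
        """
        b1, b2 = self._candidate_blocks(min_hash)
        mask = self._probe_mask(key)
        if self.blocks[b1] & mask == mask:
            return b1
        if self.blocks[b2] & mask == mask:
            return b2
        b = b1 if self.occupancy[b1] <= self.occupancy[b2] else b2
        old = self.blocks[b]
        new = old | mask
        self.blocks[b] = new
        self.occupancy[b] += (new ^ old).bit_count()
        return b

    def may_contain(self, key: int, min_hash: int) -> bool:
        """True if either candidate block has all f probe bits set.

        Never false for an inserted element (no false negatives); may be
        true for absent elements (false positives).
        """
        self.n_queries += 1
        b1, b2 = self._candidate_blocks(min_hash)
        mask = self._probe_mask(key)
        hit = (self.blocks[b1] & mask == mask) or (self.blocks[b2] & mask == mask)
        if hit:
            self.n_positive += 1
        return hit

    def total_set_bits(self) -> int:
        return sum(self.occupancy)

    # -- checkpointing ----------------------------------------------------

    def dump(self, path, k: int = 0, g: int = 0) -> None:
        """Binary checkpoint (little-endian header + raw block bitmaps)."""
        nbytes = self.block_bits // 8
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<IIQII", k, g, self.seed, self.block_bits, self.f))
            fh.write(struct.pack("<Q", self.nb_blocks))
            for b in self.blocks:
                fh.write(b.to_bytes(nbytes, "little"))

    @classmethod
    def load(cls, path) -> Tuple["BlockedBloomFilter", int, int]:
        """Load a checkpoint; returns (filter, k, g) from the header."""
        with open(path, "rb") as fh:
            if fh.read(len(_MAGIC)) != _MAGIC:
                raise ValueError(f"{path}: not a BBF checkpoint")
            k, g, seed, block_bits, f = struct.unpack("<IIQII", fh.read(24))
            (nb,) = struct.unpack("<Q", fh.read(8))
            bbf = cls(nb, f, seed=seed, block_bits=block_bits)
            nbytes = block_bits // 8
            for i in range(nb):
                v = int.from_bytes(fh.read(nbytes), "little")
                bbf.blocks[i] = v
                bbf.occupancy[i] = v.bit_count()
        return bbf, k, g


@dataclass
class ExactMembershipFilter:
    """Exact k-mer set exposing the probing interface of a bound BBF.

    Serves as an error-free stand-in for a Bloom filter in tests and probe
    instrumentation: membership answers are exact (no false positives) and
    every probe is counted.
    """

    kmers: Set[str] = field(default_factory=set)  # canonical k-mer strings
    n_queries: int = 0
    n_positive: int = 0

    def add(self, kmer: str) -> None:
        self.kmers.add(canonical(kmer))

    def update(self, kmers: Iterable[str]) -> None:
        for x in kmers:
            self.add(x)

    def may_contain_kmer(self, kmer: str) -> bool:
        self.n_queries += 1
        hit = canonical(kmer) in self.kmers
        if hit:
            self.n_positive += 1
        return hit


class BoundKmerFilter:
    """A BBF bound to (k, g, seed): probes by k-mer string.

    Computes the canonical packed key and minimizer hash a raw
    :class:`BlockedBloomFilter` needs, so graph-construction code can probe
    with plain k-mer strings.  Shares the query counters of the wrapped
    filter through ``n_queries`` / ``n_positive``.
    """

    def __init__(self, bbf: BlockedBloomFilter, k: int, g: int, minimizer_seed: int) -> None:
        self.bbf = bbf
        self.k = k
        self.g = g
        self.minimizer_seed = minimizer_seed

    def _key_and_minhash(self, kmer: str) -> Tuple[int, int]:
        from .kmers import _interior_records, canonical_bits, pack

        key = canonical_bits(pack(kmer), self.k)
        mh = min(_interior_records(kmer, self.g, self.minimizer_seed))[0]
        return key, mh

    def insert_kmer(self, kmer: str) -> int:
        key, mh = self._key_and_minhash(kmer)
        return self.bbf.insert(key, mh)

    def may_contain_kmer(self, kmer: str) -> bool:
        key, mh = self._key_and_minhash(kmer)
        return self.bbf.may_contain(key, mh)

    @property
    def n_queries(self) -> int:
        return self.bbf.n_queries

    @property
    def n_positive(self) -> int:
        return self.bbf.n_positive
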