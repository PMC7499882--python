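"""Color layer of the ccdBG: per-unitig presence matrices in tiered containers.

Each unitig with eta k-mers owns a binary matrix of eta rows (k-mer
positions) by |C| columns (input datasets): bit (i, j) set means k-mer i of
the unitig occurs in dataset j.  Matrices are kept in one of three container
tiers by sparsity/size:

* ``word``    — a single 64-bit word: either one (i, j) tuple or the full
                matrix when eta x |C| <= 62 (2 bits of metadata);
* ``medium``  — a compressed bitmap addressing up to 65488 cells within at
                most 8 KB, serialized as whichever of bit vector / sorted
                cell list / run-length list is smallest;
* ``roaring`` — an unbounded roaring-style container for larger matrices,
                held here as an uncompressed set of 32-bit cell keys.

Membership answers are identical across tiers; a container upgrades in
place when its matrix outgrows the current tier and logical content is
preserved across upgrades.

Containers are not addressed by unitig id.  An array ``O`` of containers is
linked to unitigs through a short cascade of seeded hash functions ``H``
applied to the unitig's head k-mer (first unclaimed slot wins), with a plain
hash table ``K`` as the fallback after |H| misses — a layered scheme in the
spirit of minimal-perfect-hash construction.  Claimed slots never move, so
graph edits that do not touch a unitig's colors never move its container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os.path import basename
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

from .index import CdbgIndex
from .kmers import _hash_packed_canonical, canonical_bits, pack

WORD = "word"
MEDIUM = "medium"
ROARING = "roaring"

WORD_MATRIX_BITS = 62  # 2 bits of a 64-bit word reserved for metadata
MEDIUM_MAX_CELLS = 65488  # 8 KB bitmap minus 48 bits of metadata
MEDIUM_MAX_BYTES = 8192
DEFAULT_N_HASHES = 16


class ColorContainer:
    """A set of (row, color) cells behind the three-tier encoding."""

    __slots__ = ("cells", "eta", "n_colors")

    def __init__(self, eta: int = 1, n_colors: int = 1) -> None:
        self.cells: Set[Tuple[int, int]] = set()
        self.eta = eta
        self.n_colors = n_colors

    def add(self, i: int, j: int, eta: int, n_colors: int) -> None:
        if not (0 <= i < eta and 0 <= j < n_colors):
            raise IndexError(f"cell ({i}, {j}) outside {eta} x {n_colors} matrix")
        self.eta = max(self.eta, eta)
        self.n_colors = max(self.n_colors, n_colors)
        self.cells.add((i, j))

    def contains(self, i: int, j: int) -> bool:
        return (i, j) in self.cells

    def row(self, i: int) -> Set[int]:
        return {j for r, j in self.cells if r == i}

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def matrix_bits(self) -> int:
        return self.eta * self.n_colors

    @property
    def tier(self) -> str:
        if len(self.cells) <= 1 or self.matrix_bits <= WORD_MATRIX_BITS:
            return WORD
        if self.matrix_bits <= MEDIUM_MAX_CELLS:
            return MEDIUM
        return ROARING

    def serialized_size(self) -> int:
        """Bytes of the smallest encoding of the current tier."""
        n = len(self.cells)
        if self.tier == WORD:
            return 8
        if self.tier == MEDIUM:
            # 6 bytes metadata + smallest of the three medium forms
            bitvec = math.ceil(self.matrix_bits / 8)
            sorted_list = 2 * n
            rle = 4 * self._n_runs()
            return 6 + min(bitvec, sorted_list, rle)
        return 16 + 4 * n  # roaring-style: 32-bit keys

    def medium_form(self) -> str:
        """Which medium representation the serializer would pick."""
        bitvec = math.ceil(self.matrix_bits / 8)
        sorted_list = 2 * len(self.cells)
        rle = 4 * self._n_runs()
        best = min(bitvec, sorted_list, rle)
        if best == bitvec:
            return "bitvector"
        return "sorted_list" if best == sorted_list else "run_length"

    def _n_runs(self) -> int:
        keys = sorted(i * self.n_colors + j for i, j in self.cells)
        runs = 0
        prev = None
        for v in keys:
            if prev is None or v != prev + 1:
                runs += 1
            prev = v
        return runs


@dataclass
class ColorStats:
    n_kmers: int = 0
    n_singleton: int = 0  # exactly one color
    n_core: int = 0  # all colors
    n_dispensable: int = 0  # more than one but not all
    n_unitigs: int = 0
    n_single_colorset_unitigs: int = 0  # one color set shared by all k-mers

    @property
    def single_colorset_fraction(self) -> float:
        return self.n_single_colorset_unitigs / self.n_unitigs if self.n_unitigs else 0.0


class ColorStore:
    """Container array O + hash cascade H + fallback table K."""

    def __init__(
        self,
        n_colors: int,
        color_names: Optional[Sequence[str]] = None,
        seed: int = 0,
        n_hashes: int = DEFAULT_N_HASHES,
    ) -> None:
        self.n_colors = n_colors
        self.color_names: List[str] = list(
            color_names if color_names is not None else (str(i) for i in range(n_colors))
        )
        self.H: List[int] = [
            _hash_packed_canonical(i + 1, seed ^ 0xC0105) for i in range(n_hashes)
        ]
        self.O: List[Optional[ColorContainer]] = [None] * 16
        self.K: Dict[str, int] = {}
        self._k_by_slot: Dict[int, str] = {}
        self._n_assigned = 0

    @property
    def capacity(self) -> int:
        return len(self.O)

    def _slot_hash(self, head_kmer: str, layer_seed: int) -> int:
        key = canonical_bits(pack(head_kmer), len(head_kmer))
        return _hash_packed_canonical(key, layer_seed)

    def assign_slot(self, head_kmer: str) -> int:
        """Claim a container slot for a unitig identified by its head k-mer.

        Seeds H[0], H[1], ... are tried in order against the current slot
        space; the first unclaimed hit wins.  After |H| collisions the
        mapping goes into K against a freshly appended slot.  Slot indices,
        once claimed, are never moved (the array grows by doubling, only at
        the tail).
        """
        if 2 * (self._n_assigned + 1) > self.capacity:
            self.O.extend([None] * self.capacity)  # doubling; claimed slots keep indices
        for hs in self.H:
            s = self._slot_hash(head_kmer, hs) % self.capacity
            if self.O[s] is None:
                self.O[s] = ColorContainer(n_colors=self.n_colors)
                self._n_assigned += 1
                return s
        s = len(self.O)
        self.O.append(ColorContainer(n_colors=self.n_colors))
        self.K[head_kmer] = s
        self._k_by_slot[s] = head_kmer
        self._n_assigned += 1
        return s

    def release_slot(self, slot: int) -> None:
        if self.O[slot] is None:
            raise KeyError(f"slot {slot} is not claimed")
        self.O[slot] = None
        self._n_assigned -= 1
        head = self._k_by_slot.pop(slot, None)
        if head is not None:
            del self.K[head]

    def container(self, slot: int) -> ColorContainer:
        c = self.O[slot]
        if c is None:
            raise KeyError(f"slot {slot} is not claimed")
        return c

    def add_pair(self, slot: int, i: int, j: int, eta: int) -> None:
        self.container(slot).add(i, j, eta, self.n_colors)

    def contains_pair(self, slot: int, i: int, j: int) -> bool:
        return self.container(slot).contains(i, j)

    def pairs(self, slot: int) -> Iterator[Tuple[int, int]]:
        return iter(self.container(slot))

    def add_colors(self, names: Sequence[str]) -> int:
        """Append new color columns (update mode); returns first new id."""
        first = self.n_colors
        self.n_colors += len(names)
        self.color_names.extend(names)
        for c in self.O:
            if c is not None:
                c.n_colors = self.n_colors
        return first


# -- graph-level operations ------------------------------------------------


def add_color(D: CdbgIndex, id_u: int, i: int, j: int) -> None:
    """Set color j on k-mer row i of a unitig, assigning a slot if needed."""
    store: ColorStore = D.colors
    if store is None:
        raise ValueError("graph has no color layer attached")
    rec = D.unitig(id_u)
    if not 0 <= i < rec.n_kmers:
        raise IndexError(f"row {i} outside unitig of {rec.n_kmers} k-mers")
    if rec.color_slot is None:
        rec.color_slot = store.assign_slot(rec.seq[: D.k])
    store.add_pair(rec.color_slot, i, j, rec.n_kmers)


def colors_of(D: CdbgIndex, x: str) -> Set[int]:
    """Exact color subset of k-mer ``x``; KeyError if absent."""
    store: ColorStore = D.colors
    if store is None:
        raise ValueError("graph has no color layer attached")
    hit = D.lookup_kmer(x)
    if hit is None:
        raise KeyError(f"k-mer {x} not in the graph")
    rec = D.unitig(hit.id_u)
    if rec.color_slot is None:
        return set()
    return store.container(rec.color_slot).row(hit.offset)


def color_graph(
    D: CdbgIndex, color_files: Sequence, strict: bool = True, first_color: int = 0
) -> ColorStats:
    """Stream each input file as one color and set per-k-mer presence bits.

    ``strict`` (reference mode) treats a file k-mer missing from the graph
    as a consistency error; reads mode passes ``strict=False`` and skips
    them (they were filtered out).  ``first_color`` supports update mode,
    where new files extend an existing color table.
    """
    from .io import read_seqs
    from .kmers import acgt_runs

    if D.colors is None:
        D.colors = ColorStore(
            n_colors=first_color + len(color_files),
            color_names=[basename(str(f)) for f in color_files],
            seed=D.seed,
        )
    k = D.k
    store: ColorStore = D.colors
    for c, path in enumerate(color_files, start=first_color):
        for _rid, seq in read_seqs(path):
            for _s, run in acgt_runs(seq):
                for i in range(len(run) - k + 1):
                    x = run[i : i + k]
                    hit = D.lookup_kmer(x)
                    if hit is None:
                        if strict:
                            raise ValueError(
                                f"{path}: k-mer {x} absent from the graph in reference mode"
                            )
                        continue
                    rec = D.unitig(hit.id_u)
                    if rec.color_slot is None:
                        rec.color_slot = store.assign_slot(rec.seq[:k])
                    store.add_pair(rec.color_slot, hit.offset, c, rec.n_kmers)
    return color_stats(D)


def color_stats(D: CdbgIndex) -> ColorStats:
    """Singleton/core/dispensable k-mer partition and unitig color summary."""
    store: ColorStore = D.colors
    stats = ColorStats()
    n_colors = store.n_colors if store else 0
    for u in D.unitigs():
        stats.n_unitigs += 1
        rows: Dict[int, Set[int]] = {i: set() for i in range(u.n_kmers)}
        if store is not None and u.color_slot is not None:
            for i, j in store.pairs(u.color_slot):
                rows[i].add(j)
        distinct = {frozenset(s) for s in rows.values()}
        if len(distinct) == 1:
            stats.n_single_colorset_unitigs += 1
        for s in rows.values():
            stats.n_kmers += 1
            if len(s) == 1:
                stats.n_singleton += 1
            elif n_colors > 1 and len(s) == n_colors:
                stats.n_core += 1
            elif len(s) > 1:
                stats.n_dispensable += 1
    return stats
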