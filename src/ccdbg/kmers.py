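"""Canonical k-mer arithmetic and random-order minimizer selection.

A k-mer is identified with the lexicographically smaller of itself and its
reverse complement (its *canonical* form), so that both strands of a DNA
sequence index identically.  Minimizers are g-mers (g < k) selected by a
seeded random order: every g-mer is ranked by a 64-bit hash of its canonical
form and the smallest-ranked interior g-mer of a k-mer is its minimizer.
The first and last g-mer of a k-mer are excluded from candidacy (neighbor
hashing): with this restriction all forward (resp. backward) neighbors of a
k-mer are guaranteed to share a minimizer, which downstream keeps their
Bloom-filter probes inside a single block.

Internally sequences are 2-bit packed (A=0, C=1, G=2, T=3, big-endian within
the word) so that integer order equals lexicographic order and reverse
complementation is pure bit arithmetic.  All per-position work is rolling:
iterating the minimizers of every k-mer of a sequence is linear in the
sequence length via an ascending-minima (monotone deque) sweep.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator, List, Tuple

_MASK64 = (1 << 64) - 1
_COMP = str.maketrans("ACGT", "TGCA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"

DNA_ALPHABET = "ACGT"


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains symbols outside {A,C,G,T}."""


def _check_acgt(s: str) -> None:
    for ch in s:
        if ch not in _CODE:
            raise InvalidSequenceError(f"non-ACGT symbol {ch!r} in sequence")


def splitmix64(x: int) -> int:
    """64-bit finalizer used as the random-order hash throughout."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def revcomp(s: str) -> str:
    """Reverse complement of ``s``; an involution over {A,C,G,T} strings."""
    _check_acgt(s)
    return s.translate(_COMP)[::-1]


def canonical(s: str) -> str:
    """Lexicographically smaller of ``s`` and its reverse complement."""
    _check_acgt(s)
    r = s.translate(_COMP)[::-1]
    return s if s <= r else r


def pack(s: str) -> int:
    """2-bit pack ``s`` big-endian; integer order matches lexicographic."""
    v = 0
    for ch in s:
        v = (v << 2) | _CODE[ch]
    return v


def unpack(v: int, length: int) -> str:
    out = []
    for i in range(length):
        out.append(_BASE[(v >> (2 * (length - 1 - i))) & 3])
    return "".join(out)


def revcomp_bits(v: int, length: int) -> int:
    """Reverse complement of a packed word (complement code c -> 3-c)."""
    r = 0
    for _ in range(length):
        r = (r << 2) | (3 - (v & 3))
        v >>= 2
    return r


def canonical_bits(v: int, length: int) -> int:
    r = revcomp_bits(v, length)
    return v if v <= r else r


@dataclass(frozen=True)
class Kmer:
    """A fixed-length DNA word with a canonical orientation."""

    seq: str
    k: int

    def __post_init__(self) -> None:
        if len(self.seq) != self.k:
            raise ValueError(f"sequence length {len(self.seq)} != k={self.k}")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        _check_acgt(self.seq)

    @property
    def canonical(self) -> str:
        return canonical(self.seq)


@dataclass(frozen=True)
class Minimizer:
    """An interior g-mer of a k-mer, ranked by seeded canonical hash.

    ``pos`` is the 0-based start offset of the chosen occurrence within the
    host word (k-mer or longer sequence, depending on the producing call).
    """

    gmer: str  # canonical form
    hash: int
    pos: int
    g: int


def gmer_hash(gmer: str, seed: int) -> int:
    """Seeded 64-bit hash of the canonical form of ``gmer``.

    A g-mer and its reverse complement hash identically.  For g <= 31 the
    packed canonical word fits a 64-bit value; longer g-mers fold through
    Python's arbitrary-precision integers before finalization.
    """
    _check_acgt(gmer)
    return _hash_packed_canonical(canonical_bits(pack(gmer), len(gmer)), seed)


def _hash_packed_canonical(canon: int, seed: int) -> int:
    h = canon
    while h > _MASK64:  # fold g-mers longer than 31 bases
        h = (h & _MASK64) ^ (h >> 64)
    return splitmix64(h ^ (seed & _MASK64))


def _interior_records(x: str, g: int, seed: int) -> List[Tuple[int, int, int]]:
    """(hash, pos, canon_packed) for interior g-mers of ``x``, position order.

    String-free hot-path core behind :func:`interior_gmers`,
    :func:`minimizer_of` and dictionary lookup.
    """
    k = len(x)
    if not 1 <= g <= k - 2:
        raise ValueError(f"need 1 <= g <= k-2, got g={g}, k={k}")
    _check_acgt(x)
    gmask = (1 << (2 * g)) - 1
    shift = 2 * (g - 1)
    fwd = pack(x[0:g])
    rc = revcomp_bits(fwd, g)
    code = _CODE
    out: List[Tuple[int, int, int]] = []
    for p in range(1, k - g):  # interior offsets 1 .. k-g-1
        c = code[x[p + g - 1]]
        fwd = ((fwd << 2) | c) & gmask
        rc = (rc >> 2) | ((3 - c) << shift)
        canon = fwd if fwd <= rc else rc
        out.append((_hash_packed_canonical(canon, seed), p, canon))
    return out


def interior_gmers(x: str, g: int, seed: int) -> List[Minimizer]:
    """All interior g-mers of k-mer ``x`` in position order.

    Interior start offsets are 1 .. k-g-1 (the first and last g-mer are
    excluded by the neighbor-hashing rule).
    """
    return [Minimizer(unpack(c, g), h, p, g) for h, p, c in _interior_records(x, g, seed)]


def minimizer_of(x, g: int, seed: int) -> Minimizer:
    """Minimizer of k-mer ``x``: smallest-hash interior g-mer, leftmost on ties."""
    if isinstance(x, Kmer):
        x = x.seq
    h, p, canon = min(_interior_records(x, g, seed))
    return Minimizer(unpack(canon, g), h, p, g)


def iterate_minimizers(seq: str, k: int, g: int, seed: int) -> Iterator[Tuple[int, Minimizer]]:
    """Yield ``(kmer_index, Minimizer)`` for every k-mer of ``seq`` in order.

    Equivalent to calling :func:`minimizer_of` per k-mer but linear in
    ``len(seq)`` via an ascending-minima sweep over g-mer hashes.  Sequences
    shorter than k yield nothing.
    """
    for pos, _canon, mh, mpos, mcanon in _kmer_minimizer_stream(seq, k, g, seed):
        yield pos, Minimizer(unpack(mcanon, g), mh, mpos - pos, g)


def _kmer_minimizer_stream(
    seq: str, k: int, g: int, seed: int
) -> Iterator[Tuple[int, int, int, int, int]]:
    """Rolling core: yields (kmer_pos, kmer_canon_packed, min_hash,
    min_abs_pos, min_gmer_canon_packed) per k-mer of ``seq``.

    ``min_abs_pos`` is the g-mer start offset in ``seq`` (not in the k-mer).
    Hot path shared by read filtering and graph construction.
    """
    n = len(seq)
    if n < k:
        return
    if not 1 <= g <= k - 2:
        raise ValueError(f"need 1 <= g <= k-2, got g={g}, k={k}")
    _check_acgt(seq)
    code = _CODE
    kmask = (1 << (2 * k)) - 1
    gmask = (1 << (2 * g)) - 1
    kshift = 2 * (k - 1)
    gshift = 2 * (g - 1)

    kf = pack(seq[0:k])
    kr = revcomp_bits(kf, k)
    gf = pack(seq[0:g])
    gr = revcomp_bits(gf, g)

    # window of g-mer records (hash, abs_pos, canon) kept hash-ascending;
    # ties keep the earlier (leftmost) record at the front
    win: deque = deque()

    def push(j: int, gfv: int, grv: int) -> None:
        canon = gfv if gfv <= grv else grv
        h = _hash_packed_canonical(canon, seed)
        while win and win[-1][0] > h:
            win.pop()
        win.append((h, j, canon))

    # g-mers at offsets 1 .. k-g-1 feed the first k-mer's window
    for j in range(1, k - g):
        c = code[seq[j + g - 1]]
        gf = ((gf << 2) | c) & gmask
        gr = (gr >> 2) | ((3 - c) << gshift)
        push(j, gf, gr)

    i = 0
    while True:
        h, j, canon = win[0]
        yield i, (kf if kf <= kr else kr), h, j, canon
        if i + k >= n:
            return
        c = code[seq[i + k]]
        kf = ((kf << 2) | c) & kmask
        kr = (kr >> 2) | ((3 - c) << kshift)
        # admit the g-mer at offset i+k-g (the next k-mer's last interior
        # offset); it ends at seq[i+k-1], one base short of the k-mer's end
        cg = code[seq[i + k - 1]]
        gf = ((gf << 2) | cg) & gmask
        gr = (gr >> 2) | ((3 - cg) << gshift)
        i += 1
        push(i + k - g - 1, gf, gr)
        while win[0][1] < i + 1:  # expel offsets left of the interior window
            win.popleft()


def acgt_runs(seq: str) -> Iterator[Tuple[int, str]]:
    """Maximal runs of A/C/G/T in ``seq`` as (start, run) pairs.

    Input sequences are split at any non-ACGT character and each run is
    processed independently; lowercase bases are accepted and upcased.
    """
    seq = seq.upper()
    start = None
    for i, ch in enumerate(seq):
        if ch in _CODE:
            if start is None:
                start = i
        else:
            if start is not None:
                yield start, seq[start:i]
                start = None
    if start is not None:
        yield start, seq[start:]


def iterate_kmers(seq: str, k: int) -> Iterator[str]:
    """All k-mer substrings of ``seq`` in order (no canonicalization)."""
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]
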