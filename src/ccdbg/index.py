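"""The compacted de Bruijn graph dictionary D = (U, M).

``U`` is an array of unitig records and ``M`` a hash table mapping canonical
minimizer g-mers to lists of ``(unitig id, position)`` tuples.  Every k-mer
of every unitig contributes its minimizer occurrence to ``M``; exact k-mer
lookup extracts the query's minimizer, fetches the candidate anchor list and
string-compares the query (and its reverse complement) against each anchored
unitig.  Unlike the Bloom-filter approximation this dictionary is exact:
lookups have no false positives and no false negatives.

Recurrent minimizers (g-mers occurring >= t times across the unitig set,
typical of homopolymers and tandem repeats) would make anchor lists
unboundedly long; insertion and lookup therefore fall back to the next
interior g-mer in ascending hash order whose list is still short, and only
when every interior g-mer of a k-mer is recurrent is the list allowed to
overflow past t.

Unitig identifiers are stable for the lifetime of a record; freed slots are
tombstoned and recycled through a free list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

from .kmers import (
    Minimizer,
    _interior_records,
    _kmer_minimizer_stream,
    canonical,
    revcomp,
    unpack,
)

DEFAULT_K = 31
DEFAULT_G = 23  # k - 8 for the default k
DEFAULT_T = 64  # recurrent-minimizer threshold

FORWARD = "+"
REVERSE = "-"


@dataclass
class UnitigRecord:
    """One unitig: sequence, per-k-mer occurrence counters, color slot.

    ``counters`` saturate at 2 — downstream false-positive elimination only
    distinguishes {0, 1} from >= 2 occurrences.  ``entries`` records exactly
    the ``(minimizer key, position)`` pairs this unitig contributed to M so
    removal can be done without re-deriving table state.
    """

    id_u: int
    seq: str
    counters: bytearray
    color_slot: Optional[int] = None
    entries: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_kmers(self) -> int:
        return len(self.counters)


@dataclass(frozen=True)
class KmerHit:
    id_u: int
    offset: int
    strand: str  # FORWARD if the query matches the stored orientation


class CdbgIndex:
    """Minimizer-indexed unitig dictionary with exact k-mer lookup."""

    def __init__(self, k: int = DEFAULT_K, g: int = DEFAULT_G, seed: int = 0, t: int = DEFAULT_T):
        if not 1 <= g <= k - 2:
            raise ValueError(f"need 1 <= g <= k-2, got g={g}, k={k}")
        if t < 1:
            raise ValueError("t must be >= 1")
        self.k = k
        self.g = g
        self.seed = seed
        self.t = t
        self._units: Dict[int, UnitigRecord] = {}
        self._minimizers: Dict[int, List[Tuple[int, int]]] = {}
        self._free: List[int] = []
        self._next_id = 0
        self.colors = None  # optional ColorStore attached by the color layer
        self.n_anchor_probes = 0  # instrumentation: anchor comparisons done

    # -- basic accessors --------------------------------------------------

    def __len__(self) -> int:
        return len(self._units)

    @property
    def n_unitigs(self) -> int:
        return len(self._units)

    def unitig(self, id_u: int) -> UnitigRecord:
        try:
            return self._units[id_u]
        except KeyError:
            raise KeyError(f"unknown or removed unitig id {id_u}") from None

    def unitigs(self) -> Iterator[UnitigRecord]:
        return iter(list(self._units.values()))

    def kmer_at(self, id_u: int, pos: int) -> str:
        u = self.unitig(id_u)
        return u.seq[pos : pos + self.k]

    def iter_kmers(self) -> Iterator[Tuple[str, int, int]]:
        """Yield (canonical k-mer, id_u, position) over all live unitigs."""
        k = self.k
        for u in self.unitigs():
            for p in range(u.n_kmers):
                yield canonical(u.seq[p : p + k]), u.id_u, p

    def kmer_set(self) -> Set[str]:
        return {x for x, _, _ in self.iter_kmers()}

    @property
    def n_kmers(self) -> int:
        return sum(u.n_kmers for u in self._units.values())

    # -- minimizer selection ----------------------------------------------

    def _list_len(self, key: int) -> int:
        lst = self._minimizers.get(key)
        return len(lst) if lst else 0

    def select_insert_minimizer(self, x: str) -> Minimizer:
        """Minimizer under which k-mer ``x`` would be indexed right now.

        The true minimizer if its anchor list holds < t tuples, else the
        smallest-hash interior g-mer with a non-recurrent list; if every
        interior g-mer is recurrent the true minimizer is returned and the
        caller may overflow its list.
        """
        recs = sorted(_interior_records(x, self.g, self.seed))
        for h, p, key in recs:
            if self._list_len(key) < self.t:
                return Minimizer(unpack(key, self.g), h, p, self.g)
        h, p, key = recs[0]
        return Minimizer(unpack(key, self.g), h, p, self.g)

    # -- insertion / removal ----------------------------------------------

    def insert_unitig(self, seq: str, counters: Optional[bytearray] = None) -> int:
        """Insert a unitig; index every k-mer's minimizer occurrence in M.

        The sequence is stored strand-canonically (the lexicographically
        smaller of ``seq`` and its reverse complement); supplied counters are
        reoriented alongside.  Returns the new unitig id.
        """
        k, g = self.k, self.g
        if len(seq) < k:
            raise ValueError(f"unitig shorter than k: {len(seq)} < {k}")
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            if counters is not None:
                counters = bytearray(reversed(counters))
        eta = len(seq) - k + 1
        if counters is None:
            counters = bytearray(eta)
        elif len(counters) != eta:
            raise ValueError("counters length must equal the k-mer count")

        id_u = self._free.pop() if self._free else self._next_id
        if not self._free and id_u == self._next_id:
            self._next_id += 1

        entry_set: Set[Tuple[int, int]] = set()
        pending: Dict[int, int] = {}  # key -> tuples queued by this insertion

        def cur_len(key: int) -> int:
            return self._list_len(key) + pending.get(key, 0)

        for p, _canon, mh, mpos, mcanon in _kmer_minimizer_stream(seq, k, g, self.seed):
            if cur_len(mcanon) < self.t:
                chosen = (mcanon, mpos)
            else:  # recurrent: rescan this k-mer's interior g-mers in hash order
                chosen = None
                recs = sorted(_interior_records(seq[p : p + k], g, self.seed))
                for _h, q, key in recs:
                    if cur_len(key) < self.t:
                        chosen = (key, p + q)
                        break
                if chosen is None:  # every interior g-mer recurrent: overflow permitted
                    _h, q, key = recs[0]
                    chosen = (key, p + q)
            if chosen not in entry_set:
                entry_set.add(chosen)
                pending[chosen[0]] = pending.get(chosen[0], 0) + 1

        entries = sorted(entry_set)
        for key, pos in entries:
            self._minimizers.setdefault(key, []).append((id_u, pos))
        self._units[id_u] = UnitigRecord(id_u, seq, counters, entries=entries)
        return id_u

    def remove_unitig(self, id_u: int) -> None:
        """Remove a unitig and every M tuple that references it."""
        rec = self.unitig(id_u)
        for key, pos in rec.entries:
            lst = self._minimizers[key]
            lst.remove((id_u, pos))
            if not lst:
                del self._minimizers[key]
        if self.colors is not None and rec.color_slot is not None:
            self.colors.release_slot(rec.color_slot)
        del self._units[id_u]
        self._free.append(id_u)

    # -- lookup ------------------------------------------------------------

    def lookup_kmer(self, x: str) -> Optional[KmerHit]:
        """Exact k-mer lookup; returns (id, offset, strand) or None.

        The query and its reverse complement are anchored in candidate
        unitigs at the recorded minimizer positions and string-compared.
        When an anchor list is recurrent (>= t tuples) the search continues
        with the query's next interior g-mers in ascending hash order.
        """
        k, g = self.k, self.g
        if len(x) != k:
            raise ValueError(f"query length {len(x)} != k={k}")
        recs = _interior_records(x, g, self.seed)
        # fast path: the true minimizer resolves most queries without a sort
        key0 = min(recs)[2]
        lst = self._minimizers.get(key0)
        n0 = len(lst) if lst else 0
        xr = None
        if lst:
            xr = revcomp(x)
            hit = self._anchor_scan(x, xr, key0, [p for _h, p, c in recs if c == key0], lst)
            if hit is not None:
                return hit
        if n0 < self.t:
            return None  # non-recurrent: insertion could not have used a later g-mer

        # recurrent: rescan remaining candidates in ascending hash order
        if xr is None:
            xr = revcomp(x)
        occ: Dict[int, List[int]] = {}
        order: List[int] = []
        for _h, p, key in sorted(recs):
            if key not in occ:
                occ[key] = []
                order.append(key)
            occ[key].append(p)
        seen_recurrent = False
        for key in order:
            if key == key0:
                seen_recurrent = True
                continue
            lst = self._minimizers.get(key)
            if lst:
                hit = self._anchor_scan(x, xr, key, occ[key], lst)
                if hit is not None:
                    return hit
            n = len(lst) if lst else 0
            if n >= self.t:
                seen_recurrent = True
            elif not seen_recurrent:
                return None
        return None

    def lookup_kmer_hinted(self, x: str, min_key: int, min_offset: int) -> Optional[KmerHit]:
        """Lookup with a precomputed true-minimizer hint (hot path).

        ``min_key``/``min_offset`` are the canonical packed g-mer and its
        offset within ``x`` as produced by the rolling minimizer stream.
        Falls back to the full lookup when the hinted anchor scan misses
        (repeated minimizer occurrences, recurrent fallback, absence).
        """
        lst = self._minimizers.get(min_key)
        if not lst:
            return None  # true minimizer absent and non-recurrent: k-mer absent
        hit = self._anchor_scan(x, revcomp(x), min_key, [min_offset], lst)
        if hit is not None:
            return hit
        return self.lookup_kmer(x)

    def _anchor_scan(self, x: str, xr: str, key: int, offsets: List[int], lst) -> Optional[KmerHit]:
        """Anchor x/revcomp(x) at each recorded (unitig, position) tuple."""
        k, g = self.k, self.g
        for id_u, p_m in lst:
            useq = self._units[id_u].seq
            ulen = len(useq)
            for q in offsets:
                self.n_anchor_probes += 1
                start = p_m - q
                if 0 <= start <= ulen - k and useq[start : start + k] == x:
                    return KmerHit(id_u, start, FORWARD)
                start = p_m - (k - g - q)
                if 0 <= start <= ulen - k and useq[start : start + k] == xr:
                    return KmerHit(id_u, start, REVERSE)
        return None

    def contains_kmer(self, x: str) -> bool:
        return self.lookup_kmer(x) is not None

    # -- counters ----------------------------------------------------------

    def increment_counter(self, id_u: int, pos: int) -> None:
        """Saturating increment (cap 2) of one k-mer occurrence counter."""
        c = self._units[id_u].counters
        if c[pos] < 2:
            c[pos] += 1

    # -- graph-neighbor views ---------------------------------------------

    def graph_successors(self, kmer: str) -> List[Tuple[str, KmerHit]]:
        """The (base, hit) pairs of kmer's successors present in the graph."""
        out = []
        for a in "ACGT":
            cand = kmer[1:] + a
            hit = self.lookup_kmer(cand)
            if hit is not None:
                out.append((cand, hit))
        return out

    def graph_predecessors(self, kmer: str) -> List[Tuple[str, KmerHit]]:
        out = []
        for a in "ACGT":
            cand = a + kmer[:-1]
            hit = self.lookup_kmer(cand)
            if hit is not None:
                out.append((cand, hit))
        return out

    # -- structural edits (counter- and color-preserving) ------------------

    def _collect_color_pairs(self, rec: UnitigRecord):
        if self.colors is None or rec.color_slot is None:
            return None
        return list(self.colors.pairs(rec.color_slot))

    def split_unitig(self, id_u: int, keep_runs: List[Tuple[int, int]]) -> List[int]:
        """Replace a unitig by the k-mer runs [a, b] (inclusive, k-mer indices).

        Counters and per-k-mer color sets follow their k-mers by position.
        Returns the new unitig ids (a run equal to the full range reinserts
        the unitig unchanged).
        """
        rec = self.unitig(id_u)
        k = self.k
        pairs = self._collect_color_pairs(rec)
        self.remove_unitig(id_u)
        new_ids: List[int] = []
        for a, b in keep_runs:
            if not 0 <= a <= b < rec.n_kmers:
                raise ValueError(f"bad k-mer run [{a}, {b}] for unitig of {rec.n_kmers} k-mers")
            nid = self.insert_unitig(rec.seq[a : b + k], bytearray(rec.counters[a : b + 1]))
            new_ids.append(nid)
            if pairs is not None:
                sub = [(i - a, j) for i, j in pairs if a <= i <= b]
                if sub:
                    self._attach_pairs(nid, rec.seq[a : b + k], sub)
        return new_ids

    def merge_unitigs(self, id_a: int, orient_a: str, id_b: int, orient_b: str) -> int:
        """Merge two unitigs joined tail(a)->head(b) in the given orientations."""
        ra, rb = self.unitig(id_a), self.unitig(id_b)
        k = self.k
        sa = ra.seq if orient_a == FORWARD else revcomp(ra.seq)
        sb = rb.seq if orient_b == FORWARD else revcomp(rb.seq)
        if sa[-(k - 1) :] != sb[: k - 1]:
            raise ValueError("unitigs do not overlap by k-1")
        ca = ra.counters if orient_a == FORWARD else bytearray(reversed(ra.counters))
        cb = rb.counters if orient_b == FORWARD else bytearray(reversed(rb.counters))
        pairs_a = self._collect_color_pairs(ra)
        pairs_b = self._collect_color_pairs(rb)
        eta_a = ra.n_kmers

        def _remap(pairs, rec, orient, shift):
            if pairs is None:
                return []
            last = rec.n_kmers - 1
            return [((i if orient == FORWARD else last - i) + shift, j) for i, j in pairs]

        merged_pairs = _remap(pairs_a, ra, orient_a, 0) + _remap(pairs_b, rb, orient_b, eta_a)
        merged_seq = sa + sb[k - 1 :]
        self.remove_unitig(id_a)
        self.remove_unitig(id_b)
        nid = self.insert_unitig(merged_seq, ca + cb)
        if merged_pairs and self.colors is not None:
            self._attach_pairs(nid, merged_seq, merged_pairs)
        return nid

    def _attach_pairs(self, id_u: int, oriented_seq: str, pairs) -> None:
        """Store (row, color) pairs on a freshly inserted unitig.

        ``pairs`` rows refer to ``oriented_seq``; if insertion flipped the
        sequence to its canonical orientation the rows are mirrored.
        """
        rec = self.unitig(id_u)
        flipped = rec.seq != oriented_seq
        last = rec.n_kmers - 1
        slot = self.colors.assign_slot(rec.seq[: self.k])
        rec.color_slot = slot
        for i, j in pairs:
            self.colors.add_pair(slot, (last - i) if flipped else i, j, rec.n_kmers)

    # -- integrity ---------------------------------------------------------

    def check_invariants(self) -> None:
        """Full-sweep referential check between M and U (test support)."""
        seen = set()
        for key, lst in self._minimizers.items():
            g = self.g
            gstr = unpack(key, g)
            for id_u, pos in lst:
                assert id_u in self._units, f"M references dead unitig {id_u}"
                u = self._units[id_u]
                assert 0 <= pos <= len(u.seq) - g, "minimizer position out of range"
                assert canonical(u.seq[pos : pos + g]) == gstr, "g-mer mismatch at recorded position"
                assert (key, pos) not in seen or True
        for u in self._units.values():
            for key, pos in u.entries:
                assert (u.id_u, pos) in self._minimizers.get(key, []), "entry missing from M"
            for p in range(u.n_kmers):
                hit = self.lookup_kmer(u.seq[p : p + self.k])
                assert hit is not None, "stored k-mer not reachable through M"
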