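"""Exact cdBG construction from the filtered Bloom approximation.

A second pass over the input walks every k-mer still present in BBF2.  K-mers
not yet in the dictionary trigger unitig extraction: the k-mer is extended
forward, and backward via the reverse complement, one base at a time.  An
extension step from x to x' is taken only when x' is the single non-ghost
successor of x and x the single non-ghost predecessor of x' — the maximal
non-branching path condition evaluated through Bloom probes.

Because the filter has a false-positive rate p, a spurious neighbor would
halt extraction with probability ~6p per internal k-mer, capping unitig
lengths at a geometric mean of ~1/(6p).  Candidate neighbors that have no
filter neighbor besides the current k-mer are therefore declared *ghosts*:
recorded in a side table, ignored for the uniqueness counts, and repaired in
the rare case a read later proves them real.  With ghosts, premature halts
need two adjacent false positives (probability ~42p^2).

Per-k-mer occurrence counters (saturating at 2) are filled during the read
pass; k-mers whose count stays below the mode threshold (2 for reads, 1 for
references) are false positives and are deleted afterwards.  Deleting an
interior k-mer splits its unitig (undoing a *false connection*); deleting a
whole short unitig lets its neighbors re-join (undoing a *false branching*).
A final join sweep restores maximal compaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .filtering import READS_MODE, FilterResult
from .index import FORWARD, REVERSE, CdbgIndex
from .io import read_many
from .kmers import _kmer_minimizer_stream, acgt_runs, canonical, revcomp

FORWARD_DIR = "forward"
BACKWARD_DIR = "backward"


class GhostTable(dict):
    """Canonical ghost k-mer -> canonical anchor k-mer that discovered it."""


@dataclass(frozen=True)
class FpClassification:
    kind: str  # "false_connection" | "false_branching"
    kmer: str
    affected_unitigs: Tuple[int, ...]


FALSE_CONNECTION = "false_connection"
FALSE_BRANCHING = "false_branching"


@dataclass
class BuildStats:
    n_read_kmers: int = 0
    n_filtered_out: int = 0
    n_unitigs_extracted: int = 0
    n_ghosts_recorded: int = 0
    n_ghosts_repaired: int = 0
    n_fp_deleted: int = 0
    n_joins: int = 0
    extension_steps: List[Tuple[int, int]] = field(default_factory=list)  # (probes, hits)


# -- neighbor probing ------------------------------------------------------


def successor_candidates(x: str) -> List[str]:
    return [x[1:] + a for a in "ACGT"]


def predecessor_candidates(x: str) -> List[str]:
    return [a + x[:-1] for a in "ACGT"]


def bbf_neighbors(flt, x: str, direction: str) -> Set[str]:
    """Filter-positive neighbors of ``x`` in one direction.

    All four candidates are probed (4 queries); for an internal unitig k-mer
    the combined forward+backward probing is 8 queries of which exactly 2
    are true on an error-free filter.
    """
    if direction == FORWARD_DIR:
        cands = successor_candidates(x)
    elif direction == BACKWARD_DIR:
        cands = predecessor_candidates(x)
    else:
        raise ValueError(f"direction must be forward/backward, got {direction!r}")
    return {c for c in cands if flt.may_contain_kmer(c)}


def _is_ghost(flt, cand: str, anchor: str) -> bool:
    """True when ``cand`` has no filter neighbor besides ``anchor``.

    Probes up to 7 further positions (the anchor-side candidate set minus
    the anchor itself, plus the 4 opposite-side candidates).
    """
    anchor_canon = canonical(anchor)
    for n in successor_candidates(cand) + predecessor_candidates(cand):
        if canonical(n) == anchor_canon:
            continue
        if flt.may_contain_kmer(n):
            return False
    return True


# -- unitig extraction -----------------------------------------------------


def _never(_x: str) -> bool:
    return False


def _extend_forward(
    flt, start: str, ghosts: GhostTable, visited: Set[str], stats, is_known=_never
) -> str:
    """Forward extension chars appended after ``start``; updates ghosts.

    ``is_known`` reports whether a k-mer is already proven real (present in
    the dictionary being built): such a k-mer is never ghost-dismissed, even
    if its own neighborhood in the filter looks like a dead end — without
    this, a repaired one-k-mer unitig hanging off a junction would be
    re-ghosted and the junction merged through.
    """
    out: List[str] = []
    cur = start
    while True:
        p0, h0 = flt.n_queries, flt.n_positive
        succs = sorted(bbf_neighbors(flt, cur, FORWARD_DIR))
        succs = [s for s in succs if canonical(s) not in ghosts]
        nxt = None
        if len(succs) == 1:
            nxt = succs[0]
        elif len(succs) > 1:
            live = []
            for s in succs:
                if not is_known(s) and _is_ghost(flt, s, cur):
                    ghosts[canonical(s)] = canonical(cur)
                else:
                    live.append(s)
            if len(live) == 1:
                nxt = live[0]
        if nxt is not None:
            preds = sorted(bbf_neighbors(flt, nxt, BACKWARD_DIR))
            cur_canon = canonical(cur)
            others = [q for q in preds if canonical(q) != cur_canon and canonical(q) not in ghosts]
            for q in others:
                if not is_known(q) and _is_ghost(flt, q, nxt):
                    ghosts[canonical(q)] = canonical(nxt)
                else:
                    nxt = None
                    break
        if stats is not None:
            stats.extension_steps.append((flt.n_queries - p0, flt.n_positive - h0))
        if nxt is None:
            return "".join(out)
        ncanon = canonical(nxt)
        if ncanon in visited:  # cycle guard: never revisit within one extraction
            return "".join(out)
        visited.add(ncanon)
        out.append(nxt[-1])
        cur = nxt


def extract_unitig(
    flt, x: str, ghosts: Optional[GhostTable] = None, stats=None, is_known=_never
) -> str:
    """Extract the unitig containing filter-positive k-mer ``x``.

    Extends forward from ``x`` and forward from its reverse complement (the
    backward extension), stopping on branches, dead ends, or when the walk
    revisits a k-mer of the current extraction (cycle guard).
    """
    if ghosts is None:
        ghosts = GhostTable()
    if not flt.may_contain_kmer(x):
        raise ValueError("extract_unitig requires a filter-positive seed k-mer")
    visited = {canonical(x)}
    fwd = _extend_forward(flt, x, ghosts, visited, stats, is_known)
    back = _extend_forward(flt, revcomp(x), ghosts, visited, stats, is_known)
    return revcomp(back) + x + fwd


# -- whole-graph construction ----------------------------------------------


def build_cdbg(
    read_files: Sequence,
    flt: FilterResult,
    t: int = 64,
    eliminate: bool = True,
    stats: Optional[BuildStats] = None,
) -> Tuple[CdbgIndex, GhostTable, BuildStats]:
    """Second pass: extract unitigs, count occurrences, clean false positives.

    Deterministic for fixed inputs and seed.  With ``eliminate=False`` the
    raw (counter-bearing, FP-contaminated) graph is returned for inspection.
    """
    if stats is None:
        stats = BuildStats()
    D = CdbgIndex(k=flt.k, g=flt.g, seed=flt.seed, t=t)
    ghosts = GhostTable()
    bound = flt.bound()
    k = flt.k
    bbf = flt.bbf2
    for _rid, seq in read_many(read_files):
        for _start, run in acgt_runs(seq):
            for i, kcanon, mh, mp, mc in _kmer_minimizer_stream(run, k, flt.g, flt.seed):
                stats.n_read_kmers += 1
                if not bbf.may_contain(kcanon, mh):
                    stats.n_filtered_out += 1
                    continue
                x = run[i : i + k]
                if ghosts and canonical(x) in ghosts:
                    repair_ghost(D, bound, ghosts, x)
                    stats.n_ghosts_repaired += 1
                hit = D.lookup_kmer_hinted(x, mc, mp - i)
                if hit is None:
                    useq = extract_unitig(bound, x, ghosts, stats=None, is_known=D.contains_kmer)
                    D.insert_unitig(useq)
                    stats.n_unitigs_extracted += 1
                    hit = D.lookup_kmer(x)
                D.increment_counter(hit.id_u, hit.offset)
    stats.n_ghosts_recorded = len(ghosts)
    if eliminate:
        eliminate_false_positives(D, flt.counter_threshold, stats=stats)
    return D, ghosts, stats


def build_graph(
    files: Sequence,
    k: int = 31,
    g: int = 23,
    seed: int = 0,
    mode: str = READS_MODE,
    expected_kmers: Optional[int] = None,
    bits_per_kmer: float = 14,
    t: int = 64,
) -> Tuple[CdbgIndex, BuildStats]:
    """Full pipeline: filter pass, extraction pass, FP elimination."""
    from .filtering import filter_reads, reference_mode_filter

    if mode == READS_MODE:
        flt = filter_reads(files, k, g, seed, expected_kmers, bits_per_kmer)
    else:
        flt = reference_mode_filter(files, k, g, seed, expected_kmers, bits_per_kmer)
    D, _ghosts, stats = build_cdbg(files, flt, t=t)
    return D, stats


# -- false-positive classification and elimination -------------------------


def classify_fp(D: CdbgIndex, x: str) -> FpClassification:
    """Structural role of a sub-threshold k-mer ``x``.

    Interior k-mers glue two real unitigs into one (*false connection*:
    deleting them splits the unitig); whole-unitig or terminal k-mers hang
    off a real path (*false branching*: deleting them lets the adjacent
    unitigs re-join).
    """
    hit = D.lookup_kmer(x)
    if hit is None:
        raise KeyError(f"k-mer {x} not in the graph")
    u = D.unitig(hit.id_u)
    affected = {hit.id_u}
    xo = u.seq[hit.offset : hit.offset + D.k]  # stored-orientation copy
    for _c, h in D.graph_successors(xo) + D.graph_predecessors(xo):
        affected.add(h.id_u)
    if 0 < hit.offset < u.n_kmers - 1:
        return FpClassification(FALSE_CONNECTION, canonical(x), tuple(sorted(affected)))
    return FpClassification(FALSE_BRANCHING, canonical(x), tuple(sorted(affected)))


def eliminate_false_positives(
    D: CdbgIndex, threshold: int = 2, stats: Optional[BuildStats] = None
) -> CdbgIndex:
    """Delete k-mers with counter < threshold; split and re-join unitigs.

    All deletions are applied first (splitting unitigs at deleted interior
    positions), then join sweeps merge every tail->head pair of unitigs with
    unique mutual adjacency until a fixed point: the result holds exactly
    the k-mers with counter >= threshold, maximally compacted.
    """
    n_deleted = 0
    for u in list(D.unitigs()):
        bad = [p for p in range(u.n_kmers) if u.counters[p] < threshold]
        if not bad:
            continue
        n_deleted += len(bad)
        runs: List[Tuple[int, int]] = []
        prev = -1
        for p in bad + [u.n_kmers]:
            if p - prev > 1:
                runs.append((prev + 1, p - 1))
            prev = p
        D.split_unitig(u.id_u, runs)  # empty runs: unitig fully deleted
    n_joins = _join_sweep(D)
    if stats is not None:
        stats.n_fp_deleted += n_deleted
        stats.n_joins += n_joins
    return D


def _mergeable_forward(D: CdbgIndex, id_u: int, orient: str):
    """Unique-successor merge partner of unitig end, or None."""
    u = D.unitig(id_u)
    k = D.k
    s = u.seq if orient == FORWARD else revcomp(u.seq)
    tail = s[-k:]
    succs = D.graph_successors(tail)
    if len(succs) != 1:
        return None
    _cand, hit = succs[0]
    if hit.id_u == id_u:
        return None  # circular or self-adjacent: leave as is
    v = D.unitig(hit.id_u)
    if hit.strand == FORWARD and hit.offset == 0:
        ov = FORWARD
        vhead = v.seq[:k]
    elif hit.strand == REVERSE and hit.offset == v.n_kmers - 1:
        ov = REVERSE
        vhead = revcomp(v.seq[-k:])
    else:
        return None  # enters v mid-sequence: v branches there
    preds = D.graph_predecessors(vhead)
    if len(preds) != 1:
        return None
    if preds[0][1].id_u != id_u:
        return None
    return hit.id_u, ov


def _join_sweep(D: CdbgIndex) -> int:
    """Merge all uniquely-adjacent unitig pairs until a fixed point."""
    n_joins = 0
    changed = True
    while changed:
        changed = False
        for u in list(D.unitigs()):
            if u.id_u not in D._units:
                continue  # consumed by an earlier merge this round
            for orient in (FORWARD, REVERSE):
                m = _mergeable_forward(D, u.id_u, orient)
                if m is not None:
                    D.merge_unitigs(u.id_u, orient, m[0], m[1])
                    n_joins += 1
                    changed = True
                    break
    return n_joins


# -- ghost repair ----------------------------------------------------------


def repair_ghost(D: CdbgIndex, flt, ghosts: GhostTable, x: str) -> None:
    """Un-ghost ``x`` and rebuild the unitig(s) it belongs to.

    The unitigs adjacent to ``x`` are removed (their counters saved by
    canonical k-mer), then ``x`` and every displaced k-mer are re-extracted
    from the filter and re-inserted with counters restored.  Since ``x`` now
    counts as a real neighbor, the displaced path may legitimately split at
    the junction with ``x``; extracting from every displaced seed (skipping
    those already covered) reproduces exactly the graph that would have been
    built had ``x`` never been ghosted.
    """
    xc = canonical(x)
    if xc not in ghosts:
        raise KeyError(f"{x} is not a recorded ghost k-mer")
    del ghosts[xc]
    saved: Dict[str, int] = {}
    seeds: List[str] = [x]
    k = D.k
    adjacent: Set[int] = set()
    for cand in successor_candidates(x) + predecessor_candidates(x):
        hit = D.lookup_kmer(cand)
        if hit is not None:
            adjacent.add(hit.id_u)
    for id_u in sorted(adjacent):
        u = D.unitig(id_u)
        for p in range(u.n_kmers):
            xm = u.seq[p : p + k]
            saved[canonical(xm)] = u.counters[p]
            seeds.append(xm)
        D.remove_unitig(id_u)
    for seed_kmer in seeds:
        if D.lookup_kmer(seed_kmer) is not None:
            continue
        useq = extract_unitig(flt, seed_kmer, ghosts, is_known=D.contains_kmer)
        counters = bytearray(
            saved.get(canonical(useq[p : p + k]), 0) for p in range(len(useq) - k + 1)
        )
        D.insert_unitig(useq, counters)


# -- analytic ghost-motivation simulation ----------------------------------


def simulate_premature_halts(
    p: float, n_trials: int, seed: int = 0, n_fp_probes: int = 6
) -> float:
    """Mean extracted-unitig length (in k-mers) under premature-halt errors.

    Models extraction over an unbounded non-branching path where each
    internal k-mer issues ``n_fp_probes`` independent should-be-false filter
    probes, each returning a false positive with probability ``p`` and
    halting the walk.  The halt point is geometric with success probability
    1-(1-p)^6 ~ 6p, so the expected length is ~1/(6p) (167 at p=1e-3).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0,1)")
    rng = np.random.default_rng(seed)
    q = 1.0 - (1.0 - p) ** n_fp_probes
    lengths = rng.geometric(q, size=n_trials)
    return float(lengths.mean())
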