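"""Dynamic graph update: add datasets to an existing (colored) graph.

Adding sequences to a compacted de Bruijn graph changes it in three ways:
brand-new k-mers appear, existing unitigs gain branches where new k-mers
attach (so they must split to keep every junction at a unitig boundary), and
previously dead ends may continue into new sequence (so unitigs must merge
to restore maximal compaction).  The update proceeds in exactly those
phases:

1. collect the novel k-mer set N from the new inputs (exact, reference
   mode: assembled sequences where every k-mer is real);
2. split every existing unitig at each position where a k-mer of N attaches
   as an extra neighbor, remapping counters and per-k-mer colors by
   position;
3. compact N itself into unitigs, stopping extension at junctions with the
   existing graph, and insert them;
4. run the global join sweep to merge across old/new boundaries;
5. extend the color table with one new column per added dataset and stream
   the new files through the usual coloring pass.

The result is node-centrically identical to a from-scratch build on the
union of old and new inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from os.path import basename
from typing import Dict, List, Sequence, Set, Tuple

from .colors import color_graph
from .construct import _join_sweep, predecessor_candidates, successor_candidates
from .index import FORWARD, CdbgIndex
from .io import read_many
from .kmers import acgt_runs, canonical, revcomp


@dataclass
class UpdateStats:
    n_new_kmers: int = 0
    n_splits: int = 0
    n_new_unitigs: int = 0
    n_joins: int = 0


def _novel_kmers(D: CdbgIndex, files: Sequence) -> Dict[str, str]:
    """Canonical -> as-read orientation for input k-mers absent from D."""
    k = D.k
    novel: Dict[str, str] = {}
    for _rid, seq in read_many(files):
        for _s, run in acgt_runs(seq):
            for i in range(len(run) - k + 1):
                x = run[i : i + k]
                xc = canonical(x)
                if xc not in novel and D.lookup_kmer(x) is None:
                    novel[xc] = x
    return novel


def _collect_cuts(D: CdbgIndex, novel: Dict[str, str]) -> Dict[int, Set[int]]:
    """Split positions: cut *before* k-mer index c of each affected unitig."""
    cuts: Dict[int, Set[int]] = {}

    def add_cut(id_u: int, c: int) -> None:
        if 0 < c < D.unitig(id_u).n_kmers:  # boundary cuts are no-ops
            cuts.setdefault(id_u, set()).add(c)

    for x in novel.values():
        for cand in successor_candidates(x):  # x -> y: y gains a predecessor
            hit = D.lookup_kmer(cand)
            if hit is None:
                continue
            if hit.strand == FORWARD:
                add_cut(hit.id_u, hit.offset)  # y must become a head
            else:
                add_cut(hit.id_u, hit.offset + 1)
        for cand in predecessor_candidates(x):  # y -> x: y gains a successor
            hit = D.lookup_kmer(cand)
            if hit is None:
                continue
            if hit.strand == FORWARD:
                add_cut(hit.id_u, hit.offset + 1)  # y must become a tail
            else:
                add_cut(hit.id_u, hit.offset)
    return cuts


def _compact_novel(D: CdbgIndex, novel: Dict[str, str]) -> List[str]:
    """Maximal non-branching paths within N, bounded by old-graph junctions."""

    def member(kmer: str) -> bool:
        return canonical(kmer) in novel or D.lookup_kmer(kmer) is not None

    def extend(start: str, visited: Set[str]) -> str:
        out: List[str] = []
        cur = start
        while True:
            succs = [c for c in successor_candidates(cur) if member(c)]
            if len(succs) != 1:
                break
            nxt = succs[0]
            nc = canonical(nxt)
            if nc not in novel or nc in visited:
                break  # old-graph boundary or cycle
            preds = [c for c in predecessor_candidates(nxt) if member(c)]
            if len(preds) != 1:
                break
            visited.add(nc)
            out.append(nxt[-1])
            cur = nxt
        return "".join(out)

    unitigs: List[str] = []
    placed: Set[str] = set()
    for xc in sorted(novel):
        if xc in placed:
            continue
        x = novel[xc]
        visited = {xc}
        fwd = extend(x, visited)
        back = extend(revcomp(x), visited)
        seq = revcomp(back) + x + fwd
        placed |= visited
        unitigs.append(seq)
    return unitigs


def update_graph(D: CdbgIndex, new_files: Sequence, color: bool | None = None) -> UpdateStats:
    """Merge new (reference-mode) datasets into ``D`` in place.

    With ``color=True`` (default when ``D`` already carries a color layer)
    each new file becomes a new color column.  Counters of split/merged
    unitigs and per-k-mer color sets follow their k-mers by position.
    """
    if color is None:
        color = D.colors is not None
    stats = UpdateStats()
    novel = _novel_kmers(D, new_files)
    stats.n_new_kmers = len(novel)

    cuts = _collect_cuts(D, novel)
    for id_u, cut_set in cuts.items():
        u = D.unitig(id_u)
        bounds = [0] + sorted(cut_set) + [u.n_kmers]
        runs: List[Tuple[int, int]] = [
            (bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)
        ]
        D.split_unitig(id_u, runs)
        stats.n_splits += len(runs) - 1

    for seq in _compact_novel(D, novel):
        D.insert_unitig(seq)
        stats.n_new_unitigs += 1

    stats.n_joins = _join_sweep(D)

    if color:
        first = 0
        if D.colors is not None:
            first = D.colors.add_colors([basename(str(f)) for f in new_files])
        color_graph(D, new_files, strict=True, first_color=first)
    return stats
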