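"""Sequence membership queries against the (colored) graph.

A query sequence is present when at least a fraction theta of its k-mers are
found in the graph (theta = 1.0 demands every k-mer).  In inexact mode a
k-mer also counts as found when any variant within edit distance one —
a substitution, or an indel re-windowed to length k — is in the graph.

Indel semantics: a k-length window cannot hold a true indel variant, so a
deletion drops one base and restores length by extending one base at either
window edge, and an insertion adds one base and trims one base from either
edge.  Candidate variants are verified solely by graph lookup.  This is the
one place where these semantics may diverge from other k-mer query engines;
see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, TextIO

from .index import CdbgIndex
from .kmers import acgt_runs, canonical

DNA = "ACGT"


@dataclass(frozen=True)
class QuerySpec:
    theta: float = 1.0
    inexact: bool = False
    report_colors: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")


@dataclass
class QueryResult:
    query_id: str
    n_kmers: int
    n_found: int
    present: bool
    too_short: bool = False
    color_found: Dict[int, int] = field(default_factory=dict)  # color -> k-mers found

    @property
    def ratio(self) -> float:
        return self.n_found / self.n_kmers if self.n_kmers else 0.0


_COMP = str.maketrans("ACGT", "TGCA")


def _canon_fast(s: str) -> str:
    r = s.translate(_COMP)[::-1]
    return s if s <= r else r


def _edit1_candidates(x: str):
    """Lazily yield deduplicated canonical variants, substitutions first.

    Substitution variants are the common rescue for sequencing errors, so
    they are generated (and can be looked up) before the windowed indels.
    """
    k = len(x)
    seen = {_canon_fast(x)}
    yield from seen
    for p in range(k):
        left, right = x[:p], x[p + 1 :]
        for b in DNA:
            if b != x[p]:
                v = _canon_fast(left + b + right)
                if v not in seen:
                    seen.add(v)
                    yield v
    for p in range(k):
        core = x[:p] + x[p + 1 :]  # deletion, re-extended at either end
        for b in DNA:
            for v in (b + core, core + b):
                vc = _canon_fast(v)
                if vc not in seen:
                    seen.add(vc)
                    yield vc
    for p in range(k + 1):
        for b in DNA:
            ins = x[:p] + b + x[p:]  # insertion, trimmed at either end
            for v in (ins[1:], ins[:-1]):
                vc = _canon_fast(v)
                if vc not in seen:
                    seen.add(vc)
                    yield vc


def edit1_variants(x: str) -> Set[str]:
    """Canonical forms of x and all length-k words within one edit of x.

    Substitutions at every position; deletions re-extended by one base at
    either end; insertions trimmed by one base at either end.  The set is
    deduplicated over canonical forms and always contains canonical(x).
    """
    canonical(x)  # alphabet validation
    return set(_edit1_candidates(x))


def _kmer_found(D: CdbgIndex, x: str, inexact: bool) -> bool:
    if D.lookup_kmer(x) is not None:
        return True
    if not inexact:
        return False
    for v in _edit1_candidates(x):
        if D.lookup_kmer(v) is not None:
            return True
    return False


def query_sequence(D: CdbgIndex, seq: str, spec: QuerySpec, query_id: str = "query") -> QueryResult:
    """Membership verdict for one query sequence.

    K-mers are taken per maximal ACGT run; repeated identical k-mers are
    each counted (the ratio is over positions, not distinct k-mers).
    Queries shorter than k yield n_kmers = 0, absent, and are flagged.
    """
    k = D.k
    n_kmers = 0
    n_found = 0
    color_found: Dict[int, int] = {}

    any_run = False
    for _s, run in acgt_runs(seq):
        if len(run) < k:
            continue
        any_run = True
        for i in range(len(run) - k + 1):
            x = run[i : i + k]
            n_kmers += 1
            if _kmer_found(D, x, spec.inexact):
                n_found += 1
                if spec.report_colors and D.colors is not None:
                    hit = D.lookup_kmer(x)
                    if hit is not None:
                        rec = D.unitig(hit.id_u)
                        if rec.color_slot is not None:
                            for j in D.colors.container(rec.color_slot).row(hit.offset):
                                color_found[j] = color_found.get(j, 0) + 1
    res = QueryResult(
        query_id=query_id,
        n_kmers=n_kmers,
        n_found=n_found,
        present=False,
        too_short=not any_run,
        color_found=color_found,
    )
    res.present = n_kmers > 0 and res.ratio >= spec.theta
    return res


def query_batch(
    D: CdbgIndex, records, spec: QuerySpec
) -> List[QueryResult]:
    return [query_sequence(D, seq, spec, query_id=rid) for rid, seq in records]


def write_results_tsv(results: Sequence[QueryResult], fh: TextIO, n_colors: int = 0) -> None:
    """One TSV row per query: id, counts, ratio, verdict[, per-color counts]."""
    header = ["query", "n_kmers", "n_found", "ratio", "present"]
    header += [f"color_{j}" for j in range(n_colors)]
    fh.write("\t".join(header) + "\n")
    for r in results:
        row = [r.query_id, str(r.n_kmers), str(r.n_found), f"{r.ratio:.6f}", str(int(r.present))]
        row += [str(r.color_found.get(j, 0)) for j in range(n_colors)]
        fh.write("\t".join(row) + "\n")
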