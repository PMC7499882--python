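"""Independent brute-force oracles used across the test suite.

Everything here works on plain Python strings, sets and dictionaries —
no Bloom filters, no minimizer tables — so it can stand as ground truth
for the package's data structures.
"""

from collections import Counter
from typing import Dict, Iterable, List, Set

_C = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_C)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def kmer_counts(seqs: Iterable[str], k: int) -> Counter:
    c: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            c[canon(s[i : i + k])] += 1
    return c


def kmer_set(seqs: Iterable[str], k: int) -> Set[str]:
    return set(kmer_counts(seqs, k))


def compact(kmers: Set[str]) -> Counter:
    """Maximal non-branching path compaction of an explicit k-mer set.

    Returns the multiset (Counter) of unitig sequences, each normalized to
    the lexicographically smaller orientation — the node-centric reference
    against which graph construction is compared.
    """
    kmers = {canon(x) for x in kmers}

    def succs(s: str) -> List[str]:
        return [s[1:] + a for a in "ACGT" if canon(s[1:] + a) in kmers]

    def preds(s: str) -> List[str]:
        return [a + s[:-1] for a in "ACGT" if canon(a + s[:-1]) in kmers]

    out: Counter = Counter()
    done: Set[str] = set()
    for x in sorted(kmers):
        if x in done:
            continue
        walked = {x}

        def extend(cur: str) -> str:
            chars = []
            while True:
                ss = succs(cur)
                if len(ss) != 1:
                    break
                nxt = ss[0]
                cn = canon(nxt)
                if cn in walked or len(preds(nxt)) != 1:
                    break
                walked.add(cn)
                chars.append(nxt[-1])
                cur = nxt
            return "".join(chars)

        fwd = extend(x)
        back = extend(rc(x))
        seq = rc(back) + x + fwd
        done |= walked
        out[min(seq, rc(seq))] += 1
    return out


def unitig_multiset(D) -> Counter:
    """Orientation-normalized unitig multiset of a built graph."""
    return Counter(min(u.seq, rc(u.seq)) for u in D.unitigs())


def color_map(genomes: List[str], k: int) -> Dict[str, Set[int]]:
    """Canonical k-mer -> set of genome indices containing it."""
    out: Dict[str, Set[int]] = {}
    for j, g in enumerate(genomes):
        for i in range(len(g) - k + 1):
            out.setdefault(canon(g[i : i + k]), set()).add(j)
    return out


def edit_distance_le1(a: str, b: str) -> bool:
    """True if a and b are within Levenshtein distance 1 (direct check)."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: try deleting each position of b
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]
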