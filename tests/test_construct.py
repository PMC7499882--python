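"""Unitig extraction, ghost k-mers, and false-positive elimination."""

import random

import pytest

from ccdbg.bbf import ExactMembershipFilter
from ccdbg.construct import (
    FALSE_BRANCHING,
    FALSE_CONNECTION,
    BuildStats,
    GhostTable,
    bbf_neighbors,
    build_cdbg,
    build_graph,
    classify_fp,
    eliminate_false_positives,
    extract_unitig,
    repair_ghost,
    simulate_premature_halts,
)
from ccdbg.filtering import filter_reads
from ccdbg.index import CdbgIndex
from ccdbg.io import write_fastq
from ccdbg.kmers import canonical

from conftest import random_dna
from oracles import canon, compact, kmer_counts, rc, unitig_multiset

K, G = 15, 7


def path_filter(seqs, k=K):
    flt = ExactMembershipFilter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            flt.add(s[i : i + k])
    return flt


def test_bbf_neighbors_empty_filter():
    flt = ExactMembershipFilter()
    assert bbf_neighbors(flt, "ACGTACGTACGTACG", "forward") == set()


def test_bbf_neighbors_matches_bruteforce(rng):
    s = random_dna(300, rng)
    flt = path_filter([s])
    kmers = {canon(s[i : i + K]) for i in range(len(s) - K + 1)}
    for _ in range(100):
        x = s[rng.randrange(0, len(s) - K + 1) :][:K]
        fwd = bbf_neighbors(flt, x, "forward")
        exp = {x[1:] + a for a in "ACGT" if canon(x[1:] + a) in kmers}
        assert fwd == exp
        bwd = bbf_neighbors(flt, x, "backward")
        expb = {a + x[:-1] for a in "ACGT" if canon(a + x[:-1]) in kmers}
        assert bwd == expb


def test_eight_probes_two_hits_per_internal_step(rng):
    # error-free filter over one linear path: every extension step issues
    # exactly 8 membership queries of which exactly 2 return true
    s = random_dna(200, rng)
    flt = path_filter([s])
    stats = BuildStats()
    x = s[90 : 90 + K]
    useq = extract_unitig(flt, x, GhostTable(), stats=stats)
    assert canon(useq) == canon(s)
    advancing = [step for step in stats.extension_steps if step != (4, 0)]
    terminal = [step for step in stats.extension_steps if step == (4, 0)]
    assert all(step == (8, 2) for step in advancing)
    assert len(terminal) == 2  # one dead end per direction
    assert len(advancing) == len(s) - K  # eta - 1 advances overall


def test_extract_isolated_kmer(rng):
    x = random_dna(K, rng)
    flt = ExactMembershipFilter()
    flt.add(x)
    assert extract_unitig(flt, x) == x
    with pytest.raises(ValueError):
        extract_unitig(flt, random_dna(K, rng))


def test_extract_full_linear_path(rng):
    s = random_dna(120, rng)
    flt = path_filter([s])
    for start in (0, 40, 105):
        useq = extract_unitig(flt, s[start : start + K])
        assert canon(useq) == canon(s)


def test_extract_circular_terminates(rng):
    core = random_dna(80, rng)
    circ = core + core[: K - 1]  # every k-mer wraps; all distinct w.h.p.
    kmers = [circ[i : i + K] for i in range(len(core))]
    if len({canon(x) for x in kmers}) != len(kmers):
        pytest.skip("random core produced a repeated k-mer")
    flt = path_filter([circ])
    useq = extract_unitig(flt, kmers[10])
    got = {canon(useq[i : i + K]) for i in range(len(useq) - K + 1)}
    assert got == {canon(x) for x in kmers}  # each k-mer spelled exactly once
    assert len(useq) == len(core) + K - 1


def test_build_counts_duplicate_read(tmp_path, rng):
    read = random_dna(100, rng)
    path = tmp_path / "r.fastq"
    write_fastq(path, [("a", read), ("b", read)])
    flt = filter_reads([path], K, G, seed=1, expected_kmers=500)
    D, ghosts, stats = build_cdbg([path], flt, eliminate=False)
    assert D.n_unitigs == 1
    (u,) = list(D.unitigs())
    assert len(u.seq) == 100
    assert all(c == 2 for c in u.counters)  # saturated at 2


def test_read_with_n_splits_runs(tmp_path, rng):
    left, right = random_dna(60, rng), random_dna(60, rng)
    read = left + "N" + right
    path = tmp_path / "n.fastq"
    write_fastq(path, [("a", read), ("b", read)])
    flt = filter_reads([path], K, G, seed=2, expected_kmers=500)
    D, _, _ = build_cdbg([path], flt)
    assert D.kmer_set() == kmer_counts([left, right], K).keys()


def _graph_from_kmer_set(kmers, seeds):
    """Build D by extraction from an exact filter, as the read pass does:
    seed k-mers found in the ghost table trigger repair first."""
    flt = ExactMembershipFilter(set(kmers))
    D = CdbgIndex(k=K, g=G, seed=9)
    ghosts = GhostTable()
    for x in sorted(seeds):
        if canonical(x) in ghosts:
            repair_ghost(D, flt, ghosts, x)
        if D.lookup_kmer(x) is None:
            D.insert_unitig(extract_unitig(flt, x, ghosts))
    return D


def test_classify_fp_interior_is_false_connection(rng):
    # two true segments glued by one spurious interior k-mer
    s = random_dna(90, rng)
    mid = 45
    fp_kmer = s[mid : mid + K]
    D = _graph_from_kmer_set(
        {canon(s[i : i + K]) for i in range(len(s) - K + 1)},
        [s[i : i + K] for i in range(len(s) - K + 1)],
    )
    cls = classify_fp(D, fp_kmer)
    assert cls.kind == FALSE_CONNECTION
    assert cls.kmer == canon(fp_kmer)


def test_classify_fp_hanging_unitig_is_false_branching(rng):
    s = random_dna(80, rng)
    anchor = s[30 : 30 + K]
    branch = "A" + anchor[:-1] if anchor[0] != "A" else "C" + anchor[:-1]
    kmers = {canon(s[i : i + K]) for i in range(len(s) - K + 1)} | {canon(branch)}
    D = _graph_from_kmer_set(kmers, [branch] + [s[i : i + K] for i in range(len(s) - K + 1)])
    cls = classify_fp(D, branch)
    assert cls.kind == FALSE_BRANCHING


def test_every_single_fp_injection_cleaned(rng):
    # exhaustive toy: inject one false-positive k-mer adjacent to each
    # position of a 20-k-mer path.  Extraction is seeded from the true
    # (read) k-mers only, as in the construction pass: the spurious k-mer
    # is ghost-dismissed, embedded and counter-cleaned, or splits the path
    # for the join sweep to repair — the final graph must always equal the
    # brute-force compaction of the true path alone.
    s = random_dna(20 + K - 1, rng)
    true_kmers = {canon(s[i : i + K]) for i in range(20)}
    seeds = [s[i : i + K] for i in range(20)]
    true_compacted = compact(true_kmers)
    n_embedded = 0
    for pos in range(20):
        anchor = s[pos : pos + K]
        for b in "ACGT":
            for fp in (b + anchor[:-1], anchor[1:] + b):
                if canon(fp) in true_kmers:
                    continue
                kmers = true_kmers | {canon(fp)}
                D = _graph_from_kmer_set(kmers, seeds)
                # counters: true k-mers observed twice, the FP never
                for u in D.unitigs():
                    for p in range(u.n_kmers):
                        if canon(u.seq[p : p + K]) in true_kmers:
                            u.counters[p] = 2
                if D.lookup_kmer(fp) is not None:
                    n_embedded += 1
                    cls = classify_fp(D, fp)
                    assert cls.kind in (FALSE_CONNECTION, FALSE_BRANCHING)
                eliminate_false_positives(D, threshold=2)
                assert unitig_multiset(D) == true_compacted, (pos, b, fp)
    assert n_embedded > 0  # terminal extensions do adopt the spurious k-mer


def test_false_connection_split_increases_unitig_count(rng):
    # a path whose middle k-mer is spurious: deletion splits one unitig in two
    s = random_dna(3 * K, rng)
    D = _graph_from_kmer_set(
        {canon(s[i : i + K]) for i in range(len(s) - K + 1)},
        [s[i : i + K] for i in range(len(s) - K + 1)],
    )
    assert D.n_unitigs == 1
    mid = (len(s) - K + 1) // 2
    for u in D.unitigs():
        for p in range(u.n_kmers):
            u.counters[p] = 0 if canon(u.seq[p : p + K]) == canon(s[mid : mid + K]) else 2
    eliminate_false_positives(D, threshold=2)
    assert D.n_unitigs == 2


def test_no_subthreshold_counters_is_fixed_point(rng):
    s = random_dna(100, rng)
    D = _graph_from_kmer_set(
        {canon(s[i : i + K]) for i in range(len(s) - K + 1)},
        [s[i : i + K] for i in range(len(s) - K + 1)],
    )
    for u in D.unitigs():
        for p in range(u.n_kmers):
            u.counters[p] = 2
    before = unitig_multiset(D)
    eliminate_false_positives(D, threshold=2)
    assert unitig_multiset(D) == before


def test_ghost_recorded_and_ignored(rng):
    # a spurious dead-end neighbor mid-path is ghosted, not a halt
    s = random_dna(120, rng)
    anchor = s[50 : 50 + K]
    fp = anchor[1:] + ("A" if s[50 + K] != "A" else "C")
    flt = path_filter([s])
    if flt.may_contain_kmer(fp):
        pytest.skip("random collision with a real k-mer")
    flt.add(fp)
    ghosts = GhostTable()
    useq = extract_unitig(flt, s[:K], ghosts)
    assert canon(fp) in ghosts
    assert canon(useq) == canon(s)  # extraction passed straight through


def test_ghost_repair_restores_oracle_graph(tmp_path, rng):
    # a genuine k-mer wrongly ghosted (e.g. coverage dip) and later observed
    # in a read: after repair the graph equals the never-ghosted build
    s = random_dna(100, rng)
    flt = path_filter([s])
    D = CdbgIndex(k=K, g=G, seed=4)
    ghosts = GhostTable()
    mid = 50
    ghost_kmer = s[mid : mid + K]
    ghosts[canon(ghost_kmer)] = canon(s[mid - 1 : mid - 1 + K])
    # build with the ghost in place: extraction must stop around it
    for i in range(len(s) - K + 1):
        if D.lookup_kmer(s[i : i + K]) is None and canon(s[i : i + K]) not in ghosts:
            D.insert_unitig(extract_unitig(flt, s[i : i + K], ghosts))
    assert D.lookup_kmer(ghost_kmer) is None
    repair_ghost(D, flt, ghosts, ghost_kmer)
    assert canon(ghost_kmer) not in ghosts
    assert D.lookup_kmer(ghost_kmer) is not None
    expected = compact({canon(s[i : i + K]) for i in range(len(s) - K + 1)})
    assert unitig_multiset(D) == expected
    with pytest.raises(KeyError):
        repair_ghost(D, flt, ghosts, ghost_kmer)  # repair is not replayable


def test_end_to_end_exactness_small(tmp_path, rng):
    genome = random_dna(3000, rng)
    reads = []
    for _ in range(900):
        st = rng.randrange(0, len(genome) - 100 + 1)
        r = genome[st : st + 100]
        if rng.random() < 0.5:
            r = rc(r)
        reads.append(r)
    path = tmp_path / "reads.fastq"
    write_fastq(path, [(f"r{i}", r) for i, r in enumerate(reads)])
    D, stats = build_graph([path], k=K, g=G, seed=6, mode="reads")
    oracle = {x for x, n in kmer_counts(reads, K).items() if n >= 2}
    assert D.kmer_set() == oracle
    assert unitig_multiset(D) == compact(oracle)


def test_premature_halt_simulation_matches_geometric_law():
    mean = simulate_premature_halts(1e-3, 50_000, seed=0)
    assert mean == pytest.approx(1 / (1 - (1 - 1e-3) ** 6), rel=0.02)
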