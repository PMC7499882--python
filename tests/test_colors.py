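"""Color containers, slot assignment, and graph coloring."""

import pytest

from ccdbg.colors import (
    MEDIUM,
    MEDIUM_MAX_BYTES,
    MEDIUM_MAX_CELLS,
    ROARING,
    WORD,
    ColorContainer,
    ColorStore,
    add_color,
    color_graph,
    colors_of,
)
from ccdbg.construct import build_graph
from ccdbg.io import write_fasta
from ccdbg.simulate import simulate_dataset

from conftest import random_dna
from oracles import color_map

K, G = 21, 13


# -- containers ------------------------------------------------------------


def test_word_tier_single_pair_and_tiny_matrix():
    c = ColorContainer()
    assert c.tier == WORD
    c.add(0, 0, 1, 1)
    assert c.tier == WORD and c.contains(0, 0)
    big = ColorContainer()
    big.add(5, 7, 1000, 1000)  # one pair in a huge matrix still fits a word
    assert big.tier == WORD


def test_word_to_medium_upgrade_preserves_content():
    eta, nc = 9, 7  # 63 cells: one bit past the 62-bit word matrix
    c = ColorContainer()
    pairs = [(i, j) for i in range(eta) for j in range(nc)][:40]
    for i, j in pairs:
        c.add(i, j, eta, nc)
    assert c.tier == MEDIUM
    assert all(c.contains(i, j) for i, j in pairs)
    assert not c.contains(8, 6)


def test_medium_boundary_is_cell_count():
    c = ColorContainer()
    c.add(0, 0, 1, MEDIUM_MAX_CELLS)
    c.add(0, 1, 1, MEDIUM_MAX_CELLS)
    assert c.tier == MEDIUM
    d = ColorContainer()
    d.add(0, 0, 1, MEDIUM_MAX_CELLS + 1)
    d.add(0, 1, 1, MEDIUM_MAX_CELLS + 1)
    assert d.tier == ROARING


def test_medium_serialized_size_within_8kb(rng):
    eta, nc = 256, 255  # 65280 cells <= 65488
    c = ColorContainer()
    for _ in range(30_000):
        c.add(rng.randrange(eta), rng.randrange(nc), eta, nc)
    assert c.tier == MEDIUM
    assert c.serialized_size() <= MEDIUM_MAX_BYTES
    assert c.medium_form() in ("bitvector", "sorted_list", "run_length")


def test_tier_transparency_against_set_oracle(rng):
    # insertion sequences crossing both tier boundaries behave like a set
    eta, nc = 300, 300  # 90000 cells: word -> medium impossible, roaring
    c = ColorContainer()
    oracle = set()
    tiers_seen = set()
    for step in range(70_000):
        i, j = rng.randrange(eta), rng.randrange(nc)
        c.add(i, j, eta, nc)
        oracle.add((i, j))
        tiers_seen.add(c.tier)
        if step % 10_000 == 0:
            probe = (rng.randrange(eta), rng.randrange(nc))
            assert c.contains(*probe) == (probe in oracle)
    assert set(c) == oracle
    assert ROARING in tiers_seen
    assert len(c) == len(oracle)


def test_out_of_range_cell_rejected():
    c = ColorContainer()
    with pytest.raises(IndexError):
        c.add(3, 0, 3, 4)
    with pytest.raises(IndexError):
        c.add(0, 4, 3, 4)


# -- slot assignment -------------------------------------------------------


def test_assign_resolve_bijection(rng):
    store = ColorStore(n_colors=3, seed=1)
    slots = {}
    for n in range(1000):
        head = random_dna(21, rng)
        if head in slots:
            continue
        slots[head] = store.assign_slot(head)
    assert len(set(slots.values())) == len(slots)  # no two unitigs share a slot
    for s in slots.values():
        store.container(s)  # every slot claimed and reachable


def test_collision_resolved_by_later_seed_or_fallback(rng):
    store = ColorStore(n_colors=1, seed=2, n_hashes=2)
    # tiny capacity forces collisions quickly; all slots must stay distinct
    heads = [random_dna(21, rng) for _ in range(64)]
    slots = [store.assign_slot(h) for h in heads]
    assert len(set(slots)) == len(slots)
    assert len(store.K) > 0  # some head k-mers overflowed into the fallback


def test_release_and_stability(rng):
    store = ColorStore(n_colors=2, seed=3)
    heads = [random_dna(21, rng) for _ in range(50)]
    slots = [store.assign_slot(h) for h in heads]
    for s, h in zip(slots, heads):
        store.add_pair(s, 0, 0, 1)
    before = {s: set(store.pairs(s)) for s in slots[1:]}
    store.release_slot(slots[0])  # removing one unitig's colors ...
    assert {s: set(store.pairs(s)) for s in slots[1:]} == before  # ... moves nothing
    with pytest.raises(KeyError):
        store.release_slot(slots[0])


# -- graph coloring --------------------------------------------------------


def _ref_graph(tmp_path, genomes, seed=7):
    paths = []
    for i, g in enumerate(genomes):
        p = tmp_path / f"g{i}.fasta"
        write_fasta(p, [(f"g{i}", g)])
        paths.append(p)
    D, _ = build_graph(paths, k=K, g=G, seed=seed, mode="reference")
    return D, paths


def test_single_file_all_rows_color_zero(tmp_path, rng):
    genome = random_dna(800, rng)
    D, paths = _ref_graph(tmp_path, [genome])
    stats = color_graph(D, paths, strict=True)
    assert stats.single_colorset_fraction == 1.0
    for i in range(0, len(genome) - K + 1, 17):
        assert colors_of(D, genome[i : i + K]) == {0}


def test_two_identical_files_both_colors(tmp_path, rng):
    genome = random_dna(600, rng)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta(p1, [("a", genome)])
    write_fasta(p2, [("b", genome)])
    D, _ = build_graph([p1, p2], k=K, g=G, seed=8, mode="reference")
    color_graph(D, [p1, p2], strict=True)
    for i in range(0, len(genome) - K + 1, 23):
        assert colors_of(D, genome[i : i + K]) == {0, 1}


def test_five_color_pangenome_matches_bruteforce(tmp_path):
    ds = simulate_dataset(
        tmp_path, k=K, n_colors=5, genome_len=1500, mut_rate=0.02,
        indel_rate=0.002, write_reads=False, seed=9,
    )
    D, _ = build_graph(ds.genome_files, k=K, g=G, seed=10, mode="reference")
    stats = color_graph(D, ds.genome_files, strict=True)
    truth = color_map(ds.genomes, K)
    for x, expected in truth.items():
        assert colors_of(D, x) == expected
    n_singleton = sum(1 for s in truth.values() if len(s) == 1)
    n_core = sum(1 for s in truth.values() if len(s) == 5)
    n_disp = sum(1 for s in truth.values() if 1 < len(s) < 5)
    assert (stats.n_singleton, stats.n_core, stats.n_dispensable) == (
        n_singleton, n_core, n_disp,
    )
    assert stats.n_kmers == len(truth)


def test_colors_of_absent_kmer_raises(tmp_path, rng):
    D, paths = _ref_graph(tmp_path, [random_dna(500, rng)])
    color_graph(D, paths, strict=True)
    with pytest.raises(KeyError):
        colors_of(D, "A" * K)


def test_add_color_validates_row(tmp_path, rng):
    D, paths = _ref_graph(tmp_path, [random_dna(300, rng)])
    D.colors = ColorStore(n_colors=1, seed=0)
    u = next(iter(D.unitigs()))
    add_color(D, u.id_u, 0, 0)
    assert colors_of(D, u.seq[:K]) == {0}
    with pytest.raises(IndexError):
        add_color(D, u.id_u, u.n_kmers, 0)


def test_split_merge_preserve_color_sets(tmp_path, rng):
    genome = random_dna(400, rng)
    D, paths = _ref_graph(tmp_path, [genome])
    color_graph(D, paths, strict=True)
    before = {x: colors_of(D, x) for x in list(D.kmer_set())}
    # split a long unitig in half, then let the join sweep re-merge it
    u = max(D.unitigs(), key=lambda r: r.n_kmers)
    assert u.n_kmers >= 4
    h = u.n_kmers // 2
    D.split_unitig(u.id_u, [(0, h - 1), (h, u.n_kmers - 1)])
    assert {x: colors_of(D, x) for x in before} == before
    from ccdbg.construct import _join_sweep

    _join_sweep(D)
    assert {x: colors_of(D, x) for x in before} == before
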