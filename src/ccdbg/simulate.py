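"""Synthetic pan-genome and read-set generator with exact truth tables.

Emulates the inputs the graph builder consumes: an ancestor genome, one
mutated descendant per color (substitutions plus small 1-3 bp indels, the
variation profile of closely related strains), and error-bearing short reads
drawn uniformly from each genome at a target coverage.  Alongside the FASTA
and FASTQ files it returns truth tables — per-color canonical k-mer sets and
exact occurrence counts over the reads — computed by direct dictionary
counting, independent of every graph data structure, so they can serve as
oracles for construction and coloring.

All randomness flows from one integer seed through ``numpy``'s PCG64
generator; a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Set

import numpy as np

from .io import write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _canon(s: str) -> str:
    r = _rc(s)
    return s if s <= r else r


def count_kmers(seqs, k: int) -> Counter:
    """Exact canonical k-mer occurrence counts (plain dictionary oracle)."""
    c: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            c[_canon(s[i : i + k])] += 1
    return c


@dataclass
class SyntheticDataset:
    """Generated files plus exact-count truth tables."""

    outdir: Path
    k: int
    genomes: List[str]
    reads: List[List[str]]  # per color
    genome_files: List[Path]
    read_files: List[Path]
    genome_kmers: List[Set[str]] = field(default_factory=list)  # per color
    read_counts: Counter = field(default_factory=Counter)  # over all reads

    @property
    def union_kmers(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.genome_kmers:
            out |= s
        return out

    @property
    def ge2_kmers(self) -> Set[str]:
        """K-mers occurring at least twice across all reads (reads-mode truth)."""
        return {x for x, n in self.read_counts.items() if n >= 2}


def random_genome(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_genome(
    genome: str, mut_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Descendant genome: per-base substitutions and small (1-3 bp) indels."""
    out: List[str] = []
    i = 0
    n = len(genome)
    while i < n:
        r = rng.random()
        if r < mut_rate:
            cur = genome[i]
            out.append("ACGT"[(("ACGT".index(cur)) + rng.integers(1, 4)) % 4])
            i += 1
        elif r < mut_rate + indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                i += size  # deletion
            else:
                out.append(_BASES[rng.integers(0, 4, size=size)].tobytes().decode())
                out.append(genome[i])
                i += 1
        else:
            out.append(genome[i])
            i += 1
    return "".join(out)


def simulate_reads(
    genome: str,
    coverage: float,
    read_len: int,
    err_rate: float,
    rng: np.random.Generator,
) -> List[str]:
    """Uniform single-end reads, both strands, substitution errors only."""
    n = len(genome)
    if n < read_len:
        raise ValueError("genome shorter than read length")
    n_reads = int(np.ceil(n * coverage / read_len))
    starts = rng.integers(0, n - read_len + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    reads: List[str] = []
    for s, fl in zip(starts, flip):
        r = genome[s : s + read_len]
        if fl:
            r = _rc(r)
        if err_rate > 0:
            arr = np.frombuffer(r.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(read_len) < err_rate)[0]
            for p in hits:
                cur = "ACGT".index(chr(arr[p]))
                arr[p] = ord("ACGT"[(cur + int(rng.integers(1, 4))) % 4])
            r = arr.tobytes().decode()
        reads.append(r)
    return reads


def simulate_dataset(
    outdir,
    k: int = 31,
    n_colors: int = 1,
    genome_len: int = 8000,
    mut_rate: float = 0.01,
    indel_rate: float = 0.001,
    coverage: float = 30.0,
    read_len: int = 100,
    err_rate: float = 0.005,
    seed: int = 0,
    write_reads: bool = True,
) -> SyntheticDataset:
    """Generate a pan-genome dataset under ``outdir`` and its truth tables.

    Defaults model the test regime throughout the package: kilobase-scale
    genomes, ~1% inter-strain divergence, 30x coverage of 100 bp reads with
    0.5% substitution error.  Color 0 is the ancestor itself; colors 1..C-1
    are independently mutated descendants.
    """
    if not 0 <= mut_rate < 1 or not 0 <= indel_rate < 1 or not 0 <= err_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    if genome_len < k:
        raise ValueError(f"genome_len {genome_len} < k {k}")
    if n_colors < 1:
        raise ValueError("need at least one color")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ancestor = random_genome(genome_len, rng)
    genomes = [ancestor]
    for _ in range(1, n_colors):
        genomes.append(mutate_genome(ancestor, mut_rate, indel_rate, rng))

    genome_files: List[Path] = []
    read_files: List[Path] = []
    all_reads: List[List[str]] = []
    for c, gseq in enumerate(genomes):
        gpath = outdir / f"color_{c:02d}.fasta"
        write_fasta(gpath, [(f"genome_{c}", gseq)])
        genome_files.append(gpath)
        if write_reads:
            reads = simulate_reads(gseq, coverage, read_len, err_rate, rng)
            rpath = outdir / f"reads_{c:02d}.fastq"
            write_fastq(rpath, ((f"read_{c}_{i}", r) for i, r in enumerate(reads)))
            read_files.append(rpath)
            all_reads.append(reads)
        else:
            all_reads.append([])

    ds = SyntheticDataset(
        outdir=outdir,
        k=k,
        genomes=genomes,
        reads=all_reads,
        genome_files=genome_files,
        read_files=read_files,
    )
    ds.genome_kmers = [
        {_canon(g[i : i + k]) for i in range(len(g) - k + 1)} for g in genomes
    ]
    ds.read_counts = count_kmers((r for reads in all_reads for r in reads), k)
    return ds
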