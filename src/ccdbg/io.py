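"""File formats: FASTA/FASTQ input, GFA 1.0 graphs, color sidecars.

Sequence files (plain or gzip) are streamed through Biopython's SeqIO.
Graphs are written as GFA 1.0: one ``S`` line per unitig (sequence verbatim,
in the stored strand-canonical orientation) and one ``L`` line per adjacency
with overlap CIGAR ``(k-1)M``; the header ``H`` line records k, g and the
minimizer-order seed so a reloaded graph reproduces the identical index.

The color sidecar is a little-endian binary file holding the number of
colors, the color-name table, and one record per colored unitig (head k-mer
plus the container payload as sorted (row, color) cell indices); a
human-readable TSV export mirrors it.
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple

from Bio import SeqIO

from .index import FORWARD, REVERSE, CdbgIndex

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".mfa"}
_FASTQ_EXT = {".fq", ".fastq"}

_COLOR_MAGIC = b"CCCO\x01"


class GfaParseError(ValueError):
    pass


# -- sequence input -------------------------------------------------------


def _sniff_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    raise IOError(f"{path}: cannot infer sequence format from extension {ext!r}")


def read_seqs(path) -> Iterator[Tuple[str, str]]:
    """Stream ``(record id, uppercase sequence)`` from FASTA/FASTQ(.gz)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"input file not found: {path}")
    fmt = _sniff_format(path)
    opener = gzip.open if path.suffix.lower() == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
        except ValueError as exc:
            raise IOError(f"{path}: malformed {fmt} record: {exc}") from exc


def read_many(paths: Iterable) -> Iterator[Tuple[str, str]]:
    for p in paths:
        yield from read_seqs(p)


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- GFA ------------------------------------------------------------------


def graph_edges(D: CdbgIndex) -> List[Tuple[int, str, int, str]]:
    """Deduplicated adjacency list as (id_from, orient_from, id_to, orient_to).

    An edge exists when the last k-mer of a unitig (in some orientation)
    overlaps the first k-mer of another by k-1 bases; each undirected link is
    reported once, in its lexicographically smaller representation.
    """
    from .kmers import revcomp

    k = D.k
    edges = set()
    for u in D.unitigs():
        for orient in (FORWARD, REVERSE):
            s = u.seq if orient == FORWARD else revcomp(u.seq)
            tail = s[-k:]
            for cand, hit in D.graph_successors(tail):
                v = D.unitig(hit.id_u)
                # the successor k-mer must sit at the entered end of v
                if hit.strand == FORWARD and hit.offset == 0:
                    ov = FORWARD
                elif hit.strand == REVERSE and hit.offset == v.n_kmers - 1:
                    ov = REVERSE
                else:
                    continue
                e = (u.id_u, orient, hit.id_u, ov)
                flip = (hit.id_u, _flip(ov), u.id_u, _flip(orient))
                edges.add(min(e, flip))
    return sorted(edges)


def _flip(orient: str) -> str:
    return REVERSE if orient == FORWARD else FORWARD


def write_gfa(D: CdbgIndex, path) -> None:
    """GFA 1.0 dump: header with k/g/seed, S-lines, L-lines with (k-1)M."""
    with open(path, "w") as fh:
        fh.write(f"H\tVN:Z:1.0\tKL:i:{D.k}\tGL:i:{D.g}\tSD:i:{D.seed}\n")
        for u in sorted(D.unitigs(), key=lambda r: r.id_u):
            fh.write(f"S\t{u.id_u}\t{u.seq}\n")
        cigar = f"{D.k - 1}M"
        for a, oa, b, ob in graph_edges(D):
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{cigar}\n")


def read_gfa(path, t: int | None = None) -> CdbgIndex:
    """Rebuild a graph from a GFA written by :func:`write_gfa`.

    Unitig ids are reassigned on insertion; the k-mer set, unitig multiset
    and adjacency set are reproduced exactly (node-centric losslessness).
    """
    k = g = seed = None
    seqs: List[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "H":
                for tag in fields[1:]:
                    if tag.startswith("KL:i:"):
                        k = int(tag[5:])
                    elif tag.startswith("GL:i:"):
                        g = int(tag[5:])
                    elif tag.startswith("SD:i:"):
                        seed = int(tag[5:])
            elif fields[0] == "S":
                if len(fields) < 3:
                    raise GfaParseError(f"{path}:{ln}: malformed S-line")
                seqs.append(fields[2])
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GfaParseError(f"{path}:{ln}: malformed L-line")
            # other record types ignored
    if k is None or g is None or seed is None:
        raise GfaParseError(f"{path}: header does not carry k/g/seed tags")
    D = CdbgIndex(k=k, g=g, seed=seed, **({"t": t} if t is not None else {}))
    for s in seqs:
        D.insert_unitig(s)
    return D


# -- color sidecar --------------------------------------------------------


def write_colors(D: CdbgIndex, path) -> None:
    """Binary color sidecar: |C|, names, per-unitig (head k-mer, cells)."""
    store = D.colors
    if store is None:
        raise ValueError("graph has no color layer attached")
    k = D.k
    recs = []
    for u in D.unitigs():
        if u.color_slot is None:
            continue
        cells = sorted(store.pairs(u.color_slot))
        recs.append((u.seq[:k], cells))
    with open(path, "wb") as fh:
        fh.write(_COLOR_MAGIC)
        fh.write(struct.pack("<II", store.n_colors, len(recs)))
        for name in store.color_names:
            b = name.encode()
            fh.write(struct.pack("<H", len(b)) + b)
        for head, cells in recs:
            hb = head.encode()
            fh.write(struct.pack("<HI", len(hb), len(cells)))
            fh.write(hb)
            for i, j in cells:
                fh.write(struct.pack("<II", i, j))


def read_colors(D: CdbgIndex, path) -> None:
    """Attach a color layer to ``D`` from a sidecar written by write_colors."""
    from .colors import ColorStore

    with open(path, "rb") as fh:
        if fh.read(len(_COLOR_MAGIC)) != _COLOR_MAGIC:
            raise ValueError(f"{path}: not a color sidecar")
        n_colors, n_recs = struct.unpack("<II", fh.read(8))
        names = []
        for _ in range(n_colors):
            (ln,) = struct.unpack("<H", fh.read(2))
            names.append(fh.read(ln).decode())
        store = ColorStore(n_colors=n_colors, color_names=names, seed=D.seed)
        D.colors = store
        for _ in range(n_recs):
            ln, nc = struct.unpack("<HI", fh.read(6))
            head = fh.read(ln).decode()
            hit = D.lookup_kmer(head)
            if hit is None:
                raise ValueError(f"{path}: colored head k-mer {head} absent from graph")
            rec = D.unitig(hit.id_u)
            slot = store.assign_slot(rec.seq[: D.k])
            rec.color_slot = slot
            eta = rec.n_kmers
            for _ in range(nc):
                i, j = struct.unpack("<II", fh.read(8))
                # rows were written in the stored orientation of the writer's
                # record, which insert_unitig reproduces deterministically
                store.add_pair(slot, i, j, eta)


def write_colors_tsv(D: CdbgIndex, path) -> None:
    """Human-readable per-k-mer color table (unitig id, offset, colors)."""
    store = D.colors
    if store is None:
        raise ValueError("graph has no color layer attached")
    with open(path, "w") as fh:
        fh.write("unitig\toffset\tcolors\n")
        for u in sorted(D.unitigs(), key=lambda r: r.id_u):
            if u.color_slot is None:
                continue
            by_row = {}
            for i, j in store.pairs(u.color_slot):
                by_row.setdefault(i, []).append(j)
            for i in sorted(by_row):
                cols = ",".join(str(j) for j in sorted(by_row[i]))
                fh.write(f"{u.id_u}\t{i}\t{cols}\n")
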