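"""Per-position allele counts from reads.

Two routes into an :class:`AlleleCountTable`: a built-in ungapped
seed-and-verify mapper for desk-scale synthetic reads, and a reader for
samtools-mpileup-dialect text for interoperability with external mappers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import SENTINEL, encode, revcomp_codes
from .synthetic_pools import ReadSet
from .types import GeneRef

__all__ = [
    "AlleleCountTable",
    "map_and_count",
    "read_mpileup",
    "write_counts_tsv",
    "read_counts_tsv",
]

logger = logging.getLogger(__name__)

SEED_K = 15
SEED_STRIDE = 10
MAX_MISMATCH_FRAC = 0.10

_MISS = -1
_DUP = -2

BASE_COLS = ("A", "C", "G", "T", "other")


@dataclass
class AlleleCountTable:
    """Per (gene, 1-based position) counts of A/C/G/T/other.

    ``counts[gene_id]`` is an (L, 5) int64 array in A,C,G,T,other column
    order; ``ref_codes[gene_id]`` holds the reference base codes.
    """

    counts: dict[str, np.ndarray]
    ref_codes: dict[str, np.ndarray]

    @classmethod
    def empty(cls, genes: Sequence[GeneRef]) -> "AlleleCountTable":
        return cls(
            counts={g.gene_id: np.zeros((len(g), 5), dtype=np.int64) for g in genes},
            ref_codes={g.gene_id: encode(g.sequence) for g in genes},
        )

    def depth(self, gene_id: str) -> np.ndarray:
        return self.counts[gene_id].sum(axis=1)

    def nonref(self, gene_id: str) -> np.ndarray:
        """Count of all non-reference alleles (incl. 'other') per position."""
        c = self.counts[gene_id]
        ref = self.ref_codes[gene_id]
        ref_counts = c[np.arange(len(ref)), ref]
        return c.sum(axis=1) - ref_counts

    def at(self, gene_id: str, position: int) -> np.ndarray:
        """Counts row at a 1-based position."""
        return self.counts[gene_id][position - 1]

    def allele_count(self, gene_id: str, position: int, base: str) -> int:
        return int(self.counts[gene_id][position - 1]["ACGT".index(base)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, c in self.counts.items():
            ref = self.ref_codes[gid]
            df = pd.DataFrame(c, columns=list(BASE_COLS))
            df.insert(0, "gene_id", gid)
            df.insert(1, "position", np.arange(1, len(ref) + 1))
            df.insert(2, "ref", [("ACGTN")[b] for b in ref])
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def write_counts_tsv(
    tables: dict[str, AlleleCountTable], path: str | Path
) -> None:
    frames = []
    for pool_id, table in tables.items():
        df = table.to_frame()
        df.insert(0, "pool_id", pool_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> dict[str, AlleleCountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "gene_id": str})
    tables: dict[str, AlleleCountTable] = {}
    for pool_id, pool_df in df.groupby("pool_id", sort=False):
        counts: dict[str, np.ndarray] = {}
        refs: dict[str, np.ndarray] = {}
        for gid, gdf in pool_df.groupby("gene_id", sort=False):
            gdf = gdf.sort_values("position")
            counts[gid] = gdf[list(BASE_COLS)].to_numpy(dtype=np.int64)
            refs[gid] = encode("".join(gdf["ref"]))
        tables[str(pool_id)] = AlleleCountTable(counts, refs)
    return tables


# ---------------------------------------------------------------------------
# built-in ungapped mapper
# ---------------------------------------------------------------------------


@dataclass
class _RefIndex:
    concat: np.ndarray  # padded concatenation of gene codes
    gene_ids: list[str]
    offsets: np.ndarray  # start of each gene in concat
    lengths: np.ndarray
    uniq_kmers: np.ndarray  # sorted kmer values occurring exactly once
    uniq_pos: np.ndarray  # their positions in concat
    dup_kmers: np.ndarray  # sorted kmer values occurring more than once

    pad: int = 0


def _build_index(genes: Sequence[GeneRef], read_length: int) -> _RefIndex:
    if not genes:
        raise ValueError("empty reference set")
    pad = read_length  # gap long enough that no read spans two genes
    pieces, offsets, lengths, gene_ids = [], [], [], []
    cursor = 0
    gap = np.full(pad, SENTINEL, dtype=np.uint8)
    for g in genes:
        offsets.append(cursor)
        codes = encode(g.sequence)
        pieces.append(codes)
        pieces.append(gap)
        lengths.append(len(codes))
        gene_ids.append(g.gene_id)
        cursor += len(codes) + pad
    concat = np.concatenate(pieces)

    k = SEED_K
    n = len(concat) - k + 1
    x = concat.astype(np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = vals * 4 + x[j : n + j]
    bad = (concat >= 4).astype(np.int64)
    badcum = np.concatenate([[0], np.cumsum(bad)])
    valid = (badcum[k:] - badcum[:-k]) == 0  # window free of sentinels
    vals = vals[valid]
    pos = np.nonzero(valid)[0]

    order = np.argsort(vals, kind="stable")
    sv, sp = vals[order], pos[order]
    uniq, first, counts = np.unique(sv, return_index=True, return_counts=True)
    single = counts == 1
    return _RefIndex(
        concat=concat,
        gene_ids=gene_ids,
        offsets=np.array(offsets),
        lengths=np.array(lengths),
        uniq_kmers=uniq[single],
        uniq_pos=sp[first[single]],
        dup_kmers=uniq[~single],
        pad=pad,
    )


def _seed_candidates(reads: np.ndarray, index: _RefIndex) -> np.ndarray:
    """(n_reads, n_seeds) candidate read-start positions in concat space."""
    n, rl = reads.shape
    seed_offsets = np.arange(0, rl - SEED_K + 1, SEED_STRIDE)
    pows = (4 ** np.arange(SEED_K - 1, -1, -1)).astype(np.uint64)
    cands = np.full((n, len(seed_offsets)), _MISS, dtype=np.int64)
    for col, off in enumerate(seed_offsets):
        kmers = reads[:, off : off + SEED_K].astype(np.uint64) @ pows
        if len(index.uniq_kmers):
            idx = np.searchsorted(index.uniq_kmers, kmers)
            idx = np.minimum(idx, len(index.uniq_kmers) - 1)
            hit = index.uniq_kmers[idx] == kmers
            cands[hit, col] = index.uniq_pos[idx[hit]] - off
        else:
            hit = np.zeros(n, dtype=bool)
        if len(index.dup_kmers):
            didx = np.searchsorted(index.dup_kmers, kmers)
            didx = np.minimum(didx, len(index.dup_kmers) - 1)
            dup = (index.dup_kmers[didx] == kmers) & ~hit
            cands[dup, col] = _DUP
    return cands


def _verify(
    reads: np.ndarray, starts: np.ndarray, index: _RefIndex
) -> np.ndarray:
    """Hamming distance of each read against concat at the given start."""
    rl = reads.shape[1]
    limit = len(index.concat) - rl
    ok = (starts >= 0) & (starts <= limit)
    dist = np.full(len(starts), rl + 1, dtype=np.int64)
    if ok.any():
        seg = index.concat[starts[ok, None] + np.arange(rl)]
        dist[ok] = (seg != reads[ok]).sum(axis=1)
    return dist


def _best_candidates(cands: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modal valid candidate per row and whether another distinct one exists."""
    s = np.sort(cands, axis=1)
    n, m = s.shape
    best = np.full(n, _MISS, dtype=np.int64)
    best_run = np.zeros(n, dtype=np.int64)
    run = np.ones(n, dtype=np.int64)
    valid0 = s[:, 0] >= 0
    best = np.where(valid0, s[:, 0], best)
    best_run = np.where(valid0, 1, 0)
    for j in range(1, m):
        cont = (s[:, j] == s[:, j - 1]) & (s[:, j] >= 0)
        run = np.where(cont, run + 1, 1)
        take = (s[:, j] >= 0) & (run >= best_run)
        best = np.where(take, s[:, j], best)
        best_run = np.where(take, run, best_run)
    # another distinct valid candidate?
    nvalid = (cands >= 0).sum(axis=1)
    multi = nvalid > best_run
    return best, multi


def _map_orientation(
    reads: np.ndarray, index: _RefIndex
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best start, distance and ambiguity flag for one read orientation."""
    rl = reads.shape[1]
    cands = _seed_candidates(reads, index)
    best, multi = _best_candidates(cands)
    dist = _verify(reads, best, index)
    ambiguous = np.zeros(len(reads), dtype=bool)
    # rare rows where seeds disagree: check every distinct candidate
    for i in np.nonzero(multi)[0]:
        row = np.unique(cands[i][cands[i] >= 0])
        dists = _verify(np.repeat(reads[i : i + 1], len(row), axis=0), row, index)
        j = int(np.argmin(dists))
        best[i], dist[i] = row[j], dists[j]
        if (dists == dists[j]).sum() > 1:
            ambiguous[i] = True
    # all seeds hit duplicated kmers -> equally good placements elsewhere
    all_dup_or_miss = (cands < 0).all(axis=1) & (cands == _DUP).any(axis=1)
    ambiguous |= all_dup_or_miss
    dist[all_dup_or_miss] = rl + 1
    return best, dist, ambiguous


def map_and_count(
    reads: ReadSet | str | Path,
    genes: Sequence[GeneRef],
    chunk_size: int = 250_000,
) -> AlleleCountTable:
    """Map substitution-only reads to the references and pile up alleles.

    Each read is assigned to the (gene, offset, strand) minimizing Hamming
    distance over exact seed hits; reads with best distance above 10% of the
    read length, or with tied best placements, are discarded.
    """
    if isinstance(reads, (str, Path)):
        reads = ReadSet.from_fastq(reads)
    if not genes:
        raise ValueError("empty reference set")
    rl = reads.codes.shape[1] if len(reads) else 100
    index = _build_index(genes, rl)
    max_mm = int(MAX_MISMATCH_FRAC * rl)

    flat_counts = np.zeros(len(index.concat) * 5, dtype=np.int64)
    n_unmapped = 0
    for lo in range(0, len(reads), chunk_size):
        chunk = reads.codes[lo : lo + chunk_size]
        fwd_start, fwd_dist, fwd_amb = _map_orientation(chunk, index)
        rc = revcomp_codes(chunk)
        rev_start, rev_dist, rev_amb = _map_orientation(rc, index)

        use_rev = rev_dist < fwd_dist
        tie = (rev_dist == fwd_dist) & (rev_dist <= max_mm)
        start = np.where(use_rev, rev_start, fwd_start)
        dist = np.where(use_rev, rev_dist, fwd_dist)
        amb = np.where(use_rev, rev_amb, fwd_amb) | tie
        mapped = (dist <= max_mm) & ~amb
        n_unmapped += int((~mapped).sum())

        oriented = np.where(use_rev[:, None], rc, chunk)[mapped]
        gpos = start[mapped, None] + np.arange(rl)
        flat = gpos * 5 + oriented
        flat_counts += np.bincount(
            flat.ravel(), minlength=len(flat_counts)
        )

    if n_unmapped:
        logger.info("map_and_count: %d reads discarded", n_unmapped)

    all_counts = flat_counts.reshape(-1, 5)
    table = AlleleCountTable.empty(genes)
    for gid, off, L in zip(index.gene_ids, index.offsets, index.lengths):
        block = all_counts[off : off + L]
        table.counts[gid][:, :4] = block[:, :4]
        table.counts[gid][:, 4] = block[:, 4]
    return table


# ---------------------------------------------------------------------------
# mpileup-dialect reader
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _parse_bases(bases: str, ref: str, line_no: int) -> np.ndarray:
    """Counts (A,C,G,T,other) from one mpileup base string."""
    out = np.zeros(5, dtype=np.int64)
    ref_idx = "ACGT".index(ref.upper()) if ref.upper() in "ACGT" else 4
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # mapping-quality char follows, not a base
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(f"line {line_no}: malformed indel block")
            run = int(m.group(1))
            i = m.end() + run
            continue
        if c in ".,":
            out[ref_idx] += 1
        elif c.upper() in "ACGT":
            out["ACGT".index(c.upper())] += 1
        elif c in "*Nn><":
            out[4] += 1
        else:
            raise ValueError(f"line {line_no}: unexpected symbol {c!r}")
        i += 1
    return out


def read_mpileup(path: str | Path, genes: Sequence[GeneRef]) -> AlleleCountTable:
    """Parse 6-column samtools-mpileup text into allele counts."""
    table = AlleleCountTable.empty(genes)
    known = set(table.counts)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {line_no}: expected >= 4 columns")
            chrom, pos_s, ref, depth_s = fields[:4]
            if chrom not in known:
                raise ValueError(f"line {line_no}: unknown gene {chrom!r}")
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: bad integer field") from exc
            if not 1 <= pos <= len(table.ref_codes[chrom]):
                raise ValueError(f"line {line_no}: position out of range")
            if depth == 0:
                continue  # zero-count row: row exists in the table already
            if len(fields) < 6:
                raise ValueError(f"line {line_no}: expected 6 columns")
            table.counts[chrom][pos - 1] += _parse_bases(
                fields[4], ref, line_no
            )
    return table


def write_sam(
    reads: ReadSet,
    genes: Sequence[GeneRef],
    path: str | Path,
) -> None:
    """Debug output: map reads and emit a minimal SAM subset."""
    from ._seq import decode

    index = _build_index(genes, reads.codes.shape[1] if len(reads) else 100)
    rl = reads.codes.shape[1]
    max_mm = int(MAX_MISMATCH_FRAC * rl)
    names = reads.names or [f"read{i}" for i in range(len(reads))]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for g in genes:
            fh.write(f"@SQ\tSN:{g.gene_id}\tLN:{len(g)}\n")
        fwd_start, fwd_dist, fwd_amb = _map_orientation(reads.codes, index)
        rc = revcomp_codes(reads.codes)
        rev_start, rev_dist, rev_amb = _map_orientation(rc, index)
        for i, name in enumerate(names):
            if rev_dist[i] < fwd_dist[i]:
                start, dist, amb, flag = rev_start[i], rev_dist[i], rev_amb[i], 16
                seq = decode(rc[i])
            else:
                start, dist, amb, flag = fwd_start[i], fwd_dist[i], fwd_amb[i], 0
                seq = decode(reads.codes[i])
            if dist > max_mm or amb:
                fh.write(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            gi = int(np.searchsorted(index.offsets, start, side="right") - 1)
            local = int(start - index.offsets[gi]) + 1
            fh.write(
                f"{name}\t{flag}\t{index.gene_ids[gi]}\t{local}\t60\t{rl}M"
                f"\t*\t0\t0\t{seq}\t*\n"
            )
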