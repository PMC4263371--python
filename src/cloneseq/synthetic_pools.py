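"""Synthetic pooled-mutagenesis experiments with known ground truth.

Models the pooled verification experiment: for every desired mutation, one
colony is picked per pool; each colony either carries the desired change
(Bernoulli success) or is pure wild type; PCR may introduce unwanted
substitutions anywhere else in the clone; all colonies of a pool contribute
the same expected number of reads (DNA normalization) and reads acquire
flat-rate substitution sequencing errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import decode_rows, encode, revcomp_codes
from .types import ColonyTruth, GeneRef, MutationSpec, PoolManifest, TruthTable

__all__ = [
    "SimConfig",
    "ReadSet",
    "simulate_pools",
    "random_genes",
    "random_mutations",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated pooled sequencing experiment."""

    p_success: float = 0.8
    pcr_error_rate: float = 1.3e-4
    seq_error_rate: float = 1e-3
    coverage: float = 2500.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_success", "pcr_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass
class ReadSet:
    """Reads of one pool as an (n_reads, read_length) code matrix."""

    codes: np.ndarray
    names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.codes.shape[0]

    def write_fastq(self, path: str | Path) -> None:
        qual = "I" * self.codes.shape[1]
        names = self.names or [f"read{i}" for i in range(len(self))]
        with open(path, "w") as fh:
            for name, seq in zip(names, decode_rows(self.codes)):
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        names: list[str] = []
        seqs: list[np.ndarray] = []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()  # '+'
                fh.readline()  # qualities
                names.append(header[1:].split()[0])
                seqs.append(encode(seq))
        if not seqs:
            return cls(np.zeros((0, 0), dtype=np.uint8), [])
        return cls(np.vstack(seqs), names)


def random_genes(
    n_genes: int,
    rng: np.random.Generator,
    min_len: int = 500,
    max_len: int = 2500,
    prefix: str = "gene",
    gc: float = 0.5,
) -> list[GeneRef]:
    """Random reference ORFs with the given expected GC fraction."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        genes.append(GeneRef(f"{prefix}{i + 1:04d}", _decode1(codes)))
    return genes


def _decode1(codes: np.ndarray) -> str:
    from ._seq import decode

    return decode(codes)


def random_mutations(
    genes: Sequence[GeneRef],
    n_mutations: int,
    rng: np.random.Generator,
    margin: int = 30,
    genes_cycle: Sequence[str] | None = None,
) -> list[MutationSpec]:
    """Random single-nt substitutions, spread over ``genes_cycle`` if given
    (a sequence of gene_ids, one per mutation), else round-robin."""
    by_id = {g.gene_id: g for g in genes}
    if genes_cycle is None:
        genes_cycle = [genes[i % len(genes)].gene_id for i in range(n_mutations)]
    if len(genes_cycle) != n_mutations:
        raise ValueError("genes_cycle length must equal n_mutations")
    muts: list[MutationSpec] = []
    used: set[tuple[str, int]] = set()
    for gid in genes_cycle:
        gene = by_id[gid]
        while True:
            pos = int(rng.integers(margin + 1, len(gene) - margin + 1))
            if (gid, pos) not in used:
                break
        used.add((gid, pos))
        ref = gene.sequence[pos - 1]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        muts.append(MutationSpec(gid, pos, ref, alt))
    return muts


def simulate_pools(
    genes: Sequence[GeneRef],
    mutations: Sequence[MutationSpec],
    n_pools: int,
    config: SimConfig,
    out_dir: str | Path | None = None,
    with_read_names: bool = False,
) -> tuple[PoolManifest, dict[str, ReadSet], TruthTable]:
    """Simulate the pooled experiment; optionally write FASTQ/TSV/JSON.

    Returns the pool manifest, one in-memory ReadSet per pool, and the
    table of planted truths. Deterministic for a fixed config seed.
    """
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    by_id = {g.gene_id: g for g in genes}
    for m in mutations:
        if m.gene_id not in by_id:
            raise ValueError(f"{m.mutation_id}: unknown gene {m.gene_id!r}")
        m.validate_against(by_id[m.gene_id])

    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    manifest = PoolManifest()
    truth = TruthTable()
    readsets: dict[str, ReadSet] = {}

    encoded = {g.gene_id: encode(g.sequence) for g in genes}

    for pool_idx in range(1, n_pools + 1):
        pool_id = f"pool{pool_idx}"
        colonies: list[tuple[ColonyTruth, np.ndarray]] = []
        for m in mutations:
            manifest.add(m, pool_id)
            success = bool(rng.random() < config.p_success)
            ref_codes = encoded[m.gene_id]
            colony = ref_codes.copy()
            if success:
                colony[m.position - 1] = "ACGT".index(m.alt_base)
            unwanted: list[tuple[int, str]] = []
            if config.pcr_error_rate > 0:
                n_err = rng.binomial(len(colony), config.pcr_error_rate)
                if n_err:
                    sites = rng.choice(len(colony), size=n_err, replace=False)
                    for s in np.sort(sites):
                        if s == m.position - 1:
                            continue  # desired site is never also "unwanted"
                        old = colony[s]
                        new = (old + 1 + rng.integers(0, 3)) % 4
                        colony[s] = new
                        unwanted.append((int(s) + 1, "ACGT"[new]))
            ct = ColonyTruth(m, pool_id, success, tuple(unwanted))
            truth.colonies.append(ct)
            colonies.append((ct, colony))

        readsets[pool_id] = _sample_reads(
            colonies, config, rng, with_read_names
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_tsv(out / "manifest.tsv")
        truth.to_json(out / "truth.json")
        for pool_id, rs in readsets.items():
            rs.write_fastq(out / f"{pool_id}.fastq")

    return manifest, readsets, truth


def _sample_reads(
    colonies: list[tuple[ColonyTruth, np.ndarray]],
    config: SimConfig,
    rng: np.random.Generator,
    with_read_names: bool,
) -> ReadSet:
    """DNA-normalized read sampling: equal expected read count per colony."""
    rl = config.read_length
    lengths = np.array([len(c) for _, c in colonies])
    if (lengths < rl).any():
        raise ValueError("gene shorter than read length")
    n_total = int(round(config.coverage * lengths.sum() / rl))
    n_col = len(colonies)
    per_colony = rng.multinomial(n_total, np.full(n_col, 1.0 / n_col))

    # warn when a target site is expected to be essentially unsequenced
    exp_depth = per_colony * rl / lengths
    for (ct, _), d in zip(colonies, exp_depth):
        if d < 1.0:
            warnings.warn(
                f"{ct.colony_id}: expected depth {d:.2f} < 1 at target site",
                stacklevel=3,
            )

    chunks: list[np.ndarray] = []
    names: list[str] = []
    for (ct, colony), n_c in zip(colonies, per_colony):
        if n_c == 0:
            continue
        starts = rng.integers(0, len(colony) - rl + 1, size=n_c)
        reads = colony[starts[:, None] + np.arange(rl)]
        if config.seq_error_rate > 0:
            n_err = rng.binomial(reads.size, config.seq_error_rate)
            if n_err:
                flat = rng.choice(reads.size, size=n_err, replace=False)
                shift = 1 + rng.integers(0, 3, size=n_err).astype(np.uint8)
                reads.flat[flat] = (reads.flat[flat] + shift) % 4
        flip = rng.random(n_c) < 0.5
        if flip.any():
            reads[flip] = revcomp_codes(reads[flip])
        chunks.append(reads)
        if with_read_names:
            names.extend(f"{ct.colony_id}:{i}" for i in range(n_c))
    if not chunks:
        codes = np.zeros((0, rl), dtype=np.uint8)
    else:
        codes = np.vstack(chunks)
    return ReadSet(codes, names)
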