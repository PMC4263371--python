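"""Reference experiment harnesses used by the acceptance script and tests.

Each function rebuilds one benchmark experiment from scratch: synthetic
references and desired mutations, pooled read simulation, mapping, and
calling. The three pooled-calling experiments mirror the published scale
(156, 452 and 3,528 colonies at success probabilities 0.80 / 0.82 / 0.84);
coverage is set to desk scale where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clone_caller import (
    SScoreRecord,
    UnwantedFlag,
    detect_unwanted,
    estimate_background,
    score_mutations,
)
from .pileup import map_and_count
from .synthetic_pools import (
    ReadSet,
    SimConfig,
    random_genes,
    random_mutations,
    simulate_pools,
)
from .types import GeneRef, MutationSpec, PoolManifest, TruthTable

__all__ = [
    "CallingExperiment",
    "pooled_calling_experiment",
    "t1_experiment",
    "t2_experiment",
    "t3_experiment",
    "unwanted_rate_experiment",
    "primer_batch_experiment",
]


@dataclass
class CallingExperiment:
    genes: list[GeneRef]
    mutations: list[MutationSpec]
    manifest: PoolManifest
    truth: TruthTable
    scores: list[SScoreRecord]

    @property
    def n_colonies(self) -> int:
        return len(self.truth)

    @property
    def n_called(self) -> int:
        return sum(1 for r in self.scores if r.called)

    @property
    def n_planted_successes(self) -> int:
        return len(self.truth.successes())

    def success_s_scores(self) -> list[float]:
        planted = {
            (c.mutation.mutation_id, c.pool_id): c.success
            for c in self.truth.colonies
        }
        return [
            r.s
            for r in self.scores
            if r.s is not None and planted[(r.mutation.mutation_id, r.pool_id)]
        ]

    def failure_s_scores(self) -> list[float]:
        planted = {
            (c.mutation.mutation_id, c.pool_id): c.success
            for c in self.truth.colonies
        }
        return [
            r.s
            for r in self.scores
            if r.s is not None
            and not planted[(r.mutation.mutation_id, r.pool_id)]
        ]


def pooled_calling_experiment(
    n_mutations: int,
    n_genes: int,
    n_pools: int,
    p_success: float,
    coverage: float,
    seed: int,
    gene_len: tuple[int, int] = (500, 2500),
    seq_error: float = 1e-3,
    pcr_error: float = 0.0,
    genes_cycle: list[str] | None = None,
    big_gene: tuple[int, int] | None = None,
) -> CallingExperiment:
    """Simulate, map and score one pooled mutagenesis experiment.

    ``big_gene=(length, n_mutations_on_it)`` forces one long gene carrying
    many co-pooled mutations (high k).
    """
    rng = np.random.default_rng(seed)
    genes = random_genes(n_genes, rng, *gene_len)
    if big_gene is not None:
        big_len, big_n = big_gene
        codes = rng.integers(0, 4, size=big_len).astype(np.uint8)
        from ._seq import decode

        genes[0] = GeneRef(genes[0].gene_id, decode(codes))
        rest = n_mutations - big_n
        cycle = [genes[0].gene_id] * big_n + [
            genes[1 + i % (n_genes - 1)].gene_id for i in range(rest)
        ]
        genes_cycle = cycle
    mutations = random_mutations(genes, n_mutations, rng, genes_cycle=genes_cycle)
    config = SimConfig(
        p_success=p_success,
        pcr_error_rate=pcr_error,
        seq_error_rate=seq_error,
        coverage=coverage,
        seed=seed,
    )
    manifest, readsets, truth = simulate_pools(genes, mutations, n_pools, config)
    counts = {p: map_and_count(rs, genes) for p, rs in readsets.items()}
    scores = score_mutations(counts, manifest)
    return CallingExperiment(genes, mutations, manifest, truth, scores)


def t1_experiment(seed: int = 1) -> CallingExperiment:
    """39 mutations, 39 genes, 4 pools, p=0.80, ~2500x (156 colonies)."""
    return pooled_calling_experiment(
        n_mutations=39,
        n_genes=39,
        n_pools=4,
        p_success=0.80,
        coverage=2500.0,
        seed=seed,
    )


def t2_experiment(seed: int = 1) -> CallingExperiment:
    """113 mutations on 66 genes (k>1), 4 pools, p=0.82, ~1000x."""
    return pooled_calling_experiment(
        n_mutations=113,
        n_genes=66,
        n_pools=4,
        p_success=0.82,
        coverage=1000.0,
        seed=seed,
        gene_len=(500, 1500),
    )


def t3_experiment(seed: int = 1) -> CallingExperiment:
    """882 mutations across 300 genes incl. one gene with 40 (k up to 40),
    4 pools, p=0.84, coverage reduced to ~100x for desk scale."""
    return pooled_calling_experiment(
        n_mutations=882,
        n_genes=300,
        n_pools=4,
        p_success=0.84,
        coverage=100.0,
        seed=seed,
        gene_len=(400, 1200),
        big_gene=(2400, 40),
    )


def unwanted_rate_experiment(
    seed: int,
    n_seeds: int = 50,
    coverage: float = 600.0,
    n_colonies: int = 39,
    pcr_error: float = 1.3e-4,
) -> dict:
    """Planted-PCR-error recovery: flagged unwanted mutations per cloned
    base, averaged over ``n_seeds`` independent single-pool experiments.

    Genes average ~900 nt; returns the estimated rate, the planted rate,
    and bookkeeping for tolerance computation.
    """
    total_flags = 0
    total_planted = 0
    total_bases = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * i)
        genes = random_genes(n_colonies, rng, 700, 1100)
        mutations = random_mutations(genes, n_colonies, rng)
        config = SimConfig(
            p_success=0.80,
            pcr_error_rate=pcr_error,
            seq_error_rate=1e-3,
            coverage=coverage,
            seed=seed + 1000 * i,
        )
        manifest, readsets, truth = simulate_pools(genes, mutations, 1, config)
        counts = {p: map_and_count(rs, genes) for p, rs in readsets.items()}
        bg = {
            p: estimate_background(t, manifest, p) for p, t in counts.items()
        }
        flags = detect_unwanted(counts, manifest, bg, alpha=0.2)
        total_flags += len(flags)
        total_planted += sum(len(c.unwanted) for c in truth.colonies)
        total_bases += sum(len(g) for g in genes)
    return {
        "rate": total_flags / total_bases,
        "rate_percent": 100.0 * total_flags / total_bases,
        "planted_rate": pcr_error,
        "planted_events": total_planted,
        "flagged_events": total_flags,
        "total_bases": total_bases,
        "n_seeds": n_seeds,
    }


def primer_batch_experiment(seed: int = 1, n_jobs: int = 500) -> dict:
    """Batch primer design on GC-rich synthetic templates."""
    from .primer_design import design_batch

    rng = np.random.default_rng(seed)
    genes = random_genes(n_jobs, rng, 300, 900, gc=0.6)
    mutations = random_mutations(genes, n_jobs, rng)
    by_id = {g.gene_id: g for g in genes}
    jobs = [(by_id[m.gene_id], m) for m in mutations]
    pairs, failures = design_batch(jobs)
    primers = [
        c
        for pair in pairs
        if pair is not None
        for c in (pair.forward, pair.reverse)
    ]
    return {
        "jobs": jobs,
        "pairs": pairs,
        "failures": failures,
        "n_primers": len(primers),
        "max_length": max(c.n for c in primers) if primers else 0,
        "min_tm": min(c.tm for c in primers) if primers else float("nan"),
    }
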