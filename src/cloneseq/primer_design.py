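"""QuikChange-style mutagenesis primer design.

A primer pair is a 30-50 bp window of the template carrying the desired
substitution at, or one base from, its center, together with its exact
reverse complement. Accepted primers start and end with G or C, meet a GC
content threshold (40%, relaxable to 30%), and reach a melting temperature
of at least 78 degrees C under

    Tm = 81.5 + 0.41 * %GC - 675 / N - %mismatch

with %GC and %mismatch rounded to whole-number percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import GeneRef, MutationSpec

__all__ = [
    "PrimerCandidate",
    "PrimerPair",
    "DesignError",
    "melting_temperature",
    "design_pair",
    "design_batch",
]

MIN_LEN = 30
MAX_LEN = 50
GC_THRESHOLD = 40
GC_THRESHOLD_RELAXED = 30
TM_THRESHOLD = 78.0
EDGE_MARGIN = 25

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DesignError(ValueError):
    """Raised when no primer satisfies the design criteria."""


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    start: int  # 1-based template coordinate of the first primer base
    end: int  # 1-based, inclusive
    n: int
    pct_gc: int
    pct_mismatch: int
    tm: float
    mutation_offset: int


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    relaxed: bool = False


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def melting_temperature(n: int, pct_gc: int, pct_mismatch: int) -> float:
    """Tm in degrees C; %GC and %mismatch are whole-number percentages."""
    if n <= 0:
        raise ValueError("primer length must be positive")
    return 81.5 + 0.41 * pct_gc - 675.0 / n - pct_mismatch


def _center(n: int) -> int:
    """1-based center position: N/2 for even N, (N+1)/2 for odd."""
    return n // 2 if n % 2 == 0 else (n + 1) // 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _candidates(gene: GeneRef, mutation: MutationSpec) -> Iterable[PrimerCandidate]:
    """Every (N, offset) window candidate, unfiltered."""
    template = gene.sequence
    L = len(template)
    p = mutation.position
    for n in range(MIN_LEN, MAX_LEN + 1):
        center = _center(n)
        for off in (-1, 0, 1):
            j = center + off  # 1-based index of the mutated base in the primer
            if not 1 <= j <= n:
                continue
            start = p - j + 1
            end = start + n - 1
            if start < 1 or end > L:
                continue
            seq = (
                template[start - 1 : p - 1]
                + mutation.alt_base
                + template[p:end]
            )
            gc = sum(1 for c in seq if c in "GC")
            pct_gc = _round_half_up(100.0 * gc / n)
            pct_mm = _round_half_up(100.0 / n)  # one substituted base
            tm = melting_temperature(n, pct_gc, pct_mm)
            yield PrimerCandidate(seq, start, end, n, pct_gc, pct_mm, tm, off)


def _passes(c: PrimerCandidate, gc_threshold: int) -> bool:
    return (
        c.sequence[0] in "GC"
        and c.sequence[-1] in "GC"
        and c.pct_gc >= gc_threshold
        and c.tm >= TM_THRESHOLD
    )


def _rank_key(c: PrimerCandidate) -> tuple:
    return (-c.tm, c.n, abs(c.mutation_offset), c.start)


def design_pair(
    gene: GeneRef, mutation: MutationSpec, relax: bool = True
) -> PrimerPair:
    """Best-ranked primer pair for one mutation.

    Ranking among passing candidates: highest Tm, then shortest length,
    then centered mutation, then leftmost start. When no candidate meets
    the 40% GC bound and ``relax`` is true, the bound drops to 30%.
    """
    mutation.validate_against(gene)
    p, L = mutation.position, len(gene)
    if p - 1 < EDGE_MARGIN or L - p < EDGE_MARGIN:
        raise DesignError(
            f"{mutation.mutation_id}: site within {EDGE_MARGIN} nt of a "
            "template end"
        )
    pool = list(_candidates(gene, mutation))
    passing = [c for c in pool if _passes(c, GC_THRESHOLD)]
    relaxed = False
    if not passing and relax:
        passing = [c for c in pool if _passes(c, GC_THRESHOLD_RELAXED)]
        relaxed = True
    if not passing:
        failed = _failure_report(pool)
        raise DesignError(
            f"{mutation.mutation_id}: no candidate passes ({failed})"
        )
    best = min(passing, key=_rank_key)
    rev_seq = reverse_complement(best.sequence)
    reverse = PrimerCandidate(
        rev_seq,
        best.start,
        best.end,
        best.n,
        best.pct_gc,
        best.pct_mismatch,
        best.tm,
        best.mutation_offset,
    )
    return PrimerPair(best, reverse, relaxed)


def _failure_report(pool: list[PrimerCandidate]) -> str:
    if not pool:
        return "no window fits the template"
    fails = []
    if not any(c.sequence[0] in "GC" and c.sequence[-1] in "GC" for c in pool):
        fails.append("G/C terminal bases")
    if not any(c.pct_gc >= GC_THRESHOLD_RELAXED for c in pool):
        fails.append("GC content >= 30%")
    if not any(c.tm >= TM_THRESHOLD for c in pool):
        fails.append("Tm >= 78C")
    return "failed criteria: " + (", ".join(fails) or "joint constraints")


def design_batch(
    jobs: Sequence[tuple[GeneRef, MutationSpec]],
) -> tuple[list[PrimerPair | None], list[tuple[int, str]]]:
    """Independent per-job design; failures are collected, not fatal.

    Returns (pairs, failures) where ``pairs[i]`` is None for failed jobs
    and ``failures`` holds (job index, error message) entries.
    """
    pairs: list[PrimerPair | None] = []
    failures: list[tuple[int, str]] = []
    for i, (gene, mutation) in enumerate(jobs):
        try:
            pairs.append(design_pair(gene, mutation, relax=True))
        except (DesignError, ValueError) as exc:
            pairs.append(None)
            failures.append((i, str(exc)))
    return pairs, failures


def batch_to_frame(
    jobs: Sequence[tuple[GeneRef, MutationSpec]],
    pairs: Sequence[PrimerPair | None],
) -> pd.DataFrame:
    rows = []
    for (gene, mutation), pair in zip(jobs, pairs):
        if pair is None:
            continue
        rows.append(
            {
                "mutation_id": mutation.mutation_id,
                "fwd_seq": pair.forward.sequence,
                "rev_seq": pair.reverse.sequence,
                "N": pair.forward.n,
                "pct_gc": pair.forward.pct_gc,
                "tm": pair.forward.tm,
                "relaxed_flag": pair.relaxed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mutation_id",
            "fwd_seq",
            "rev_seq",
            "N",
            "pct_gc",
            "tm",
            "relaxed_flag",
        ],
    )


def write_batch_tsv(
    jobs: Sequence[tuple[GeneRef, MutationSpec]],
    pairs: Sequence[PrimerPair | None],
    path: str | Path,
) -> None:
    batch_to_frame(jobs, pairs).to_csv(path, sep="\t", index=False)
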