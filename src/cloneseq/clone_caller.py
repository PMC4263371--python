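"""Pooled-colony calling: S scores, unwanted-mutation flags, clone verdicts.

For each attempted mutation in a pool the score S = k * R_mut / R_all
normalizes the alt-allele read fraction by k, the number of distinct
attempted mutations for the same gene co-pooled together; a colony is
called mutation-positive when S > 0.8. Non-target positions are screened
for unwanted PCR-introduced substitutions against the pool's sequencing
error background with a cumulative binomial test at P < 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup import AlleleCountTable
from .types import MutationSpec, PoolManifest

__all__ = [
    "SScoreRecord",
    "BackgroundRate",
    "UnwantedFlag",
    "CloneVerdict",
    "score_mutations",
    "estimate_background",
    "detect_unwanted",
    "resolve_clones",
    "call_pools",
]

logger = logging.getLogger(__name__)

S_THRESHOLD = 0.8
ALPHA = 0.2
B_HAT_FLOOR = 1e-6
MIN_BACKGROUND_POSITIONS = 100


@dataclass(frozen=True)
class SScoreRecord:
    mutation: MutationSpec
    pool_id: str
    r_mut: int
    r_all: int
    k: int
    s: float | None
    called: bool


@dataclass(frozen=True)
class BackgroundRate:
    pool_id: str
    b_hat: float
    n_positions: int


@dataclass(frozen=True)
class UnwantedFlag:
    gene_id: str
    pool_id: str
    position: int
    nonref_count: int
    depth: int
    p_value: float
    attributed_colony: str  # colony_id or "ambiguous"


@dataclass(frozen=True)
class CloneVerdict:
    mutation: MutationSpec
    chosen_pool: str | None
    status: str  # usable | failed_mutagenesis | disqualified_unwanted | unresolved


def score_mutations(
    counts: dict[str, AlleleCountTable],
    manifest: PoolManifest,
    s_threshold: float = S_THRESHOLD,
) -> list[SScoreRecord]:
    """One S score per (attempted mutation, pool)."""
    records: list[SScoreRecord] = []
    for rec in manifest:
        pool_id = rec["pool_id"]
        table = counts[pool_id]
        mut = MutationSpec(rec["gene_id"], rec["position"], rec["ref"], rec["alt"])
        row = table.at(mut.gene_id, mut.position)
        r_all = int(row.sum())
        r_mut = int(row["ACGT".index(mut.alt_base)])
        k = manifest.k(mut.gene_id, pool_id)
        if r_all == 0:
            logger.warning(
                "%s@%s: no coverage at target site", mut.mutation_id, pool_id
            )
            records.append(SScoreRecord(mut, pool_id, 0, 0, k, None, False))
            continue
        s = k * r_mut / r_all
        records.append(
            SScoreRecord(mut, pool_id, r_mut, r_all, k, s, s > s_threshold)
        )
    return records


def estimate_background(
    table: AlleleCountTable,
    manifest: PoolManifest,
    pool_id: str,
    min_positions: int = MIN_BACKGROUND_POSITIONS,
) -> BackgroundRate:
    """Mean non-reference allele fraction over covered non-target positions."""
    targets = manifest.target_positions(pool_id)
    fracs: list[np.ndarray] = []
    for gid in table.counts:
        depth = table.depth(gid)
        nonref = table.nonref(gid)
        mask = depth > 0
        tpos = [p - 1 for (g, p) in targets if g == gid]
        if tpos:
            mask[np.array(tpos)] = False
        fracs.append(nonref[mask] / depth[mask])
    all_fracs = np.concatenate(fracs) if fracs else np.array([])
    if len(all_fracs) < min_positions:
        raise ValueError(
            f"{pool_id}: only {len(all_fracs)} covered non-target positions "
            f"(need >= {min_positions}) for background estimation"
        )
    return BackgroundRate(pool_id, float(all_fracs.mean()), len(all_fracs))


def detect_unwanted(
    counts: dict[str, AlleleCountTable],
    manifest: PoolManifest,
    background: dict[str, BackgroundRate] | BackgroundRate | None = None,
    alpha: float = ALPHA,
    min_colony_fraction: float = 0.5,
) -> list[UnwantedFlag]:
    """Binomial screen of non-target positions for unwanted mutations.

    A covered non-target site is flagged when its upper-tail cumulative
    binomial probability under the pool background falls below ``alpha``
    and its non-reference fraction is at least ``min_colony_fraction`` of
    one colony's expected read share (1/k for the gene's k co-pooled
    colonies); the fraction floor keeps lone sequencing errors from being
    mistaken for clonal events (set it to 0 for the bare binomial rule).
    Attribution is to the single colony when the gene has one colony in
    the pool, otherwise "ambiguous".
    """
    if isinstance(background, BackgroundRate):
        background = {background.pool_id: background}
    flags: list[UnwantedFlag] = []
    for pool_id, table in counts.items():
        if background is None or pool_id not in background:
            bg = estimate_background(table, manifest, pool_id)
        else:
            bg = background[pool_id]
        b = max(bg.b_hat, B_HAT_FLOOR)
        targets = manifest.target_positions(pool_id)
        colonies = {
            r["gene_id"]: [] for r in manifest if r["pool_id"] == pool_id
        }
        for r in manifest:
            if r["pool_id"] == pool_id:
                colonies[r["gene_id"]].append(r["colony_id"])
        for gid in table.counts:
            depth = table.depth(gid)
            nonref = table.nonref(gid)
            k = max(len(colonies.get(gid, [])), 1)
            min_frac = min_colony_fraction / k
            cand = (depth > 0) & (nonref >= np.maximum(min_frac * depth, 1))
            tpos = [p - 1 for (g, p) in targets if g == gid]
            if tpos:
                cand[np.array(tpos)] = False
            for idx in np.nonzero(cand)[0]:
                n, x = int(depth[idx]), int(nonref[idx])
                p = float(stats.binom.sf(x - 1, n, b))  # P(X >= x)
                if p < alpha:
                    attributed = (
                        colonies[gid][0]
                        if len(colonies.get(gid, [])) == 1
                        else "ambiguous"
                    )
                    flags.append(
                        UnwantedFlag(gid, pool_id, int(idx) + 1, x, n, p, attributed)
                    )
    return flags


def resolve_clones(
    scores: Sequence[SScoreRecord],
    flags: Sequence[UnwantedFlag],
    manifest: PoolManifest,
) -> list[CloneVerdict]:
    """Pick, per desired mutation, the first pool with a clean called clone."""
    flagged: dict[tuple[str, str], list[UnwantedFlag]] = {}
    for f in flags:
        flagged.setdefault((f.gene_id, f.pool_id), []).append(f)

    by_mut: dict[str, dict[str, SScoreRecord]] = {}
    order: list[MutationSpec] = []
    for rec in scores:
        mid = rec.mutation.mutation_id
        if mid not in by_mut:
            by_mut[mid] = {}
            order.append(rec.mutation)
        by_mut[mid][rec.pool_id] = rec

    pools = manifest.pools
    verdicts: list[CloneVerdict] = []
    for mut in order:
        pool_recs = by_mut[mut.mutation_id]
        chosen = None
        any_called = False
        any_unscored = False
        for pool_id in pools:
            rec = pool_recs.get(pool_id)
            if rec is None:
                continue
            if rec.s is None:
                any_unscored = True
                continue
            if not rec.called:
                continue
            any_called = True
            colony_id = f"{mut.mutation_id}@{pool_id}"
            gene_flags = flagged.get((mut.gene_id, pool_id), [])
            disqualified = any(
                f.attributed_colony in ("ambiguous", colony_id)
                for f in gene_flags
            )
            if not disqualified:
                chosen = pool_id
                break
        if chosen is not None:
            status = "usable"
        elif any_called:
            status = "disqualified_unwanted"
        elif any_unscored:
            status = "unresolved"
        else:
            status = "failed_mutagenesis"
        verdicts.append(CloneVerdict(mut, chosen, status))
    return verdicts


def call_pools(
    counts: dict[str, AlleleCountTable],
    manifest: PoolManifest,
    alpha: float = ALPHA,
    s_threshold: float = S_THRESHOLD,
    min_colony_fraction: float = 0.5,
) -> tuple[list[SScoreRecord], list[UnwantedFlag], list[CloneVerdict]]:
    """Full calling pipeline over all pools."""
    scores = score_mutations(counts, manifest, s_threshold)
    flags = detect_unwanted(
        counts, manifest, alpha=alpha, min_colony_fraction=min_colony_fraction
    )
    verdicts = resolve_clones(scores, flags, manifest)
    return scores, flags, verdicts


def scores_to_frame(scores: Sequence[SScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_id": r.mutation.mutation_id,
                "gene_id": r.mutation.gene_id,
                "position": r.mutation.position,
                "alt": r.mutation.alt_base,
                "pool_id": r.pool_id,
                "R_mut": r.r_mut,
                "R_all": r.r_all,
                "k": r.k,
                "S": r.s,
                "called": r.called,
            }
            for r in scores
        ]
    )


def flags_to_frame(flags: Sequence[UnwantedFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": f.gene_id,
                "pool_id": f.pool_id,
                "position": f.position,
                "nonref_count": f.nonref_count,
                "depth": f.depth,
                "p_value": f.p_value,
                "attributed_colony": f.attributed_colony,
            }
            for f in flags
        ],
        columns=[
            "gene_id",
            "pool_id",
            "position",
            "nonref_count",
            "depth",
            "p_value",
            "attributed_colony",
        ],
    )


def verdicts_to_frame(verdicts: Sequence[CloneVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_id": v.mutation.mutation_id,
                "chosen_pool": v.chosen_pool or "",
                "status": v.status,
            }
            for v in verdicts
        ]
    )


def write_call_outputs(
    out_dir: str | Path,
    scores: Sequence[SScoreRecord],
    flags: Sequence[UnwantedFlag],
    verdicts: Sequence[CloneVerdict],
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_to_frame(scores).to_csv(out / "scores.tsv", sep="\t", index=False)
    flags_to_frame(flags).to_csv(out / "flags.tsv", sep="\t", index=False)
    verdicts_to_frame(verdicts).to_csv(out / "verdicts.tsv", sep="\t", index=False)
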