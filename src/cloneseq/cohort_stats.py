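"""Cohort-level summaries: disruption fractions by structural locus class
and same-disease concordance of same-gene mutation pairs."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "MutationPhenotype",
    "disruption_fraction_by_class",
    "compare_fractions",
    "pair_concordance",
]

logger = logging.getLogger(__name__)

LOCUS_CLASSES = ("interface_residue", "interface_domain", "away")


@dataclass(frozen=True)
class MutationPhenotype:
    mutation: str
    gene: str
    locus_class: str
    disrupted: bool | None = None  # disrupts the considered interaction
    stable: bool | None = None  # None = inconclusive
    profile: tuple[tuple[str, bool], ...] = ()  # (partner, disrupted) pairs
    diseases: frozenset[str] = field(default_factory=frozenset)

    def normalized_diseases(self) -> frozenset[str]:
        return frozenset(d.casefold().strip() for d in self.diseases)


def disruption_fraction_by_class(
    phenotypes: Sequence[MutationPhenotype],
    stable_only: bool = False,
) -> dict[str, dict[str, float]]:
    """Per locus class: fraction of mutations disrupting the considered
    interaction, with binomial SE = sqrt(p(1-p)/n)."""
    out: dict[str, dict[str, float]] = {}
    for cls in LOCUS_CLASSES:
        members = [
            p
            for p in phenotypes
            if p.locus_class == cls
            and p.disrupted is not None
            and (not stable_only or p.stable is True)
        ]
        n = len(members)
        if n == 0:
            logger.warning("class %r empty; omitted", cls)
            continue
        d = sum(1 for p in members if p.disrupted)
        frac = d / n
        out[cls] = {
            "fraction": frac,
            "se": math.sqrt(frac * (1 - frac) / n),
            "n": n,
            "n_disrupted": d,
        }
    return out


def compare_fractions(
    a_hits: int, a_n: int, b_hits: int, b_n: int
) -> float:
    """Two-sided Fisher's exact test on the 2x2 disrupted/total table."""
    if a_n == 0 or b_n == 0:
        raise ValueError("both classes must be non-empty")
    table = [[a_hits, a_n - a_hits], [b_hits, b_n - b_hits]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _same_disease(a: MutationPhenotype, b: MutationPhenotype) -> bool:
    return bool(a.normalized_diseases() & b.normalized_diseases())


def pair_concordance(
    phenotypes: Sequence[MutationPhenotype],
    mode: str = "stability",
) -> dict:
    """Same-disease fractions of concordant vs discordant same-gene pairs.

    mode='stability': pairs are bucketed both_stable / both_unstable /
    discordant. mode='profile': pairs sharing the identical tested-partner
    set are bucketed same_profile / different_profile (others skipped).
    The Fisher p compares same-disease counts between concordant and
    discordant pairs; pairs sharing a mutation are not independent, which
    this test ignores.
    """
    if mode not in ("stability", "profile"):
        raise ValueError(f"unknown mode {mode!r}")
    buckets: dict[str, list[bool]] = {}

    by_gene: dict[str, list[MutationPhenotype]] = {}
    for p in phenotypes:
        if p.diseases:
            by_gene.setdefault(p.gene, []).append(p)

    for gene, members in by_gene.items():
        for a, b in combinations(members, 2):
            same = _same_disease(a, b)
            if mode == "stability":
                if a.stable is None or b.stable is None:
                    continue
                if a.stable and b.stable:
                    bucket = "both_stable"
                elif not a.stable and not b.stable:
                    bucket = "both_unstable"
                else:
                    bucket = "discordant"
            else:
                pa, pb = dict(a.profile), dict(b.profile)
                if not pa or set(pa) != set(pb):
                    continue  # incomparable partner sets
                bucket = (
                    "same_profile" if pa == pb else "different_profile"
                )
            buckets.setdefault(bucket, []).append(same)

    result: dict = {"mode": mode, "buckets": {}}
    for bucket, flags in buckets.items():
        n = len(flags)
        hits = sum(flags)
        result["buckets"][bucket] = {
            "n_pairs": n,
            "n_same_disease": hits,
            "fraction_same_disease": hits / n if n else float("nan"),
        }

    if mode == "stability":
        conc = buckets.get("both_stable", []) + buckets.get("both_unstable", [])
        disc = buckets.get("discordant", [])
    else:
        conc = buckets.get("same_profile", [])
        disc = buckets.get("different_profile", [])
    if conc and disc:
        result["p_value"] = compare_fractions(
            sum(conc), len(conc), sum(disc), len(disc)
        )
    else:
        result["p_value"] = None
    return result


def phenotypes_from_frame(df: pd.DataFrame) -> list[MutationPhenotype]:
    """Rows: mutation, gene, locus_class, disrupted, stable, profile,
    diseases. 'profile' is 'partner1:0;partner2:1' and 'diseases' is
    semicolon-separated; empty cells mean unknown."""

    def parse_profile(cell) -> tuple[tuple[str, bool], ...]:
        if not isinstance(cell, str) or not cell:
            return ()
        items = []
        for part in cell.split(";"):
            partner, flag = part.rsplit(":", 1)
            items.append((partner, flag == "1"))
        return tuple(items)

    def parse_bool(cell) -> bool | None:
        if pd.isna(cell) or cell == "" or cell == "-":
            return None
        if isinstance(cell, bool):
            return cell
        return str(cell).strip() in ("1", "True", "true")

    out = []
    for r in df.itertuples(index=False):
        diseases = (
            frozenset(x for x in str(r.diseases).split(";") if x)
            if isinstance(getattr(r, "diseases", None), str)
            else frozenset()
        )
        out.append(
            MutationPhenotype(
                mutation=str(r.mutation),
                gene=str(r.gene),
                locus_class=str(r.locus_class),
                disrupted=parse_bool(getattr(r, "disrupted", None)),
                stable=parse_bool(getattr(r, "stable", None)),
                profile=parse_profile(getattr(r, "profile", "")),
                diseases=diseases,
            )
        )
    return out
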