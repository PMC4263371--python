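"""Yeast two-hybrid growth scoring: positives, disruption calls, profiles.

Growth on each selective plate is encoded as integer 2-fold serial
dilution steps (0-4). A pair is positive when either reporter grows and
neither cycloheximide control does (growth on a CHX plate marks a
spontaneous auto-activator). A mutation disrupts an interaction when
growth drops by at least one dilution step (>= 50%) on BOTH reporters,
in the majority of replicates, relative to the wild-type allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Y2HReadout",
    "DisruptionCall",
    "call_positive",
    "is_autoactivator",
    "call_disruption",
    "build_profiles",
]


@dataclass(frozen=True)
class Y2HReadout:
    """Growth scores for one DB x AD pairing in one replicate.

    Plate order: His3 reporter (SC-Leu-Trp-His+3AT), His3 CHX control
    (SC-Leu-His+3AT+CHX), Ade2 reporter (SC-Leu-Trp-Ade), Ade2 CHX
    control (SC-Leu-Ade+CHX).
    """

    db_allele: str
    ad_allele: str
    replicate: int
    his3: int
    his3_chx: int
    ade2: int
    ade2_chx: int

    def __post_init__(self) -> None:
        for name in ("his3", "his3_chx", "ade2", "ade2_chx"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class DisruptionCall:
    mutation: str  # mutant DB allele id
    partner: str  # AD partner id
    disrupted: bool
    single_reporter: bool = False  # wild type grew on only one reporter


def call_positive(readout: Y2HReadout) -> bool:
    """Growth on either reporter and on neither CHX control."""
    return (
        (readout.his3 > 0 or readout.ade2 > 0)
        and readout.his3_chx == 0
        and readout.ade2_chx == 0
    )


def is_autoactivator(readout: Y2HReadout) -> bool:
    return readout.his3_chx > 0 or readout.ade2_chx > 0


def call_disruption(
    wt: Sequence[Y2HReadout], mut: Sequence[Y2HReadout]
) -> DisruptionCall | None:
    """Disruption call for one (mutation, partner) against wild type.

    Returns None when the wild-type pair is not positive in a majority
    of replicates (the interaction is not detectable, so disruption is
    undefined and the pair is excluded).
    """
    if not wt or not mut:
        raise ValueError("need wild-type and mutant replicates")
    n_pos = sum(call_positive(r) for r in wt)
    if n_pos * 2 <= len(wt):
        return None
    single_reporter = not (
        any(r.his3 > 0 for r in wt) and any(r.ade2 > 0 for r in wt)
    )
    votes = 0
    n = min(len(wt), len(mut))
    for w, m in zip(wt[:n], mut[:n]):
        his_drop = m.his3 <= w.his3 - 1
        ade_drop = m.ade2 <= w.ade2 - 1
        if his_drop and ade_drop:
            votes += 1
    disrupted = votes * 2 > n
    return DisruptionCall(
        mutation=mut[0].db_allele,
        partner=mut[0].ad_allele,
        disrupted=disrupted,
        single_reporter=single_reporter,
    )


def build_profiles(
    calls: Sequence[DisruptionCall],
) -> dict[str, dict[str, bool]]:
    """Per-mutation disruption profile over its tested partners.

    Profiles are ordered by partner id so that two mutations tested
    against the identical partner set yield directly comparable vectors;
    mutations with differing tested-partner sets are not comparable.
    """
    profiles: dict[str, dict[str, bool]] = {}
    for c in calls:
        profiles.setdefault(c.mutation, {})[c.partner] = c.disrupted
    return {
        m: dict(sorted(partners.items())) for m, partners in profiles.items()
    }


def profiles_comparable(
    profiles: Mapping[str, Mapping[str, bool]], a: str, b: str
) -> bool:
    return set(profiles[a]) == set(profiles[b])


def readouts_from_frame(df: pd.DataFrame) -> list[Y2HReadout]:
    """Rows: db_allele, ad_allele, replicate, his3, his3_chx, ade2, ade2_chx."""
    return [
        Y2HReadout(
            str(r.db_allele),
            str(r.ad_allele),
            int(r.replicate),
            int(r.his3),
            int(r.his3_chx),
            int(r.ade2),
            int(r.ade2_chx),
        )
        for r in df.itertuples(index=False)
    ]


def score_table(df: pd.DataFrame, wildtype_map: Mapping[str, str]) -> pd.DataFrame:
    """Disruption calls for every (mutant DB, partner) in a readout table.

    ``wildtype_map`` maps mutant DB allele ids to their wild-type allele id.
    """
    readouts = readouts_from_frame(df)
    grouped: dict[tuple[str, str], list[Y2HReadout]] = {}
    for r in readouts:
        grouped.setdefault((r.db_allele, r.ad_allele), []).append(r)
    rows = []
    for (db, ad), mut_reps in grouped.items():
        if db not in wildtype_map:
            continue
        wt_reps = grouped.get((wildtype_map[db], ad))
        if wt_reps is None:
            continue
        call = call_disruption(wt_reps, mut_reps)
        rows.append(
            {
                "mutation": db,
                "partner": ad,
                "wt_positive": call is not None,
                "disrupted": call.disrupted if call else None,
                "single_reporter": call.single_reporter if call else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mutation", "partner", "wt_positive", "disrupted", "single_reporter"],
    )
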