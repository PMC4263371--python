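"""Protein-stability calls from plate fluorescence readouts.

Per plate, the background is the mean intensity of the empty-vector
control wells and K is their range (max - min). An allele's normalized
intensity is I_norm = I - I_background per replicate; the allele is
called stable when its mean I_norm exceeds K.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "EMPTY_VECTOR",
    "StabilityCall",
    "call_stability",
    "compare_to_wildtype",
]

EMPTY_VECTOR = "EMPTY_VECTOR"


@dataclass(frozen=True)
class StabilityCall:
    allele_id: str
    mean_i_norm: float
    k: float
    stable: bool


def _plate_background(plate_df: pd.DataFrame) -> tuple[float, float]:
    controls = plate_df.loc[plate_df["allele_id"] == EMPTY_VECTOR, "intensity"]
    if len(controls) < 2:
        raise ValueError(
            f"plate {plate_df['plate_id'].iloc[0]!r}: needs >= 2 empty-vector wells"
        )
    return float(controls.mean()), float(controls.max() - controls.min())


def call_stability(readouts: pd.DataFrame) -> list[StabilityCall]:
    """Stability calls from a long-format readout table.

    ``readouts`` columns: plate_id, allele_id, intensity, and optionally
    well/replicate. An allele spread across plates is normalized per plate
    and its replicate I_norm values combined; the threshold is then the
    largest K among the contributing plates (conservative).
    """
    if (readouts["intensity"] < 0).any():
        raise ValueError("negative fluorescence intensity")
    norms: dict[str, list[float]] = {}
    ks: dict[str, list[float]] = {}
    for _, plate_df in readouts.groupby("plate_id", sort=False):
        i_background, k = _plate_background(plate_df)
        for allele, adf in plate_df.groupby("allele_id", sort=False):
            if allele == EMPTY_VECTOR:
                continue
            norms.setdefault(allele, []).extend(
                (adf["intensity"] - i_background).tolist()
            )
            ks.setdefault(allele, []).append(k)
    calls = []
    for allele, values in norms.items():
        mean_norm = sum(values) / len(values)
        k = max(ks[allele])
        calls.append(StabilityCall(allele, mean_norm, k, mean_norm > k))
    return calls


def compare_to_wildtype(
    calls: Sequence[StabilityCall], allele_map: Mapping[str, str]
) -> list[tuple[str, bool | None]]:
    """Per mutant: diminished (True), not diminished (False), or
    inconclusive (None) when the wild-type signal itself is not stable."""
    by_id = {c.allele_id: c for c in calls}
    out: list[tuple[str, bool | None]] = []
    for mutant, wildtype in allele_map.items():
        if wildtype not in by_id:
            raise ValueError(f"missing wild-type call for {mutant!r}")
        if mutant not in by_id:
            raise ValueError(f"missing mutant call for {mutant!r}")
        wt, mut = by_id[wildtype], by_id[mutant]
        if not wt.stable:
            out.append((mutant, None))
        else:
            out.append((mutant, not mut.stable))
    return out


def calls_to_frame(
    calls: Sequence[StabilityCall],
    diminished: Sequence[tuple[str, bool | None]] | None = None,
) -> pd.DataFrame:
    dim = dict(diminished or [])
    return pd.DataFrame(
        [
            {
                "allele_id": c.allele_id,
                "mean_I_norm": c.mean_i_norm,
                "K": c.k,
                "stable": c.stable,
                "diminished_vs_wt": {True: "1", False: "0", None: "-"}.get(
                    dim.get(c.allele_id, False), "0"
                )
                if c.allele_id in dim
                else "",
            }
            for c in calls
        ]
    )


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate_id", "allele_id", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return df
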