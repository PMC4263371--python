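"""Differential-interactor scoring from SILAC pull-down ratio tables.

Four experiments: WT_Control and Mutant_Control (bait vs control pull-down,
heavy bait), plus the reciprocal WT_Mutant (wild type heavy) and Mutant_WT
(mutant heavy) swaps. Per-peptide light/heavy ratios are combined by
geometric mean; the swap experiments are normalized by the bait's own
ratio so global mixing errors cancel. The combined statistic

    E = (r_wm * log2 FC_wm + r_mw * log2 FC_mw) / (r_wm + r_mw)

weights each swap's log2 fold change by its peptide evidence; negative E
marks weakened interactors and positive E enhanced ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EXPERIMENTS",
    "InteractorScore",
    "aggregate",
    "classify",
    "ks_bootstrap_p",
    "score_experiment",
]

EXPERIMENTS = ("WT_Control", "Mutant_Control", "WT_Mutant", "Mutant_WT")

RATIO_BOUND = 2.0  # WT_p / Mut_p interactor evidence threshold
FC_LOST = 0.5
FC_GAINED = 2.0
MIN_READS = 5


@dataclass
class InteractorScore:
    protein_id: str
    wt_p: float = np.nan
    mut_p: float = np.nan
    fc_wm: float = np.nan
    fc_mw: float = np.nan
    e: float = np.nan
    r_wc: int = 0
    r_mc: int = 0
    r_wm: int = 0
    r_mw: int = 0
    classification: str = "unclassified"
    p_value: float | None = None


def _gm(values: np.ndarray) -> float:
    if (values <= 0).any():
        raise ValueError("ratios must be positive")
    return float(np.exp(np.mean(np.log(values))))


def _ratios(df: pd.DataFrame, experiment: str, protein: str | None) -> np.ndarray:
    sel = df["experiment"] == experiment
    if protein is None:
        sel &= df["is_bait"]
    else:
        sel &= (df["protein_id"] == protein) & ~df["is_bait"]
    return df.loc[sel, "xpress_ratio"].to_numpy(dtype=float)


def aggregate(records: pd.DataFrame) -> dict[str, InteractorScore]:
    """Per-protein scores from a ratio table.

    ``records`` columns: experiment, protein_id, peptide_id, xpress_ratio
    (light/heavy), is_bait. Bait rows must be present in both swap
    experiments (WT_Mutant, Mutant_WT) for normalization.
    """
    for col in ("experiment", "protein_id", "xpress_ratio", "is_bait"):
        if col not in records.columns:
            raise ValueError(f"ratio table missing column {col!r}")
    bad = set(records["experiment"]) - set(EXPERIMENTS)
    if bad:
        raise ValueError(f"unknown experiment labels: {sorted(bad)}")

    bait_wm = _ratios(records, "WT_Mutant", None)
    bait_mw = _ratios(records, "Mutant_WT", None)
    if len(bait_wm) == 0 or len(bait_mw) == 0:
        raise ValueError("bait normalization records required in both swaps")
    gm_bait_wm = _gm(bait_wm)  # C_j: mutant/wild-type bait amount
    gm_bait_mw = _gm(bait_mw)  # D_i

    proteins = sorted(
        set(records.loc[~records["is_bait"], "protein_id"])
    )
    scores: dict[str, InteractorScore] = {}
    for prot in proteins:
        sc = InteractorScore(prot)
        x = _ratios(records, "WT_Control", prot)
        y = _ratios(records, "Mutant_Control", prot)
        p_ = _ratios(records, "WT_Mutant", prot)
        q = _ratios(records, "Mutant_WT", prot)
        sc.r_wc, sc.r_mc, sc.r_wm, sc.r_mw = map(len, (x, y, p_, q))
        if len(x):
            sc.wt_p = 1.0 / _gm(x)
        if len(y):
            sc.mut_p = 1.0 / _gm(y)
        if len(p_):
            sc.fc_wm = _gm(p_) / gm_bait_wm
        if len(q):
            sc.fc_mw = (1.0 / _gm(q)) / (1.0 / gm_bait_mw)
        if len(p_) and len(q):
            sc.e = (
                sc.r_wm * np.log2(sc.fc_wm) + sc.r_mw * np.log2(sc.fc_mw)
            ) / (sc.r_wm + sc.r_mw)
        scores[prot] = sc
    return scores


def classify(score: InteractorScore) -> str:
    """lost / gained / unchanged / unclassified per the threshold rules."""
    s = score
    swaps_ok = s.r_wm >= MIN_READS and s.r_mw >= MIN_READS
    wt_interactor = s.wt_p > RATIO_BOUND and s.r_wc >= MIN_READS
    mut_interactor = s.mut_p > RATIO_BOUND and s.r_mc >= MIN_READS
    if wt_interactor and swaps_ok and s.fc_wm < FC_LOST and s.fc_mw < FC_LOST:
        return "lost"
    if mut_interactor and swaps_ok and s.fc_wm > FC_GAINED and s.fc_mw > FC_GAINED:
        return "gained"
    if (
        wt_interactor
        and mut_interactor
        and swaps_ok
        and FC_LOST < s.fc_wm < FC_GAINED
        and FC_LOST < s.fc_mw < FC_GAINED
    ):
        return "unchanged"
    return "unclassified"


def peptide_log_ratios(records: pd.DataFrame, protein: str) -> np.ndarray:
    """Pooled bait-normalized per-peptide log2 fold changes of one protein
    across the two swap experiments (both oriented mutant/wild-type)."""
    gm_bait_wm = _gm(_ratios(records, "WT_Mutant", None))
    gm_bait_mw = _gm(_ratios(records, "Mutant_WT", None))
    p_ = _ratios(records, "WT_Mutant", protein)
    q = _ratios(records, "Mutant_WT", protein)
    out = []
    if len(p_):
        out.append(np.log2(p_ / gm_bait_wm))
    if len(q):
        out.append(np.log2(gm_bait_mw / q))
    return np.concatenate(out) if out else np.array([])


def ks_bootstrap_p(
    values: np.ndarray,
    background: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float | None:
    """Two-sided KS test of a protein's peptide log ratios against the
    background, with a bootstrap null: resampled background sets of the
    same size scored by their KS distance to the full background.

    Returns None (undefined) for fewer than 3 peptide values.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    values = np.asarray(values, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(background) == 0:
        raise ValueError("empty background")
    if len(values) < 3:
        return None
    observed = stats.ks_2samp(values, background).statistic
    rng = np.random.default_rng(seed)
    n = len(values)
    bg_sorted = np.sort(background)
    m = len(bg_sorted)

    samples = rng.choice(background, size=(n_boot, n), replace=True)
    samples.sort(axis=1)
    # resample values are background values, so the KS sup is attained at
    # background jump points (right-continuous evaluation, as in ks_2samp)
    d = np.empty(n_boot)
    bg_ecdf_at_bg = np.arange(1, m + 1) / m
    for i in range(n_boot):
        ecdf_s_at_bg = np.searchsorted(samples[i], bg_sorted, side="right") / n
        d[i] = np.max(np.abs(ecdf_s_at_bg - bg_ecdf_at_bg))
    return float(np.mean(d >= observed - 1e-12))


def score_experiment(
    records: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """aggregate -> classify -> KS bootstrap p per protein.

    The KS background pools the bait-normalized peptide log ratios of all
    proteins classified unchanged.
    """
    scores = aggregate(records)
    for sc in scores.values():
        sc.classification = classify(sc)
    unchanged = [p for p, sc in scores.items() if sc.classification == "unchanged"]
    background = (
        np.concatenate([peptide_log_ratios(records, p) for p in unchanged])
        if unchanged
        else np.array([])
    )
    for i, (prot, sc) in enumerate(sorted(scores.items())):
        if len(background):
            sc.p_value = ks_bootstrap_p(
                peptide_log_ratios(records, prot),
                background,
                n_boot=n_boot,
                seed=seed + i,
            )
    return scores_to_frame(list(scores.values()))


def scores_to_frame(scores: Sequence[InteractorScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "WT_p": s.wt_p,
                "Mut_p": s.mut_p,
                "FC_wm": s.fc_wm,
                "FC_mw": s.fc_mw,
                "E": s.e,
                "r_wc": s.r_wc,
                "r_mc": s.r_mc,
                "r_wm": s.r_wm,
                "r_mw": s.r_mw,
                "classification": s.classification,
                "p_value": s.p_value,
            }
            for s in scores
        ]
    )
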