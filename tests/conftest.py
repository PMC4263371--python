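from __future__ import annotations

import numpy as np
import pytest

from cloneseq.primer_design import (
    GC_THRESHOLD,
    GC_THRESHOLD_RELAXED,
    TM_THRESHOLD,
)
from cloneseq.types import GeneRef, MutationSpec


def brute_force_primer(
    gene: GeneRef, mutation: MutationSpec, gc_threshold: int = GC_THRESHOLD
):
    """Independent exhaustive primer search used as the design oracle.

    Walks every (start, end) window of length 30-50 containing the mutated
    base at or one position from the window center, applies the printed
    criteria directly, and ranks by (Tm desc, length asc, |offset| asc,
    start asc). Returns (sequence, n, tm, offset, start) or None.
    """
    template = gene.sequence
    L = len(template)
    p = mutation.position
    best = None
    for start in range(1, L + 1):
        for n in range(30, 51):
            end = start + n - 1
            if end > L:
                break
            if not start <= p <= end:
                continue
            j = p - start + 1  # 1-based index of mutation in window
            center = n // 2 if n % 2 == 0 else (n + 1) // 2
            offset = j - center
            if abs(offset) > 1:
                continue
            seq = (
                template[start - 1 : p - 1]
                + mutation.alt_base
                + template[p:end]
            )
            if seq[0] not in "GC" or seq[-1] not in "GC":
                continue
            pct_gc = int(np.floor(100.0 * sum(c in "GC" for c in seq) / n + 0.5))
            if pct_gc < gc_threshold:
                continue
            pct_mm = int(np.floor(100.0 / n + 0.5))
            tm = 81.5 + 0.41 * pct_gc - 675.0 / n - pct_mm
            if tm < TM_THRESHOLD:
                continue
            key = (-tm, n, abs(offset), start)
            if best is None or key < best[0]:
                best = (key, (seq, n, tm, offset, start))
    return None if best is None else best[1]


def brute_force_primer_relaxed(gene: GeneRef, mutation: MutationSpec):
    hit = brute_force_primer(gene, mutation, GC_THRESHOLD)
    if hit is not None:
        return hit, False
    hit = brute_force_primer(gene, mutation, GC_THRESHOLD_RELAXED)
    return hit, True


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


# --- pool-1 / pool-n worked example -------------------------------------


def build_worked_example():
    """Two-pool scenario with five genes reproducing the illustrative
    calling patterns: clean single-mutant genes, a two-mutant gene with
    both clones correct, one failed clone, and a gene disqualified by a
    shared unwanted mutation in pool 1 but clean in pool n.

    Returns (genes, mutations, manifest, counts, expectations).
    """
    from cloneseq.pileup import AlleleCountTable
    from cloneseq.types import PoolManifest

    gen = np.random.default_rng(2024)
    lengths = {"I": 600, "II": 600, "III": 400, "IV": 800, "V": 600}
    seqs = {
        gid: "".join(gen.choice(list("ACGT"), n)) for gid, n in lengths.items()
    }

    def force(gid, pos, base):
        s = seqs[gid]
        seqs[gid] = s[: pos - 1] + base + s[pos:]

    force("I", 116, "T")
    force("II", 298, "G")
    force("III", 41, "A")
    force("III", 194, "C")
    force("IV", 74, "C")
    force("IV", 511, "G")
    force("V", 53, "T")
    force("V", 272, "G")
    force("V", 436, "C")  # site of the unwanted mutation in pool 1

    genes = [GeneRef(gid, seqs[gid]) for gid in lengths]
    muts = [
        MutationSpec("I", 116, "T", "A"),
        MutationSpec("II", 298, "G", "T"),
        MutationSpec("III", 41, "A", "T"),
        MutationSpec("III", 194, "C", "T"),
        MutationSpec("IV", 74, "C", "T"),
        MutationSpec("IV", 511, "G", "A"),
        MutationSpec("V", 53, "T", "G"),
        MutationSpec("V", 272, "G", "A"),
    ]
    manifest = PoolManifest()
    for pool in ("pool1", "pooln"):
        for m in muts:
            manifest.add(m, pool)

    depth = 1000

    def clean_table():
        table = AlleleCountTable.empty(genes)
        for g in genes:
            ref = table.ref_codes[g.gene_id]
            table.counts[g.gene_id][np.arange(len(ref)), ref] = depth
        return table

    def set_split(table, gid, pos, alt, alt_frac=0.5):
        ref = table.ref_codes[gid][pos - 1]
        row = np.zeros(5, dtype=np.int64)
        row[ref] = int(depth * (1 - alt_frac))
        row["ACGT".index(alt)] = int(depth * alt_frac)
        table.counts[gid][pos - 1] = row

    pool1 = clean_table()
    set_split(pool1, "I", 116, "A", 1.0)  # k=1, clone correct
    set_split(pool1, "II", 298, "T", 1.0)
    set_split(pool1, "III", 41, "T", 0.5)  # k=2, both correct
    set_split(pool1, "III", 194, "T", 0.5)
    # IV: G511A succeeded, C74T failed (all reads wild type at 74)
    set_split(pool1, "IV", 511, "A", 0.5)
    # V: both correct but an unwanted C436G at half the reads
    set_split(pool1, "V", 53, "G", 0.5)
    set_split(pool1, "V", 272, "A", 0.5)
    set_split(pool1, "V", 436, "G", 0.5)

    pooln = clean_table()
    set_split(pooln, "I", 116, "A", 1.0)
    set_split(pooln, "II", 298, "T", 1.0)
    set_split(pooln, "III", 41, "T", 0.5)
    set_split(pooln, "III", 194, "T", 0.5)
    set_split(pooln, "IV", 74, "T", 0.5)
    set_split(pooln, "IV", 511, "A", 0.5)
    set_split(pooln, "V", 53, "G", 0.5)
    set_split(pooln, "V", 272, "A", 0.5)

    counts = {"pool1": pool1, "pooln": pooln}
    expectations = {
        "pool1_usable": {
            "I_T116A", "II_G298T", "III_A41T", "III_C194T", "IV_G511A"
        },
        "pool1_failed": {"IV_C74T"},
        "pool1_unwanted_disqualified": {"V_T53G", "V_G272A"},
        "pooln_usable": {
            "I_T116A", "III_A41T", "III_C194T", "IV_C74T",
            "IV_G511A", "V_T53G", "V_G272A",
        },
    }
    return genes, muts, manifest, counts, expectations


# --- session-scoped large experiments shared by acceptance tests ----------


@pytest.fixture(scope="session")
def t1_exp():
    from cloneseq.experiments import t1_experiment

    return t1_experiment(seed=1)


@pytest.fixture(scope="session")
def t2_exp():
    from cloneseq.experiments import t2_experiment

    return t2_experiment(seed=1)


@pytest.fixture(scope="session")
def t3_exp():
    from cloneseq.experiments import t3_experiment

    return t3_experiment(seed=1)
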