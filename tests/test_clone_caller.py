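import math

import numpy as np
import pytest
from scipy import stats

from cloneseq.clone_caller import (
    call_pools,
    detect_unwanted,
    estimate_background,
    resolve_clones,
    score_mutations,
)
from cloneseq.pileup import AlleleCountTable, map_and_count
from cloneseq.synthetic_pools import (
    SimConfig,
    random_genes,
    random_mutations,
    simulate_pools,
)
from cloneseq.types import GeneRef, MutationSpec, PoolManifest

from conftest import build_worked_example


def _single_site_counts(gene_len, pos, ref, alt, r_all, r_mut, gene_id="g"):
    gene = GeneRef(gene_id, ref * (pos - 1) + ref + ref * (gene_len - pos))
    table = AlleleCountTable.empty([gene])
    codes = table.ref_codes[gene_id]
    table.counts[gene_id][np.arange(gene_len), codes] = r_all
    row = np.zeros(5, dtype=np.int64)
    row["ACGT".index(ref)] = r_all - r_mut
    row["ACGT".index(alt)] = r_mut
    table.counts[gene_id][pos - 1] = row
    return gene, table


class TestScoreMutations:
    def _score(self, k, r_mut, r_all):
        gene, table = _single_site_counts(50, 10, "A", "G", r_all, r_mut)
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        for extra in range(k - 1):
            pos = 20 + extra
            manifest.add(MutationSpec("g", pos, "A", "C"), "pool1")
        recs = score_mutations({"pool1": table}, manifest)
        return recs[0]

    def test_half_reads_with_two_colonies_scores_one(self):
        rec = self._score(k=2, r_mut=500, r_all=1000)
        assert rec.s == pytest.approx(1.0)
        assert rec.called

    def test_all_wild_type_scores_zero(self):
        rec = self._score(k=2, r_mut=0, r_all=1000)
        assert rec.s == 0.0
        assert not rec.called

    def test_pure_mutant_single_colony(self):
        rec = self._score(k=1, r_mut=800, r_all=800)
        assert rec.s == pytest.approx(1.0)
        assert rec.called

    def test_zero_coverage_yields_undefined_score(self):
        gene, table = _single_site_counts(50, 10, "A", "G", 100, 50)
        table.counts["g"][9] = 0
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        rec = score_mutations({"pool1": table}, manifest)[0]
        assert rec.s is None and not rec.called

    def test_decrementing_k_rescales_s_exactly(self):
        # S = k * R_mut / R_all: halving k halves S
        rec2 = self._score(k=2, r_mut=300, r_all=1000)
        rec1 = self._score(k=1, r_mut=300, r_all=1000)
        assert rec2.s == pytest.approx(2 * rec1.s)


class TestBackground:
    def test_noise_free_background_is_zero(self):
        gene, table = _single_site_counts(200, 10, "A", "G", 100, 100)
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        bg = estimate_background(table, manifest, "pool1")
        assert bg.b_hat == 0.0
        assert bg.n_positions == 199  # target site excluded

    def test_planted_rate_recovered(self, rng):
        genes = random_genes(4, rng, 800, 1200)
        muts = random_mutations(genes, 4, rng)
        cfg = SimConfig(
            p_success=1.0, pcr_error_rate=0.0, seq_error_rate=1e-3,
            coverage=400.0, seed=21,
        )
        manifest, readsets, _ = simulate_pools(genes, muts, 1, cfg)
        table = map_and_count(readsets["pool1"], genes)
        bg = estimate_background(table, manifest, "pool1")
        # mean nonref fraction across positions ~ seq error rate
        n_bases = sum(len(g) for g in genes) * 400
        se = math.sqrt(1e-3 / n_bases) * math.sqrt(bg.n_positions)
        assert abs(bg.b_hat - 1e-3) < 3e-4

    def test_single_planted_error_contribution(self):
        # only non-target signal: one fully non-reference site
        gene, table = _single_site_counts(300, 10, "A", "G", 100, 100)
        table.counts["g"][49] = np.array([0, 100, 0, 0, 0])  # pos 50 all C
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        bg = estimate_background(table, manifest, "pool1")
        assert bg.b_hat == pytest.approx(1.0 / 299)

    def test_insufficient_positions_error(self):
        gene, table = _single_site_counts(50, 10, "A", "G", 100, 100)
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        with pytest.raises(ValueError, match="non-target positions"):
            estimate_background(table, manifest, "pool1")


class TestDetectUnwanted:
    def _pool(self, nonref_at_50, depth=2500, gene_len=300, k=1):
        gene, table = _single_site_counts(gene_len, 10, "A", "G", depth, depth)
        row = np.zeros(5, dtype=np.int64)
        row[0] = depth - nonref_at_50
        row[1] = nonref_at_50
        table.counts["g"][49] = row
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        for extra in range(k - 1):
            manifest.add(MutationSpec("g", 20 + extra, "A", "C"), "pool1")
        return table, manifest

    def test_marginal_count_not_flagged(self):
        from cloneseq.clone_caller import BackgroundRate

        table, manifest = self._pool(nonref_at_50=3)
        bg = BackgroundRate("pool1", 1e-3, 299)
        flags = detect_unwanted(
            {"pool1": table}, manifest, bg, alpha=0.2, min_colony_fraction=0.0
        )
        # oracle: exact binomial upper tail
        p = 1 - stats.binom.cdf(2, 2500, 1e-3)
        assert p == pytest.approx(0.456, abs=0.01)
        assert all(f.position != 50 for f in flags)

    def test_half_fraction_flagged_ambiguous_with_two_colonies(self):
        from cloneseq.clone_caller import BackgroundRate

        table, manifest = self._pool(nonref_at_50=1250, k=2)
        bg = BackgroundRate("pool1", 1e-3, 299)
        flags = detect_unwanted({"pool1": table}, manifest, bg)
        hit = [f for f in flags if f.position == 50]
        assert len(hit) == 1
        assert hit[0].attributed_colony == "ambiguous"
        assert hit[0].p_value < 0.2

    def test_single_colony_attribution(self):
        from cloneseq.clone_caller import BackgroundRate

        table, manifest = self._pool(nonref_at_50=2400, k=1)
        bg = BackgroundRate("pool1", 1e-3, 299)
        flags = detect_unwanted({"pool1": table}, manifest, bg)
        hit = [f for f in flags if f.position == 50]
        assert hit[0].attributed_colony == "g_A10G@pool1"

    def test_zero_background_single_read_flagged(self):
        from cloneseq.clone_caller import BackgroundRate

        gene, table = _single_site_counts(300, 10, "A", "G", 2, 2)
        table.counts["g"][49] = np.array([1, 1, 0, 0, 0])
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        bg = BackgroundRate("pool1", 0.0, 299)
        flags = detect_unwanted({"pool1": table}, manifest, bg)
        assert any(f.position == 50 for f in flags)

    @pytest.mark.parametrize("depth", [300, 1000])
    @pytest.mark.parametrize("frac", [0.25, 0.5])
    def test_power_at_quarter_fraction(self, depth, frac):
        from cloneseq.clone_caller import BackgroundRate

        table, manifest = self._pool(
            nonref_at_50=int(depth * frac), depth=depth, k=2
        )
        bg = BackgroundRate("pool1", 2e-3, 299)
        flags = detect_unwanted({"pool1": table}, manifest, bg)
        assert any(f.position == 50 for f in flags)


class TestResolveClones:
    def test_worked_example_pool1_and_pooln(self):
        genes, muts, manifest, counts, expect = build_worked_example()
        scores, flags, verdicts = call_pools(counts, manifest)
        s = {(r.mutation.mutation_id, r.pool_id): r for r in scores}
        # pool-1 patterns
        for mid in expect["pool1_usable"]:
            assert s[(mid, "pool1")].called
        for mid in expect["pool1_failed"]:
            assert not s[(mid, "pool1")].called
            assert s[(mid, "pool1")].s == 0.0
        for mid in expect["pool1_unwanted_disqualified"]:
            assert s[(mid, "pool1")].called  # mutagenesis itself succeeded
        flagged = [(f.gene_id, f.pool_id, f.position) for f in flags]
        assert flagged == [("V", "pool1", 436)]
        assert flags[0].attributed_colony == "ambiguous"
        # pool-n: all seven listed clones usable
        for mid in expect["pooln_usable"]:
            assert s[(mid, "pooln")].called
        # overall verdicts
        v = {x.mutation.mutation_id: x for x in verdicts}
        for mid in expect["pool1_usable"]:
            assert v[mid].status == "usable" and v[mid].chosen_pool == "pool1"
        assert v["IV_C74T"].status == "usable"
        assert v["IV_C74T"].chosen_pool == "pooln"
        for mid in expect["pool1_unwanted_disqualified"]:
            assert v[mid].status == "usable"
            assert v[mid].chosen_pool == "pooln"  # pool 1 disqualified

    def test_never_called_is_failed(self):
        gene, table = _single_site_counts(200, 10, "A", "G", 100, 0)
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        scores = score_mutations({"pool1": table}, manifest)
        verdicts = resolve_clones(scores, [], manifest)
        assert verdicts[0].status == "failed_mutagenesis"
        assert verdicts[0].chosen_pool is None

    def test_unscored_is_unresolved(self):
        gene, table = _single_site_counts(200, 10, "A", "G", 100, 0)
        table.counts["g"][9] = 0
        manifest = PoolManifest()
        manifest.add(MutationSpec("g", 10, "A", "G"), "pool1")
        scores = score_mutations({"pool1": table}, manifest)
        verdicts = resolve_clones(scores, [], manifest)
        assert verdicts[0].status == "unresolved"


class TestEndToEndAgreement:
    def test_called_equals_planted_success_at_high_coverage(self, rng):
        genes = random_genes(8, rng, 500, 900)
        muts = random_mutations(genes, 10, rng)
        cfg = SimConfig(
            p_success=0.7, pcr_error_rate=0.0, seq_error_rate=1e-3,
            coverage=800.0, seed=31,
        )
        manifest, readsets, truth = simulate_pools(genes, muts, 2, cfg)
        counts = {p: map_and_count(rs, genes) for p, rs in readsets.items()}
        scores = score_mutations(counts, manifest)
        planted = {
            (c.mutation.mutation_id, c.pool_id): c.success
            for c in truth.colonies
        }
        for r in scores:
            assert r.called == planted[(r.mutation.mutation_id, r.pool_id)]
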