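# cloneseq

Toolkit for verifying pooled site-directed mutagenesis by sequencing, and
for the downstream comparative interactome-scanning analyses that consume
the verified clones.

One colony is picked per desired mutation per pool; pooled 1x100 bp reads
are mapped back to the reference ORFs and every attempted mutation gets a
normalized score `S = k * R_mut / R_all` (k = co-pooled mutations on the
same gene). Colonies with `S > 0.8` carry their mutation; non-target
positions are screened for unwanted PCR-introduced substitutions against
the pool's sequencing-error background (cumulative binomial, P < 0.2),
and clean clones are chosen per mutation across pools. Companion modules
cover mutagenesis primer design, GFP stability calls, Y2H disruption
scoring, SASA-based interface classification, SILAC differential
interactor scoring, and cohort statistics.

## Modules

| module | purpose |
| --- | --- |
| `cloneseq.synthetic_pools` | simulate pooled mutagenesis experiments with known ground truth |
| `cloneseq.primer_design` | QuikChange-style primer pairs (30-50 bp, GC >= 40%, Tm >= 78 C) |
| `cloneseq.pileup` | built-in ungapped mapper + samtools-mpileup-dialect reader |
| `cloneseq.clone_caller` | S scores, unwanted-mutation flags, clone verdicts |
| `cloneseq.gfp_stability` | plate fluorescence -> stability calls (I_norm vs K range) |
| `cloneseq.y2h_disruption` | reporter/CHX growth scoring, 50%-reduction disruption rule |
| `cloneseq.interface3d` | Shrake-Rupley SASA, interface residues/domains, locus classes |
| `cloneseq.silac_scoring` | geometric-mean ratio aggregation, lost/gained/unchanged calls |
| `cloneseq.cohort_stats` | disruption fractions by locus class, disease pair concordance |

## CLI

```bash
cloneseq sim --genes ref.fasta --mutations muts.tsv --pools 4 \
    --p-success 0.8 --pcr-error 1.3e-4 --seq-error 1e-3 \
    --coverage 2500 --seed 42 --out simdir/
cloneseq map --genes ref.fasta --reads simdir/pool1.fastq \
    --reads simdir/pool2.fastq --out counts.tsv
cloneseq call --counts counts.tsv --manifest simdir/manifest.tsv \
    --alpha 0.2 --s-threshold 0.8 --out calls/
cloneseq primers --genes ref.fasta --mutations muts.tsv --out primers.tsv
cloneseq gfp --plates plates.csv --out gfp.tsv
cloneseq y2h --scores y2h.csv --wildtype-map wtmap.tsv --out y2h_calls.tsv
cloneseq silac --ratios ratios.tsv --nboot 10000 --seed 7 --out silac.tsv
cloneseq stats --phenotypes merged.tsv --out stats.json
```

`muts.tsv` columns: `gene_id  position  ref  alt` (1-based). See module
docstrings for the other table layouts.

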