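# repchip

Replicate-aware ChIP-seq analysis toolkit: three tiers of quality control,
majority-rule consensus peaks across biological replicates, RPKM
quantification with a detection-above-background (DABG) rescue test, and
pairwise concordance statistics — plus a seeded simulator that generates
multi-replicate experiments with known truth, so the whole pipeline is
testable without any external data.

## What it does

Given per-replicate peak calls (BED6 / ENCODE narrowPeak) and aligned-read
positions (BED6), the toolkit:

1. **QC1/QC2 metrics** (`repchip.qc_metrics`) — PCR bottleneck coefficient
   (PBC, flagged at 0.7), fraction of reads in peaks (FRIP), and strand
   cross-correlation NSC/RSC with phantom-peak guarding.
2. **Cross-replicate overlap** (`repchip.replicate_overlap`) — peaks
   sharing at least one nucleotide are clustered into single-linkage
   groups; groups are classified *unique* / *partial* / *majority*
   (strictly more than 50% of replicates) / *common-all*; pairwise
   identification agreement via the simple agreement coefficient and
   McNemar's test.
3. **Consensus regions + quantification** (`repchip.consensus_quant`) —
   four consensus definitions (MAX span, SMT between summits, ASF
   footprint and ASW average-width around the average summit, plus a REF
   deepest-replicate baseline); RPKM per region per replicate; and the
   DABG rescue test: for every replicate missing from a group, a one-sided
   Z-test of the region's RPKM against that replicate's own low-quartile
   called-peak background.
4. **QC3 concordance** (`repchip.concordance`) — weighted kappa on
   quintile-binned coverage (flagged "excellent" above 0.75), Spearman
   correlation, and Bland-Altman bias / limits of agreement.
5. **Annotation-based units** (`repchip.genomic_features`) — promoters
   (TSS ± 2 kb) and genic spans (gene ± 2 kb) as peak-caller-independent
   quantification units.
6. **Simulation** (`repchip.synthetic_data`) — true sites with lognormal
   strengths, per-replicate detection dropout, boundary jitter,
   replicate-private noise peaks, and paired pseudo-fragment reads over a
   smooth background landscape; closed-form binomial recovery expectations
   via `expected_recovery`.

All coordinates are 0-based half-open internally; GFF and narrowPeak
conventions are converted on ingest. Peak calling and alignment themselves
are out of scope — the toolkit consumes their outputs.

## Command line

Every stage is a subcommand of `repchip`; `repchip run` chains them.

```bash
# generate a 5-replicate synthetic experiment with known truth
repchip simulate --outdir exp --n-sites 200 --n-replicates 5 \
    --p-detect 0.8 --reads-per-replicate 200000 --seed 1

# QC1/QC2 metrics for one replicate
repchip qc1 --reads exp/rep1.reads.bed --peaks exp/rep1.peaks.narrowPeak \
    --labels rep1 --read-length 36 --out qc1.tsv

# overlap groups + pairwise agreement
repchip overlap --peaks exp/rep1.peaks.narrowPeak --peaks exp/rep2.peaks.narrowPeak \
    --peaks exp/rep3.peaks.narrowPeak \
    --out-groups groups.bed --out-pairs pairs.tsv

# consensus regions, coverage matrix, concordance
repchip consensus --peaks exp/rep1.peaks.narrowPeak --peaks exp/rep2.peaks.narrowPeak \
    --peaks exp/rep3.peaks.narrowPeak --chrom-sizes exp/chrom.sizes \
    --method smt --out consensus.bed
repchip quantify --regions consensus.bed --reads exp/rep1.reads.bed \
    --reads exp/rep2.reads.bed --reads exp/rep3.reads.bed \
    --labels rep1,rep2,rep3 --out coverage.tsv
repchip concordance --matrix coverage.tsv --out concordance.tsv

# DABG rescue screen
repchip dabg --peaks exp/rep1.peaks.narrowPeak --reads exp/rep1.reads.bed \
    --peaks exp/rep2.peaks.narrowPeak --reads exp/rep2.reads.bed \
    --peaks exp/rep3.peaks.narrowPeak --reads exp/rep3.reads.bed \
    --chrom-sizes exp/chrom.sizes --out dabg.tsv

# promoter / genic quantification units from an annotation
repchip features --gff exp/genes.gff3 --chrom-sizes exp/chrom.sizes \
    --kind promoter --out promoters.bed

# everything at once from a JSON config
repchip run --config config.json
```

The `run` config is JSON with `peaks` and `reads` (label → path maps),
`chrom_sizes`, `outdir`, and optional `annotation`, `method`
(max/smt/asf/asw/ref), `footprint`, `avg_width`, `alpha`, `read_length`,
`n_bins`, `kappa_weights`. QC thresholds produce flags in the reports,
never failures.

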