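# chipstarr

Quantitative enhancer-activity calling from ChIP-STARR-seq data.

ChIP-STARR-seq clones ChIP-enriched DNA fragments downstream of a minimal
promoter in a self-transcribing reporter (STARR-seq), so fragments with
enhancer activity transcribe themselves. Paired-end sequencing of the
plasmid library and of the reporter RNA identifies every plasmid by the
exact genomic coordinates of its insert, which makes activity measurable
per plasmid:

    RPP (reads per plasmid)  =  normalized RNA count / normalized DNA count

`chipstarr` implements the full computational path from peak calls and
fragment tables to activity maps and their downstream dissection:

1. **Region scaffold** — peaks from all samples are fixed to 500 bp (TF) or
   1000 bp (histone) around their summits, blacklisted peaks removed, the
   pooled set merged, and merged blocks recursively halved to ≤ 1000 bp
   disjoint regions.
2. **RPP quantification** — RNA fragments are matched to plasmids only on
   exact (chrom, start, end) identity; each plasmid library is normalized
   jointly with its derived RNA samples by median-of-ratios size factors;
   per-region activity is the maximum plasmid-level mean RPP.
3. **Activity threshold θ** — changepoint analysis of the ranked
   log2(RPP+1) curve (Gaussian cost with segment-specific mean and
   variance; AMOC/PELT/BinSeg/exact-DP solvers). Regions with RPP ≥ θ are
   active.
4. **Core/extended modules** — active regions overlapping a merged set of
   previously published predicted enhancers form the core module, the rest
   the extended module; regions are tied to genes by the basal-plus-extension
   rule (5 kb up / 1 kb down, extension to 100 kb).
5. **Transposable elements** — observed/expected overlap ratios per repeat
   family (O/E > 2 enriched, < 0.5 depleted, ≤ 15 total overlaps excluded).
6. **Super-enhancers** — ROSE-style stitching of H3K27ac peaks (12.5 kb,
   ±2.5 kb TSS exclusion), rank-signal slope-1 cutoff, and dissection of the
   *active subspace*: the fraction of SE bases covered by active plasmids.
7. **Sequence classifier** — conservation, GC, strand-max dinucleotide
   frequencies and exact-p-value PWM hits feed a balanced random forest
   (500 trees, 50 features/split, depth 10, 10-fold CV).

A synthetic-data generator (`chipstarr.simulate`) produces a complete
desk-scale experiment — genome, peaks, plasmid/RNA fragment tables with
negative-binomial noise, repeats, TSSs, super-enhancer domains — with
ground truth for every latent quantity, so the entire pipeline is verified
end to end by parameter recovery.

## Worked example

Run the whole pipeline on a simulated experiment (~50,000 plasmids, two RNA
replicates):

```bash
starr run --config demo.yaml
```

with `demo.yaml`:

```yaml
outdir: scratch/pipeline
simulate:
  seed: 1
```

or equivalently through the numbered analysis drivers:

```bash
python analysis/01_simulate.py
python analysis/02_quantify_activity.py
...
python analysis/07_recovery.py
```

The activity summary printed by step 02:

```
n_scaffold_regions  max_region_bp  n_measured  theta  n_active  n_inactive  n_unmeasured  orphan_rna_rate
               391           1000         331  45.23        61         270            60             0.02
```

391 scaffold regions were built from the simulated peaks (all ≤ 1000 bp);
331 of them were covered by at least one plasmid. The ranked-RPP
changepoint threshold came out at θ = 45.2 for this simulation, calling 61
regions active — the dataset plants 60 truly active enhancer loci. The
recovery report (step 07) compares everything against the ground truth:

```
spearman_latent_vs_rpp_max   0.874
balanced_accuracy_active     1.000
LTR7      planted O/E 4.0 -> recovered 4.00 (enriched)
HERVH-int planted O/E 4.0 -> recovered 3.89 (enriched)
se_00..se_04 planted active fraction 0.030 -> recovered 0.026..0.032
orphan_rate 0.020 configured -> 0.020 observed
```

So the rank order of latent activities is recovered (Spearman 0.87), the
threshold separates active from inactive loci perfectly, planted
transposable-element enrichments and the planted super-enhancer active
subspace (3% of SE bases) are recovered quantitatively, and the orphan-RNA
bookkeeping is exact.

Individual stages are also available as subcommands (`starr simulate`,
`scaffold`, `quant`, `threshold`, `modules`, `repeats`, `se`, `features`,
`classify`, `report`); see `starr --help`.

### Fragment-table dialect

Fragment inputs are either SAM/BAM (proper pairs, both mates MAPQ ≥ 30 on
one chromosome) or a 5-column TSV: `chrom  frag_start  frag_end  sample_id
count` with 0-based half-open coordinates. Full 10-column BEDPE is accepted
too (the name column is the sample id; cross-chromosome rows are dropped
with a warning).

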