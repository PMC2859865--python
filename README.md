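# bovicnv

Copy-number variant (CNV) discovery from bovine SNP-array intensity data,
with a matched synthetic-data generator for end-to-end validation.

## The problem

Medium-density SNP genotyping arrays (tens of thousands of markers, ~50 kb
spacing) report, for every sample × marker, a normalized total intensity
(R), a log R ratio (LRR) against a diploid reference, a B allele frequency
(BAF) and a called genotype (AA/AB/BB/NC). Deletions and duplications leave
coordinated footprints in these signals: a hemizygous deletion lowers LRR
and collapses BAF onto {0, 1}; a duplication raises LRR and splits the
heterozygote BAF band toward 1/3 and 2/3. Deletion polymorphisms segregating
in a pedigree additionally produce apparent Mendelian inconsistencies: a
sire carrying A/− is typed AA, his steer inheriting the deleted haplotype
with a maternal B is typed BB, and an A-vs-B opposite-homozygote conflict
appears at a marker where no genotyping error occurred.

`bovicnv` implements this analysis for half-sib beef-cattle designs
(sires and their steer progeny), but nothing in the code is specific to
cattle beyond the default 29 autosomes. The package is aimed at
quantitative geneticists and bioinformaticians who want a small,
inspectable, fully tested implementation rather than a monolithic pipeline.

## What the package does

- **`bovicnv.array_io`** — read/write tab-separated final-report intensity
  files and pedigree files, per-sample QC (call rate, LRR standard
  deviation with a strict `sd_lrr < 0.30` filter), BED export.
- **`bovicnv.synthetic_data`** — a seeded generator producing a half-sib
  cohort with haplotype-borne deletion/duplication alleles at configurable
  population frequencies, emitting LRR/BAF/R/genotypes, a pedigree, qPCR
  assays and a complete truth table (per-sample integer copy number at
  every marker).
- **`bovicnv.cnv_caller`** — a four-state (copy 0/1/2/3) hidden Markov
  model over LRR + BAF with distance-dependent transition probabilities,
  decoded per sample and chromosome by exact Viterbi; runs of non-diploid
  states spanning at least `min_markers` become CNV calls.
- **`bovicnv.cnvr`** — aggregation of per-sample calls into CNV regions by
  transitive ≥1 bp overlap, region frequency/type/length, gene-interval
  annotation and callset summary statistics.
- **`bovicnv.delpoly`** — deletion-polymorphism screens orthogonal to the
  HMM: per-marker parent–child opposite-homozygote error frequencies
  (candidates where frequency > 3%), a pairwise intensity-ratio scan
  (|log2(R_subject/R_reference)| ≥ 1.5), a six-cluster genoplot classifier
  (AA, AB, BB, A_del, B_del, null_del) from BAF/R, Hardy–Weinberg and
  missing-rate marker statistics, and a merge of both catalogues.
- **`bovicnv.qpcr`** — comparative-CT (2^−ΔΔCT) copy-number estimation from
  triplicate qPCR assays against a two-copy calibrator.

## Worked example

```python
import bovicnv.synthetic_data as sd
import bovicnv.cnv_caller as cc
import bovicnv.cnvr as cnvr
import bovicnv.delpoly as dp

# simulate a small half-sib cohort with embedded deletion and duplication alleles
cfg = sd.SimulationConfig(
    seed=11, n_sires=6, n_steers=60, n_chromosomes=2, n_markers=1200,
    event_specs=[
        sd.CNVEventSpec(1, 2_000_000, 2_400_000, copy_state=1, population_frequency=0.25),
        sd.CNVEventSpec(2, 5_000_000, 5_500_000, copy_state=3, population_frequency=0.15),
    ],
)
ds = sd.simulate_dataset(cfg)

calls = cc.call_cnvs(ds.table)
regions = cnvr.build_cnvrs(calls, n_samples=len(ds.table.samples))
print(f"{len(calls)} CNV calls in {len(regions)} regions")
for r in regions:
    print(f"  chr{r.chromosome}:{r.start}-{r.end}  type={cnvr.classify_type(r)}"
          f"  carriers={r.n_carriers}  freq={cnvr.cnvr_frequency(r, len(ds.table.samples))}")

stats = dp.pc_error_frequencies(ds.table, ds.pedigree)
candidates = dp.select_candidates(stats)
print(f"{len(candidates)} markers with parent-child error frequency > 3%")
```

Output:

```
55 CNV calls in 2 regions
  chr1:1955021-2394895  type=loss_only  carriers=25  freq=0.379
  chr2:5063077-5487777  type=gain_only  carriers=30  freq=0.455
9 markers with parent-child error frequency > 3%
```

Both embedded events are recovered as single regions with boundaries at
the flanking markers, and the parent–child error screen flags markers
inside the chromosome 1 deletion.

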