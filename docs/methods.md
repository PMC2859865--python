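# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions and the known limitations of `bovicnv`.

## 1. Signal model

At each marker the array reports, per sample:

- **R** — normalized total intensity; proportional to total allele copy
  number, so a diploid sample sits near R = 1 and a hemizygote near 0.5.
- **LRR** — log R ratio, `log2(R_observed / R_expected_diploid)`; near 0
  for two copies, depressed for losses, elevated for gains.
- **BAF** — B allele frequency; the fraction of the signal attributable to
  the B allele, clustering at {0, ½, 1} for diploid AA/AB/BB.
- **Genotype** — the clustering algorithm's discrete call
  (AA/AB/BB or NC for no-call).

Copy-number states are the integers 0–3 (homozygous deletion, hemizygous
deletion, normal diploid, single-copy duplication). Higher amplifications
are out of scope for medium-density arrays and are not modelled.

## 2. Segmentation HMM (`cnv_caller`)

A four-state hidden Markov model over (LRR, BAF) per sample per
chromosome, decoded exactly by Viterbi.

**Emissions.** LRR is Gaussian per state with means
`lrr_means = (−3.0, −0.66, 0.0, +0.40)` and common SD `lrr_sd = 0.20`.
The means are the standard cluster centres for copies 0/1/2/3 on log2
intensity scale: a hemizygote is at log2(1/2) ≈ −1 before attenuation
(−0.66 reflects the usual signal compression), a single-copy gain at
roughly log2(3/2) ≈ 0.58 similarly attenuated to +0.40, and copy 0 is far
below everything (the exact value barely matters once it is ≪ −2). BAF is
a Gaussian mixture (`baf_sd = 0.05`) over the genotype clusters each state
permits: {0, 1} for one copy, {0, ½, 1} for two, {0, ⅓, ⅔, 1} for three;
mixture weights are Hardy–Weinberg given the B-allele frequency
(`pfb = 0.5` by default — per-marker population frequencies can be used
but cohort-level estimation is not part of the package). Copy 0 has no
genotype, so its BAF density is uniform on [0, 1]. A marker with missing
LRR and BAF contributes log-likelihood 0 to every state (uninformative).

**Transitions.** The probability of changing state decays with the
physical gap g between adjacent markers: the zero-gap rates
`p_enter_cnv = 0.01` (diploid → any CNV state, split equally across the
three), `p_stay_cnv = 0.95` (CNV persistence) and `p_cnv_to_cnv = 0.01`
(direct switching between CNV states) are all scaled by
`exp(−g / transition_decay_bp)` with `transition_decay_bp = 500 kb`, so
distant markers are nearly independent. This is the standard
distance-aware construction for sparse marker maps. Initial-state
probabilities equal the zero-gap transition row out of the diploid state.

**Calls.** Maximal runs of a single non-diploid state spanning at least
`min_markers = 3` markers become `CNVCall`s; call boundaries are the
positions of the run's first and last markers (the data cannot localize a
breakpoint between markers, so no extrapolation into flanking gaps is
attempted). Viterbi ties are broken toward the lowest state index (first
argmax), i.e. toward losses; ties are measure-zero under continuous noise,
but the rule is fixed so decoding is deterministic. The decoder is tested
against exhaustive enumeration of all 4^n state paths up to n = 12.

## 3. CNV regions (`cnvr`)

Calls on the same chromosome are merged into CNV regions by transitive
closure of pairwise overlap: two intervals overlap iff
`a.start < b.end and b.start < a.end` (half-open convention, ≥1 bp shared).
Region **length is `end − start`** and region frequency is
carriers / cohort size, rounded to 3 decimals. Regions are typed
`loss_only` / `gain_only` / `mixed` from their member states. Coordinates
are stored 1-based; **BED export writes `start − 1` and `end`** (0-based
half-open), and BED import reverses this. These two conventions are
internally consistent under the half-open reading and both are exercised
in the tests. Gene annotation uses an interval tree and reports genes whose
span intersects the region (abutting-only genes, sharing no base, are
excluded by the same half-open predicate).

## 4. Deletion-polymorphism screens (`delpoly`)

**Parent–child (P-C) error screen.** For a sire–steer duo, the only
genotype configuration impossible under Mendelian inheritance at a
biallelic marker is opposite homozygotes (AA vs BB). A segregating
deletion produces exactly this artefact: A/− is typed AA and B/− typed BB.
Duos are first QC'd on overall heritability concordance
(1 − errors/informative, threshold ≥ 0.996); then per-marker error
frequencies are computed over informative duos (both members called), and
markers with frequency **strictly > 3%** become candidates
(`strict=False` gives ≥ for the laxer reading). The 3% threshold sits far
above the residual genotyping-error floor (≲0.5%) while catching deletion
alleles of a few percent population frequency.

**Pairwise intensity scan.** Each QC-passing sample is compared to a
single reference — the lowest-`sd_lrr` QC-passing sample — and markers
with `|log2(R_sample / R_reference)| ≥ 1.5` are flagged (deletion side:
negative ratio). A hemizygote against a diploid reference sits near −1
before noise, and a null near −4+, so 1.5 separates real null/low-copy
signal from intensity jitter. The marker-level catalogue keeps markers
flagged on the deletion side in at least `min_carriers = 3` samples; this
guard is the package's own choice to suppress single-sample intensity
artefacts.

**Six-genotype classifier.** At a candidate marker, samples are classified
into AA, AB, BB, A_del, B_del, null_del from BAF and R. BAF splits samples
into A-side (< 0.15), B-side (> 0.85) and heterozygous band; R is cut into
three tiers at `c0 = 0.15·m` (null) and `c1 = 0.70·m` (hemizygous vs
diploid), where m is the diploid intensity anchor. The anchor is the
median R of heterozygous-band samples — hemizygotes cannot be AB, so this
band is diploid — after excluding samples with R ≤ 0.5× the overall median
R: null samples have uniform BAF and otherwise contaminate the band when
deletion frequency is high. If fewer than 3 anchor samples remain, the
95th percentile of R is used. A refinement pass re-estimates m from all
samples landing in the diploid tier. A marker has `cluster_evidence` if
≥ `min_hemizygous = 3` samples classify as hemizygous; classification
requires ≥ `min_called = 10` samples. The classifier is tested to ≥ 95%
agreement with simulation truth at a 20%-frequency deletion.

**Merging.** The heritability and pairwise catalogues are merged by marker
ID (union), with provenance (`methods` set) and optional per-marker
evidence (P-C error frequency, cluster flag, Hardy–Weinberg chi-square
p-value, missing rate) attached. `marker_hwe_chi2` is the 1-df goodness-of-fit
test against Hardy–Weinberg expectations (`None` for monomorphic markers);
deletions inflate apparent homozygosity and depress the p-value.

## 5. qPCR copy estimation (`qpcr`)

The comparative-CT method: per assay, ΔCT is the mean of per-replicate
(target − reference) CT differences over exactly three positive
replicates; ΔΔCT subtracts the ΔCT of a known two-copy calibrator; copy
number is `2 × 2^(−ΔΔCT)` and the reported integer is `floor(copy + 0.5)`.
A CT ceiling of 40 encodes non-amplification, so copy-0 samples produce a
large ΔCT and round to 0. The method is scale-free in absolute CT (adding
a constant to every CT leaves estimates unchanged), which the tests verify.

## 6. Synthetic-data generator (`synthetic_data`)

The generator emulates a half-sib design: `n_sires = 17` sires and
`n_steers = 248` steers assigned round-robin (or `steers_per_sire` to
force an exact design, e.g. one steer per sire for independent duos).

- **Marker map** — per chromosome, inter-marker gaps are i.i.d.
  exponential with mean `mean_spacing_bp = 51,500` (median below the mean,
  as on real arrays), markers truncated at `chromosome_length_bp = 110 Mb`;
  `n_markers = 54,001` total across `n_chromosomes = 29` autosomes by
  default.
- **Haplotypes** — each sire carries two haplotypes; each steer inherits
  one sire haplotype (drawn independently per chromosome — no intra-
  chromosome recombination) and one population haplotype. SNP B-allele
  frequencies are uniform on `allele_freq_range = (0.05, 0.95)`. CNV
  alleles (`CNVEventSpec`) live on haplotypes at the specified population
  frequency, so deletions segregate through the pedigree and reproduce the
  opposite-homozygote artefact exactly. Per-marker copy number is the sum
  of haplotype multiplicities (1 − deletion + duplication per haplotype,
  clipped to [0, 2]), capped at 3 overall to stay within the modelled
  state space.
- **Genotypes** — derived from B dosage and copy number; null markers are
  reported NC by default (`null_genotype = "nc"`), or as a random
  homozygote to mimic clustering software that force-calls nulls. Random
  no-calls at `nc_rate = 0.0043` (call rate 99.57%); optional genotype
  error at `genotype_error_rate = 0` by default.
- **Intensities** — LRR ~ Normal(`lrr_means[copy]`, `lrr_noise_sd = 0.15`);
  BAF = clip(B dosage / copy + Normal(0, `baf_noise_sd = 0.03`)) or
  uniform for copy 0; R = max(0.01, `r_base`·copy/2 + Normal(0,
  `r_noise_sd = 0.08`)), with copy-0 samples at the background level
  `r_background = 0.05`.
- **qPCR** — CTs from the true copy number with noise
  `qpcr_ct_noise_sd = 0.1` and non-amplification at the
  `qpcr_ct_ceiling = 40`.
- **Truth** — a complete per-sample × marker copy-number table plus the
  per-sample event list, for recovery scoring.

What the generator does **not** emulate: linkage disequilibrium,
recombination within chromosomes, GC-content intensity waves, batch
effects, X/Y chromosomes, de-novo (non-inherited) events as a population
process (events are haplotype-borne; `inherited=False` simply draws
carriers per individual), or copy numbers above 3.

All randomness flows from a single `numpy.random.default_rng(seed)`
threaded through every stage, so a `SimulationConfig` is a complete,
reproducible description of a dataset (JSON round-trip supported).

## 7. QC and conventions

- Sample QC: per-sample LRR standard deviation uses the **population**
  (ddof = 0) formula over non-missing markers; the filter is **strict**
  `sd_lrr < 0.30`. Call rate is called/total markers.
- All thresholds stated as "exceeds" are strict inequalities
  (P-C candidate > 3%; sd filter < 0.30); the pairwise scan uses ≥ 1.5 as
  an "at least" magnitude criterion.
- Derived seeds are kept below 2^31 for portability.

## 8. Problem sizes used in validation

The test suite and `scripts/acceptance.py` use cohorts the package chose
to balance statistical resolution against runtime: a shared 5-sire /
45-steer, 3-chromosome, 1,800-marker cohort with two deletions and one
duplication for recovery and screening tests; a 150-duo one-steer-per-sire
design where the binomial standard error is the correct yardstick for the
P-C error frequency (half-sib designs violate independence because
siblings share the sire's deletion haplotype); a 10-sire / 245-steer
single-chromosome cohort for the six-genotype classifier; and the
acceptance script's 10-sire / 90-steer, 4-chromosome, ~2,000-marker
pipeline with five embedded events. Exhaustive Viterbi checking is bounded
at 12 markers (4^12 ≈ 1.7 × 10^7 paths).

## 9. Limitations

- The HMM assumes homogeneous emission noise across markers and samples;
  real arrays show per-probe variance and wave artefacts that would need
  per-marker parameters.
- `pfb = 0.5` flattens the BAF mixture weights; supplying per-marker
  B-allele frequencies sharpens state discrimination but is left to the
  caller.
- Breakpoints are reported at flanking marker positions; true breakpoints
  lie anywhere in the adjacent gaps (~50 kb uncertainty at default
  spacing).
- The P-C screen needs duos; it cannot run on unrelated cohorts, and its
  power at a marker scales with deletion frequency and heterozygosity.
- The pairwise scan depends on a clean reference sample; a reference
  carrying a deletion masks that locus cohort-wide.
- Copy numbers above 3 are collapsed to 3 throughout.
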