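"""Aggregation of per-sample CNV calls into population-level CNV regions.

A CNV region (CNVR) is the transitive closure of pairwise overlap among
calls: any two calls sharing >= 1 bp on the same chromosome belong to the
same region, whose span is the min start / max end of its members. Region
frequency is member-call count over genotyped samples; the type class is
gain_only / loss_only / mixed by member copy states. Lengths follow the
printed convention ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from intervaltree import IntervalTree

from .array_io import GeneInterval, write_bed
from .cnv_caller import CNVCall


@dataclass
class CNVRegion:
    """A merged region with its member calls and population summary."""

    chromosome: int
    start: int
    end: int
    member_calls: list[CNVCall]
    frequency: float | None = None
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if not self.member_calls:
            raise ValueError("a region needs at least one member call")
        for c in self.member_calls:
            if not (c.chromosome == self.chromosome and c.start < self.end and self.start < c.end):
                raise ValueError("member call does not overlap the region span")

    @property
    def n_cnvs(self) -> int:
        return len(self.member_calls)

    @property
    def type(self) -> str:
        return classify_type(self)

    @property
    def n_carriers(self) -> int:
        """Distinct samples contributing calls (optional alternative count)."""
        return len({c.sample_id for c in self.member_calls})


@dataclass(frozen=True)
class CallsetSummary:
    """Cohort-level summary statistics of a CNV call set."""

    n_cnvs: int
    mean_per_sample: float
    mean_size_kb: float
    median_size_kb: float
    n_gain: int
    n_loss: int
    loss_gain_ratio: float | None  # None when there are no gains
    n_common_1pct: int
    n_common_2_5pct: int
    n_common_5pct: int
    n_genes: int


def build_cnvrs(
    calls: list[CNVCall], n_samples: int | None = None
) -> list[CNVRegion]:
    """Partition calls into regions by transitive >= 1 bp overlap.

    Regions are disjoint, sorted by (chromosome, start); each input call
    belongs to exactly one region. If ``n_samples`` is given, region
    frequencies (member count / n_samples) are filled in.
    """
    regions: list[CNVRegion] = []
    by_chrom: dict[int, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur: list[CNVCall] = []
        cur_end = None
        for c in chunk:
            if cur and c.start < cur_end:
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                if cur:
                    regions.append(_make_region(chrom, cur, n_samples))
                cur = [c]
                cur_end = c.end
        if cur:
            regions.append(_make_region(chrom, cur, n_samples))
    return regions


def _make_region(
    chrom: int, members: list[CNVCall], n_samples: int | None
) -> CNVRegion:
    region = CNVRegion(
        chromosome=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        member_calls=members,
    )
    if n_samples is not None:
        region.frequency = cnvr_frequency(region, n_samples)
    return region


def region_length(region) -> int:
    """Region length as printed in CNVR tables: end - start."""
    return region.end - region.start


def cnvr_frequency(region: CNVRegion, n_samples: int) -> float:
    """Member-call count over genotyped samples, rounded to 3 decimals.

    The numerator counts member calls, not distinct carriers (the reporting
    convention of the CNVR tables this reproduces); use
    :attr:`CNVRegion.n_carriers` for the distinct-carrier alternative.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return round(region.n_cnvs / n_samples, 3)


def classify_type(region: CNVRegion) -> str:
    """gain_only if every member is a gain, loss_only if every member is a
    loss, otherwise mixed."""
    states = [c.copy_state for c in region.member_calls]
    if all(s > 2 for s in states):
        return "gain_only"
    if all(s < 2 for s in states):
        return "loss_only"
    return "mixed"


def annotate_genes(
    regions: list[CNVRegion], genes: list[GeneInterval]
) -> list[CNVRegion]:
    """Fill each region's gene list: a gene is listed iff its interval
    overlaps the region span by >= 1 bp (half-open comparison); genes are
    deduplicated per region and listed in positional order."""
    by_chrom: dict[int, IntervalTree] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end, g)
    for region in regions:
        tree = by_chrom.get(region.chromosome)
        found = tree.overlap(region.start, region.end) if tree else set()
        hits = sorted({iv.data for iv in found}, key=lambda g: (g.start, g.gene_id))
        seen: set[str] = set()
        region.genes = [g.gene_id for g in hits if not (g.gene_id in seen or seen.add(g.gene_id))]
    return regions


def _size_stats_kb(intervals) -> tuple[float, float]:
    sizes = [region_length(iv) / 1000.0 for iv in intervals]
    if not sizes:
        return 0.0, 0.0
    return round(sum(sizes) / len(sizes), 1), round(median(sizes), 1)


def _common_counts(regions: list[CNVRegion]) -> tuple[int, int, int]:
    freqs = [r.frequency for r in regions if r.frequency is not None]
    return (
        sum(f > 0.01 for f in freqs),
        sum(f > 0.025 for f in freqs),
        sum(f > 0.05 for f in freqs),
    )


def summarize_callset(
    calls: list[CNVCall], regions: list[CNVRegion], n_samples: int
) -> CallsetSummary:
    """Table-1-style summary of an individual-CNV call set.

    Mean per sample, mean/median sizes (end - start, kb) and the
    loss/gain ratio are rounded to one decimal; common-region counts use
    strict thresholds (> 1%, > 2.5%, > 5%) on region frequencies; the gene
    count is the number of distinct genes across annotated regions. With no
    gains the ratio is reported as None (undefined), not an exception.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_gain = sum(c.copy_state > 2 for c in calls)
    n_loss = sum(c.copy_state < 2 for c in calls)
    mean_kb, median_kb = _size_stats_kb(calls)
    c1, c25, c5 = _common_counts(regions)
    genes = {g for r in regions for g in r.genes}
    return CallsetSummary(
        n_cnvs=len(calls),
        mean_per_sample=round(len(calls) / n_samples, 1),
        mean_size_kb=mean_kb,
        median_size_kb=median_kb,
        n_gain=n_gain,
        n_loss=n_loss,
        loss_gain_ratio=round(n_loss / n_gain, 1) if n_gain else None,
        n_common_1pct=c1,
        n_common_2_5pct=c25,
        n_common_5pct=c5,
        n_genes=len(genes),
    )


def summarize_regions(regions: list[CNVRegion], n_samples: int) -> CallsetSummary:
    """The same summary computed over regions (Table-1 CNVR row): counts,
    per-sample mean and size statistics refer to regions themselves."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mean_kb, median_kb = _size_stats_kb(regions)
    types = [classify_type(r) for r in regions]
    c1, c25, c5 = _common_counts(regions)
    genes = {g for r in regions for g in r.genes}
    return CallsetSummary(
        n_cnvs=len(regions),
        mean_per_sample=round(len(regions) / n_samples, 1),
        mean_size_kb=mean_kb,
        median_size_kb=median_kb,
        n_gain=sum(t == "gain_only" for t in types),
        n_loss=sum(t == "loss_only" for t in types),
        loss_gain_ratio=None,
        n_common_1pct=c1,
        n_common_2_5pct=c25,
        n_common_5pct=c5,
        n_genes=len(genes),
    )


def write_regions_tsv(regions: list[CNVRegion], path) -> None:
    """Export regions in the CNVR-table layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("CNV region\tLength (bp)\tNo. of CNVs\tFrequency\tNo. of genes\tGenes\n")
        for r in regions:
            freq = "" if r.frequency is None else f"{r.frequency:.3f}"
            fh.write(
                f"chr{r.chromosome}:{r.start}-{r.end}\t{region_length(r)}\t"
                f"{r.n_cnvs}\t{freq}\t{len(r.genes)}\t{','.join(r.genes)}\n"
            )


def write_regions_bed(regions: list[CNVRegion], path) -> None:
    write_bed(
        [(r.chromosome, r.start, r.end, classify_type(r)) for r in regions], path
    )
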