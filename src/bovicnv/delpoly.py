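"""Common-deletion-polymorphism discovery.

Two complementary marker-level screens are implemented and merged:

1. **Heritability-error (Mendelian-inconsistency) screening.** For a
   biallelic marker, the only sire/steer duo configuration impossible under
   Mendelian transmission is the opposite-homozygote pair (AA vs BB). A
   deletion allele segregating at a marker produces exactly this artefact:
   a hemizygous B/- sire is reported BB, and a steer inheriting that
   deleted haplotype plus a dam A allele is reported AA. Markers whose
   parent-child (P-C) error frequency exceeds a threshold (default strict
   > 3%) are candidates; a six-cluster genoplot classifier (A/A, A/B, B/B,
   A/-, B/-, -/-) on BAF x total-intensity R replaces manual visual
   inspection.

2. **Pairwise intensity-ratio scanning.** Against a high-quality reference
   sample, markers with |log2(R_target/R_reference)| >= 1.5 flag copy
   differences; markers where enough samples hit the negative side form
   the pairwise deletion catalogue.

Ancillary per-marker flags (Hardy-Weinberg deviation, missing-genotype
rate) are provided because deletions inflate both, but they are not
selection criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import IntensityTable, PedigreePair, SampleQC

SIX_GENOTYPES = ("AA", "AB", "BB", "A_del", "B_del", "null_del")


@dataclass(frozen=True)
class MendelMarkerStat:
    """Per-marker parent-child error count over informative duos."""

    marker_id: str
    n_pairs_informative: int
    n_errors: int

    def __post_init__(self) -> None:
        if self.n_errors > self.n_pairs_informative:
            raise ValueError("errors cannot exceed informative pairs")

    @property
    def pc_error_freq(self) -> float | None:
        if self.n_pairs_informative == 0:
            return None
        return self.n_errors / self.n_pairs_informative


@dataclass(frozen=True)
class PairwiseHit:
    """A target/reference intensity-ratio excursion at one marker."""

    marker_id: str
    target_sample: str
    reference_sample: str
    log2_ratio: float

    @property
    def is_deletion_side(self) -> bool:
        return self.log2_ratio < 0


@dataclass
class DeletionPolymorphism:
    """A merged catalogue entry with method provenance and evidence."""

    marker_id: str
    methods: set[str]
    pc_error_freq: float | None = None
    cluster_evidence: bool = False
    hwe_p: float | None = None
    missing_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be non-empty")
        bad = self.methods - {"heritability", "pairwise"}
        if bad:
            raise ValueError(f"unknown methods: {bad}")


@dataclass
class SixGenotypeParams:
    """Thresholds of the automated genoplot-cluster classifier.

    BAF sides are called below ``baf_low`` (A side) / above ``baf_high``
    (B side). Intensity tiers are relative to ``m``, the median R of
    diploid-tier homozygotes: null below ``c0 * m``, hemizygous in
    ``[c0 * m, c1 * m)``, diploid above. ``min_hemizygous`` samples on a
    BAF side are needed to flag the six-cluster pattern.
    """

    baf_low: float = 0.15
    baf_high: float = 0.85
    c0: float = 0.15
    c1: float = 0.70
    min_hemizygous: int = 3
    min_called: int = 10


@dataclass
class SixGenotypeResult:
    labels: pd.Series  # sample -> one of SIX_GENOTYPES; empty if too few samples
    cluster_evidence: bool
    n_hemizygous: int = 0
    n_null: int = 0


def mendel_error(sire_genotype: str, steer_genotype: str) -> bool:
    """True iff the duo is an opposite-homozygote pair (AA vs BB), the only
    single-parent-impossible configuration at a biallelic marker."""
    if sire_genotype == "NC" or steer_genotype == "NC":
        raise ValueError("mendel_error requires called genotypes; pre-filter NC")
    for g, who in ((sire_genotype, "sire"), (steer_genotype, "steer")):
        if g not in ("AA", "AB", "BB"):
            raise ValueError(f"unknown {who} genotype {g!r}")
    return {sire_genotype, steer_genotype} == {"AA", "BB"}


def pair_heritability_concordance(
    table: IntensityTable, pairs: list[PedigreePair]
) -> dict[tuple[str, str], float]:
    """Per-duo heritability concordance: 1 - (P-C errors / informative
    markers). Used as pair QC before marker-level screening."""
    gt = table.genotype
    out = {}
    for p in pairs:
        sire = gt.loc[p.sire_id].to_numpy()
        steer = gt.loc[p.steer_id].to_numpy()
        informative = (sire != "NC") & (steer != "NC")
        n = int(informative.sum())
        if n == 0:
            out[(p.sire_id, p.steer_id)] = float("nan")
            continue
        err = _opposite_hom(sire, steer) & informative
        out[(p.sire_id, p.steer_id)] = 1.0 - err.sum() / n
    return out


def filter_pairs(
    table: IntensityTable,
    pairs: list[PedigreePair],
    min_concordance: float = 0.996,
) -> list[PedigreePair]:
    """Keep duos whose heritability concordance is >= the threshold."""
    conc = pair_heritability_concordance(table, pairs)
    return [p for p in pairs if conc[(p.sire_id, p.steer_id)] >= min_concordance]


def _opposite_hom(sire: np.ndarray, steer: np.ndarray) -> np.ndarray:
    return ((sire == "AA") & (steer == "BB")) | ((sire == "BB") & (steer == "AA"))


def pc_error_frequencies(
    table: IntensityTable,
    pairs: list[PedigreePair],
    markers: list[str] | None = None,
) -> list[MendelMarkerStat]:
    """Per-marker P-C error counts over informative duos (both called)."""
    ids = markers if markers is not None else table.markers.marker_ids
    gt = table.genotype[ids]
    sires = gt.loc[[p.sire_id for p in pairs]].to_numpy()
    steers = gt.loc[[p.steer_id for p in pairs]].to_numpy()
    informative = (sires != "NC") & (steers != "NC")
    errors = _opposite_hom(sires, steers) & informative
    n_inf = informative.sum(axis=0)
    n_err = errors.sum(axis=0)
    return [
        MendelMarkerStat(m, int(n_inf[j]), int(n_err[j])) for j, m in enumerate(ids)
    ]


def select_candidates(
    stats: list[MendelMarkerStat], threshold: float = 0.03, strict: bool = True
) -> list[str]:
    """Markers whose P-C error frequency exceeds the threshold.

    Default is the strict inequality (> 3%); ``strict=False`` switches to
    >=, matching the laxer reading of the selection rule.
    """
    out = []
    for s in stats:
        f = s.pc_error_freq
        if f is None:
            continue
        if (f > threshold) if strict else (f >= threshold):
            out.append(s.marker_id)
    return out


def classify_six_genotypes(
    table: IntensityTable,
    marker_id: str,
    params: SixGenotypeParams | None = None,
) -> SixGenotypeResult:
    """Automated six-cluster genoplot classification for one marker.

    Samples split by BAF side (A / heterozygous / B) and by normalized
    total-intensity tier. The diploid reference level ``m`` is estimated
    first from BAF-heterozygous samples (heterozygotes only exist at copy
    2), then refined as the median R of diploid-tier homozygotes; tiers are
    reassigned once against the refined ``m``. ``cluster_evidence`` is True
    when a hemizygous tier of at least ``min_hemizygous`` side-classified
    samples exists, i.e. when the genoplot would show the six-cluster
    pattern.
    """
    p = params or SixGenotypeParams()
    baf = table.baf[marker_id]
    r = table.r_total[marker_id]
    valid = baf.notna() & r.notna()
    if int(valid.sum()) < p.min_called:
        return SixGenotypeResult(pd.Series(dtype=object), cluster_evidence=False)
    baf = baf[valid]
    r = r[valid]
    side = pd.Series(
        np.where(baf < p.baf_low, "A", np.where(baf > p.baf_high, "B", "H")),
        index=baf.index,
    )
    # anchor the diploid intensity level on BAF-heterozygous samples, but
    # guard against copy-0 contamination: null samples have uniform BAF and
    # near-background R, so they can flood the middle BAF band at markers
    # where the deletion is common
    het_r = r[(side == "H") & (r > 0.5 * float(r.median()))]
    m = float(het_r.median()) if len(het_r) >= 3 else float(r.quantile(0.95))
    for _ in range(2):  # one refinement pass against diploid-tier homozygotes
        diploid = r >= p.c1 * m
        hom_dip = r[diploid & (side != "H")]
        if len(hom_dip) >= 3:
            m = float(hom_dip.median())
    null_tier = r < p.c0 * m
    hemi_tier = (r >= p.c0 * m) & (r < p.c1 * m)
    labels = pd.Series(index=baf.index, dtype=object)
    labels[null_tier] = "null_del"
    labels[hemi_tier & (baf < 0.5)] = "A_del"
    labels[hemi_tier & (baf >= 0.5)] = "B_del"
    dip = ~(null_tier | hemi_tier)
    labels[dip & (side == "A")] = "AA"
    labels[dip & (side == "H")] = "AB"
    labels[dip & (side == "B")] = "BB"
    n_hemi = int(hemi_tier.sum())
    return SixGenotypeResult(
        labels=labels,
        cluster_evidence=n_hemi >= p.min_hemizygous,
        n_hemizygous=n_hemi,
        n_null=int(null_tier.sum()),
    )


def pairwise_scan(
    table: IntensityTable,
    target_sample: str,
    reference_sample: str,
    threshold: float = 1.5,
) -> list[PairwiseHit]:
    """Markers where |log2(R_target / R_reference)| >= threshold.

    Markers missing R in either sample are skipped. The reference should be
    a high-quality (low sd_lrr) sample; see :func:`select_reference_sample`.
    """
    if target_sample == reference_sample:
        raise ValueError("target and reference must differ")
    r_t = table.r_total.loc[target_sample]
    r_r = table.r_total.loc[reference_sample]
    ok = r_t.notna() & r_r.notna()
    ratio = np.log2(r_t[ok] / r_r[ok])
    hits = ratio[np.abs(ratio) >= threshold]
    return [
        PairwiseHit(m, target_sample, reference_sample, float(v))
        for m, v in hits.items()
    ]


def select_reference_sample(qc: list[SampleQC], sd_threshold: float = 0.30) -> str:
    """Lowest-noise sample among those passing QC."""
    passing = [q for q in qc if q.sd_lrr < sd_threshold]
    if not passing:
        raise ValueError("no sample passes QC")
    return min(passing, key=lambda q: q.sd_lrr).sample_id


def pairwise_deletion_candidates(
    table: IntensityTable,
    qc: list[SampleQC],
    threshold: float = 1.5,
    min_carriers: int = 3,
) -> list[str]:
    """Marker-level pairwise deletion catalogue.

    Every QC-passing sample other than the reference is scanned; a marker
    qualifies when at least ``min_carriers`` targets hit the deletion side
    (log2 ratio <= -threshold). Positive-side (duplication) hits are
    recorded by :func:`pairwise_scan` but excluded from the deletion
    catalogue.
    """
    reference = select_reference_sample(qc)
    counts: dict[str, int] = {}
    for sample in table.samples:
        if sample == reference:
            continue
        for hit in pairwise_scan(table, sample, reference, threshold):
            if hit.is_deletion_side:
                counts[hit.marker_id] = counts.get(hit.marker_id, 0) + 1
    order = {m: i for i, m in enumerate(table.markers.marker_ids)}
    return sorted(
        (m for m, n in counts.items() if n >= min_carriers), key=order.__getitem__
    )


def merge_methods(
    heritability_markers: list[str],
    pairwise_markers: list[str],
    pc_error_freqs: dict[str, float] | None = None,
    cluster_flags: dict[str, bool] | None = None,
    hwe_ps: dict[str, float] | None = None,
    missing_rates: dict[str, float] | None = None,
) -> list[DeletionPolymorphism]:
    """Set union of the two catalogues with method provenance.

    The output size obeys inclusion-exclusion: |A| + |B| - |A and B|.
    Markers found by both methods carry both flags.
    """
    methods_by_marker: dict[str, set[str]] = {}
    for m in heritability_markers:
        methods_by_marker.setdefault(m, set()).add("heritability")
    for m in pairwise_markers:
        methods_by_marker.setdefault(m, set()).add("pairwise")
    out = []
    for m in sorted(methods_by_marker):
        out.append(
            DeletionPolymorphism(
                marker_id=m,
                methods=methods_by_marker[m],
                pc_error_freq=(pc_error_freqs or {}).get(m),
                cluster_evidence=(cluster_flags or {}).get(m, False),
                hwe_p=(hwe_ps or {}).get(m),
                missing_rate=(missing_rates or {}).get(m),
            )
        )
    return out


def marker_hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> float | None:
    """One-degree-of-freedom chi-square Hardy-Weinberg test p-value on
    called genotype counts; None for monomorphic or empty markers."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return None
    p = (2 * n_bb + n_ab) / (2 * n)  # B allele frequency
    if p == 0.0 or p == 1.0:
        return None
    q = 1 - p
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def marker_missing_rate(genotypes: pd.Series) -> float:
    """Fraction of NC entries at a marker."""
    if len(genotypes) == 0:
        raise ValueError("empty genotype column")
    return float((genotypes == "NC").mean())


def write_catalogue_tsv(
    catalogue: list[DeletionPolymorphism], table: IntensityTable, path
) -> None:
    chrom = table.markers.chromosome_of()
    pos = table.markers.position_of()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "marker_id\tchromosome\tposition\tmethods\tpc_error_freq\t"
            "cluster_evidence\thwe_p\tmissing_rate\n"
        )
        for d in catalogue:
            freq = "" if d.pc_error_freq is None else f"{d.pc_error_freq:.4f}"
            hwe = "" if d.hwe_p is None else f"{d.hwe_p:.3g}"
            miss = "" if d.missing_rate is None else f"{d.missing_rate:.4f}"
            fh.write(
                f"{d.marker_id}\t{chrom.get(d.marker_id, '')}\t{pos.get(d.marker_id, '')}\t"
                f"{'+'.join(sorted(d.methods))}\t{freq}\t{d.cluster_evidence}\t{hwe}\t{miss}\n"
            )
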