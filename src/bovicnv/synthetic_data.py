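"""Seed-reproducible synthetic cohorts for the CNV pipeline.

Emulates a half-sib beef-cattle cohort genotyped on a ~54k SNP array:
29 autosomes, exponentially spaced markers (mean gap ~51.5 kb, so the
median gap falls below the mean, as on the real chip), 17 sires each with
a set of steer offspring (248 steers by default, 265 animals total), and
embedded deletion/duplication alleles segregating in the population.

The deletion mechanism reproduces the genotype artefact that drives
Mendelian-inconsistency screening: on a haplotype carrying a deletion the
SNP allele is absent, so a hemizygous A/- animal is reported as the A/A
homozygote and a B/- animal as B/B. A sire transmitting its deleted
haplotype to a steer whose dam contributes the opposite allele yields an
opposite-homozygote parent-child pair, impossible under diploid Mendelian
transmission.

Every generated dataset carries a :class:`TruthTable` (per sample x marker
copy number plus per-sample event intervals) so downstream callers and
classifiers can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import IntensityTable, MarkerMap, PedigreePair
from .qpcr import QPCRAssay

__all__ = [
    "CNVEventSpec",
    "SimulationConfig",
    "TruthTable",
    "GenotypeSimulation",
    "SimulatedDataset",
    "simulate_marker_map",
    "simulate_pedigree",
    "simulate_pedigree_genotypes",
    "simulate_intensities",
    "simulate_qpcr",
    "simulate_dataset",
]


@dataclass(frozen=True)
class CNVEventSpec:
    """A copy-number allele segregating in the population.

    ``copy_state`` names the event type: 0 or 1 for a deletion allele
    (hemizygous carriers sit at copy 1; homozygous carriers, arising at
    frequency ~f^2, at copy 0), 3 for a duplication allele. ``inherited``
    events ride on haplotypes, so a sire transmits the allele to each steer
    with probability 1/2; non-inherited events are drawn independently per
    individual haplotype (de novo-like).
    """

    chromosome: int
    start: int
    end: int
    copy_state: int
    population_frequency: float
    inherited: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if self.copy_state not in (0, 1, 3):
            raise ValueError("copy_state must be 0, 1 (deletion) or 3 (duplication)")
        if not 0 < self.population_frequency <= 1:
            raise ValueError("population_frequency must be in (0, 1]")

    @property
    def is_deletion(self) -> bool:
        return self.copy_state in (0, 1)


@dataclass
class SimulationConfig:
    """Study-design and signal-model parameters for the generator.

    Defaults describe the cohort the pipeline targets: 17 sires and 248
    steers (265 animals), 54,001 markers over 29 autosomes at a mean
    spacing of 51.5 kb, array call rate ~99.57% (``nc_rate``). Signal-model
    defaults follow the conventional SNP-array model: per-copy-state LRR
    means (-3.0, -0.66, 0.0, +0.40) for copy 0/1/2/3 and total intensity R
    proportional to copy number.
    """

    seed: int = 0
    n_sires: int = 17
    steers_per_sire: int | None = None
    n_steers: int = 248
    n_chromosomes: int = 29
    chromosome_length_bp: int = 110_000_000
    mean_spacing_bp: float = 51_500.0
    n_markers: int = 54_001
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    lrr_means: tuple[float, float, float, float] = (-3.0, -0.66, 0.0, 0.40)
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    r_base: float = 1.0
    r_noise_sd: float = 0.08
    r_background: float = 0.05
    nc_rate: float = 0.0043
    genotype_error_rate: float = 0.0
    null_genotype: str = "nc"  # "nc" or "random_hom" for -/- samples
    event_specs: list[CNVEventSpec] = field(default_factory=list)
    qpcr_base_ct: float = 25.0
    qpcr_base_ct_reference: float = 25.0
    qpcr_ct_noise_sd: float = 0.1
    qpcr_ct_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if self.steers_per_sire is not None:
            self.n_steers = self.n_sires * self.steers_per_sire
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.mean_spacing_bp <= 0:
            raise ValueError("mean_spacing_bp must be positive")
        if self.null_genotype not in ("nc", "random_hom"):
            raise ValueError("null_genotype must be 'nc' or 'random_hom'")

    @property
    def n_samples(self) -> int:
        return self.n_sires + self.n_steers

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["event_specs"] = [CNVEventSpec(**e) for e in raw.get("event_specs", [])]
        raw["allele_freq_range"] = tuple(raw["allele_freq_range"])
        raw["lrr_means"] = tuple(raw["lrr_means"])
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth: integer copy number per (sample, marker) and, per
    sample, the list of event intervals (chromosome, start, end, copy)."""

    copy: pd.DataFrame  # samples x markers, int
    events_by_sample: dict[str, list[tuple[int, int, int, int]]]

    def to_tsv(self, path) -> None:
        self.copy.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class GenotypeSimulation:
    """Genotype layer plus the latent quantities the intensity model needs."""

    genotype: pd.DataFrame  # samples x markers, str
    truth: TruthTable
    b_dosage: pd.DataFrame  # number of B alleles among surviving copies
    pedigree: list[PedigreePair]
    allele_freqs: np.ndarray  # per-marker B allele frequency


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    markers: MarkerMap
    table: IntensityTable
    pedigree: list[PedigreePair]
    truth: TruthTable
    b_dosage: pd.DataFrame
    allele_freqs: np.ndarray


def _markers_per_chromosome(n_markers: int, n_chromosomes: int) -> list[int]:
    base, extra = divmod(n_markers, n_chromosomes)
    return [base + (1 if c < extra else 0) for c in range(n_chromosomes)]


def simulate_marker_map(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> MarkerMap:
    """Draw marker positions with exponential inter-marker gaps.

    Exponential gaps are right-skewed, so the empirical median spacing
    falls below the configured mean, matching the real chip geometry.
    Raises if a chromosome cannot hold its markers within
    ``chromosome_length_bp``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = _markers_per_chromosome(config.n_markers, config.n_chromosomes)
    rows = []
    for chrom, n in enumerate(counts, start=1):
        if n == 0:
            continue
        gaps = rng.exponential(config.mean_spacing_bp, size=n)
        gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
        pos = np.cumsum(gaps)
        if pos[-1] > config.chromosome_length_bp:
            raise ValueError(
                f"chromosome {chrom} too short ({config.chromosome_length_bp} bp) "
                f"for {n} markers at mean spacing {config.mean_spacing_bp}"
            )
        for i, p in enumerate(pos):
            rows.append((f"SNP-{chrom:02d}-{i + 1:06d}", chrom, int(p)))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]))


def simulate_pedigree(config: SimulationConfig) -> list[PedigreePair]:
    """Deterministic sire/steer ids; steers assigned to sires round-robin."""
    sires = [f"SIRE{i + 1:03d}" for i in range(config.n_sires)]
    return [
        PedigreePair(sires[j % config.n_sires], f"STEER{j + 1:04d}")
        for j in range(config.n_steers)
    ]


def _event_marker_masks(
    events: Sequence[CNVEventSpec], markers: MarkerMap
) -> np.ndarray:
    """Boolean (n_events, n_markers): marker lies inside the event span."""
    chrom = markers.df["chromosome"].to_numpy()
    pos = markers.df["position"].to_numpy()
    masks = np.zeros((len(events), len(markers)), dtype=bool)
    for i, e in enumerate(events):
        masks[i] = (chrom == e.chromosome) & (pos >= e.start) & (pos <= e.end)
        if not masks[i].any():
            raise ValueError(
                f"event {e.chromosome}:{e.start}-{e.end} spans no marker"
            )
    return masks


def simulate_pedigree_genotypes(
    config: SimulationConfig,
    markers: MarkerMap,
    rng: np.random.Generator | None = None,
) -> GenotypeSimulation:
    """Draw genotypes for sires and steers under Hardy-Weinberg with
    haplotype-borne CNV alleles.

    Sires receive two population haplotypes; each steer inherits one sire
    haplotype (chosen once per chromosome, no recombination) plus one
    population (dam) haplotype. Deletion alleles erase the SNP allele on
    their haplotype, so hemizygotes are reported as the homozygote of the
    remaining allele and null (-/-) animals as NC (or a random homozygote,
    per ``null_genotype``). Duplication alleles double their haplotype's
    allele dosage.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pedigree = simulate_pedigree(config)
    n_sires, n_steers = config.n_sires, config.n_steers
    n_markers = len(markers)
    chrom_of_marker = markers.df["chromosome"].to_numpy()
    chrom_index = {c: i for i, c in enumerate(sorted(set(chrom_of_marker)))}
    marker_chrom_idx = np.array([chrom_index[c] for c in chrom_of_marker])

    lo, hi = config.allele_freq_range
    p = rng.uniform(lo, hi, size=n_markers)  # B allele frequency per marker

    # sire haplotype alleles: True = B
    sire_hap = rng.random((n_sires, 2, n_markers)) < p
    # event allele flags per sire haplotype
    events = config.event_specs
    n_events = len(events)
    masks = _event_marker_masks(events, markers) if n_events else np.zeros((0, n_markers), bool)
    freqs = np.array([e.population_frequency for e in events])
    sire_ev = rng.random((n_sires, 2, n_events)) < freqs if n_events else np.zeros((n_sires, 2, 0), bool)

    # steer transmitted sire-haplotype index, one draw per chromosome
    n_chrom = len(chrom_index)
    t = rng.integers(0, 2, size=(n_steers, n_chrom))
    sire_idx = np.array(
        [int(pair.sire_id.removeprefix("SIRE")) - 1 for pair in pedigree]
    )
    t_marker = t[:, marker_chrom_idx]  # (n_steers, n_markers)
    steer_pat = sire_hap[sire_idx[:, None], t_marker, np.arange(n_markers)[None, :]]
    steer_mat = rng.random((n_steers, n_markers)) < p
    if n_events:
        ev_chrom_idx = np.array([chrom_index[e.chromosome] for e in events])
        t_event = t[:, ev_chrom_idx]  # (n_steers, n_events)
        pat_ev_inh = sire_ev[sire_idx[:, None], t_event, np.arange(n_events)[None, :]]
        pat_ev_dn = rng.random((n_steers, n_events)) < freqs
        inherited = np.array([e.inherited for e in events])
        steer_pat_ev = np.where(inherited, pat_ev_inh, pat_ev_dn)
        steer_mat_ev = rng.random((n_steers, n_events)) < freqs
    else:
        steer_pat_ev = np.zeros((n_steers, 0), bool)
        steer_mat_ev = np.zeros((n_steers, 0), bool)

    # haplotype allele multiplicity per marker: 1 - deletions + duplications
    def hap_multiplicity(ev_flags: np.ndarray) -> np.ndarray:
        """ev_flags: (n_individuals, n_events) -> (n_individuals, n_markers)."""
        mult = np.ones((ev_flags.shape[0], n_markers), dtype=np.int8)
        for i, e in enumerate(events):
            sign = -1 if e.is_deletion else 1
            mult[:, masks[i]] += sign * ev_flags[:, i : i + 1].astype(np.int8)
        return np.clip(mult, 0, 2)

    sire_mult = np.stack(
        [hap_multiplicity(sire_ev[:, h, :]) for h in (0, 1)], axis=1
    )  # (n_sires, 2, n_markers)
    steer_pat_mult = hap_multiplicity(steer_pat_ev)
    steer_mat_mult = hap_multiplicity(steer_mat_ev)

    sire_copy = sire_mult.sum(axis=1)
    steer_copy = steer_pat_mult + steer_mat_mult
    sire_b = (sire_mult * sire_hap.astype(np.int8)).sum(axis=1)
    steer_b = steer_pat_mult * steer_pat.astype(np.int8) + steer_mat_mult * steer_mat.astype(np.int8)

    copy = np.vstack([sire_copy, steer_copy]).astype(np.int8)
    b_dose = np.vstack([sire_b, steer_b]).astype(np.int8)
    # truth copy number is reported in {0,1,2,3}; double-duplication
    # haplotype pairs (rare, ~f^2 of duplication carriers) are capped at 3
    over = copy > 3
    b_dose = np.where(over, np.minimum(b_dose, 3), b_dose)
    copy = np.where(over, 3, copy)

    samples = [f"SIRE{i + 1:03d}" for i in range(n_sires)] + [
        f"STEER{j + 1:04d}" for j in range(n_steers)
    ]

    gt = np.where(
        b_dose == 0, "AA", np.where(b_dose == copy, "BB", "AB")
    ).astype(object)
    null_mask = copy == 0
    if config.null_genotype == "nc":
        gt[null_mask] = "NC"
    else:
        rand_hom = np.where(rng.random(gt.shape) < 0.5, "AA", "BB")
        gt[null_mask] = rand_hom[null_mask]
    # array missingness
    nc_mask = rng.random(gt.shape) < config.nc_rate
    gt[nc_mask] = "NC"
    # genotyping error: replace a called genotype with a different call
    if config.genotype_error_rate > 0:
        err_mask = (rng.random(gt.shape) < config.genotype_error_rate) & (gt != "NC")
        shift = rng.integers(1, 3, size=gt.shape)
        order = np.array(["AA", "AB", "BB"])
        cur = np.searchsorted(order, gt.astype(str).ravel()).reshape(gt.shape)
        cur = np.clip(cur, 0, 2)
        gt = np.where(err_mask, order[(cur + shift) % 3], gt)

    marker_ids = markers.marker_ids
    copy_df = pd.DataFrame(copy, index=samples, columns=marker_ids)
    b_df = pd.DataFrame(b_dose, index=samples, columns=marker_ids)
    gt_df = pd.DataFrame(gt.astype(str), index=samples, columns=marker_ids)

    events_by_sample: dict[str, list[tuple[int, int, int, int]]] = {s: [] for s in samples}
    if n_events:
        sire_ev_count = sire_ev.sum(axis=1)  # (n_sires, n_events)
        steer_ev_count = steer_pat_ev.astype(int) + steer_mat_ev.astype(int)
        all_counts = np.vstack([sire_ev_count, steer_ev_count])
        for si, s in enumerate(samples):
            for ei, e in enumerate(events):
                k = int(all_counts[si, ei])
                if k:
                    delta = -k if e.is_deletion else k
                    events_by_sample[s].append(
                        (e.chromosome, e.start, e.end, max(0, min(3, 2 + delta)))
                    )

    truth = TruthTable(copy=copy_df, events_by_sample=events_by_sample)
    return GenotypeSimulation(
        genotype=gt_df,
        truth=truth,
        b_dosage=b_df,
        pedigree=pedigree,
        allele_freqs=p,
    )


def simulate_intensities(
    config: SimulationConfig,
    markers: MarkerMap,
    sim: GenotypeSimulation,
    rng: np.random.Generator | None = None,
) -> IntensityTable:
    """Emit LRR/BAF/R signal layers from the genotype truth.

    LRR ~ Normal(mu_state, lrr_noise_sd) with per-copy-state means from the
    config. BAF clusters at b_dosage/copy (so copy 2 gives {0, 1/2, 1},
    copy 1 gives {0, 1}, copy 3 gives {0, 1/3, 2/3, 1}); copy-0 samples have
    uniform BAF noise, since with no template the allelic ratio is
    meaningless. R scales with copy/2 so hemizygotes sit at reduced total
    intensity and null samples near the background floor.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    copy = sim.truth.copy.to_numpy(dtype=np.int8)
    b = sim.b_dosage.to_numpy(dtype=np.int8)
    mus = np.asarray(config.lrr_means, dtype=float)
    lrr = mus[copy] + rng.normal(0.0, config.lrr_noise_sd, size=copy.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf_mean = np.where(copy > 0, b / np.maximum(copy, 1), 0.0)
    baf = np.clip(baf_mean + rng.normal(0.0, config.baf_noise_sd, size=copy.shape), 0, 1)
    baf = np.where(copy == 0, rng.uniform(0, 1, size=copy.shape), baf)
    r_mean = np.where(copy > 0, config.r_base * copy / 2.0, config.r_background)
    r = np.maximum(0.01, r_mean + rng.normal(0.0, config.r_noise_sd, size=copy.shape))

    idx, cols = sim.truth.copy.index, sim.truth.copy.columns
    return IntensityTable(
        markers=markers,
        lrr=pd.DataFrame(lrr, index=idx, columns=cols),
        baf=pd.DataFrame(baf, index=idx, columns=cols),
        r_total=pd.DataFrame(r, index=idx, columns=cols),
        genotype=sim.genotype.copy(),
    )


def simulate_qpcr(
    truth: TruthTable,
    sample_ids: Sequence[str],
    marker_id: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[QPCRAssay]:
    """Simulate TaqMan CT triplicates for one marker across samples.

    CT of the target assay rises by one cycle per halving of template:
    CT = base_ct - log2(copy/2) + noise. The internal-control (BTF3-like)
    assay sits at its own base CT. Copy-0 samples do not amplify; their CT
    is set to the configured ceiling cycle exactly.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    assays = []
    for s in sample_ids:
        c = int(truth.copy.at[s, marker_id])
        if c == 0:
            ct_t = (config.qpcr_ct_ceiling,) * 3
        else:
            ct_t = tuple(
                config.qpcr_base_ct
                - np.log2(c / 2.0)
                + rng.normal(0.0, config.qpcr_ct_noise_sd)
                for _ in range(3)
            )
        ct_r = tuple(
            config.qpcr_base_ct_reference + rng.normal(0.0, config.qpcr_ct_noise_sd)
            for _ in range(3)
        )
        assays.append(QPCRAssay(s, marker_id, ct_t, ct_r))
    return assays


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator under one seed: map, pedigree genotypes,
    intensity layers. A fixed config+seed reproduces the dataset exactly."""
    rng = np.random.default_rng(config.seed)
    markers = simulate_marker_map(config, rng)
    sim = simulate_pedigree_genotypes(config, markers, rng)
    table = simulate_intensities(config, markers, sim, rng)
    return SimulatedDataset(
        config=config,
        markers=markers,
        table=table,
        pedigree=sim.pedigree,
        truth=sim.truth,
        b_dosage=sim.b_dosage,
        allele_freqs=sim.allele_freqs,
    )
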