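"""Readers, writers and sample-level QC for SNP-array intensity data.

Handles the tab-separated "Final Report" dialect exported by Illumina
genotyping software (one row per sample x marker carrying log R ratio,
B allele frequency, genotype call and optionally the total intensity R),
two-column sire/steer pedigree files, gene-annotation BED, and BED export
of genomic intervals.

Coordinates are stored 1-based internally, as printed on the array manifest;
interval lengths and overlaps treat ``(start, end)`` as half-open
(length = end - start), and BED export writes ``start - 1``/``end`` so the
end base stays covered on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB", "NC")
#: tokens in input files that mean "no call"
_NC_TOKENS = {"NC", "--", "", "nan", "NaN"}

FINAL_REPORT_COLUMNS = {
    "marker_id": "SNP Name",
    "sample_id": "Sample ID",
    "chromosome": "Chr",
    "position": "Position",
    "lrr": "Log R Ratio",
    "baf": "B Allele Freq",
    "genotype": "GType",
    "r_total": "R",
}


class FinalReportError(ValueError):
    """Raised when an intensity file violates the dialect or a value range."""


@dataclass(frozen=True)
class MarkerRecord:
    """A single array marker: identifier and genomic position (1-based bp)."""

    marker_id: str
    chromosome: int
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")
        if self.chromosome < 1:
            raise ValueError(f"marker {self.marker_id}: chromosome must be >= 1")


class MarkerMap:
    """Sorted collection of unique markers, the coordinate backbone.

    Wraps a DataFrame with columns ``marker_id``, ``chromosome``, ``position``
    sorted by (chromosome, position).
    """

    def __init__(self, records: pd.DataFrame | Iterable[MarkerRecord]):
        if isinstance(records, pd.DataFrame):
            df = records[["marker_id", "chromosome", "position"]].copy()
        else:
            df = pd.DataFrame(
                [(r.marker_id, r.chromosome, r.position) for r in records],
                columns=["marker_id", "chromosome", "position"],
            )
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id in map: {dup!r}")
        if len(df) and (df["position"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        df = df.sort_values(["chromosome", "position"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return self.df["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.df["chromosome"].unique().tolist())

    def chromosome_of(self) -> pd.Series:
        """Chromosome per marker, indexed by marker_id (map order)."""
        return self.df.set_index("marker_id")["chromosome"]

    def position_of(self) -> pd.Series:
        return self.df.set_index("marker_id")["position"]

    def markers_on(self, chromosome: int) -> pd.DataFrame:
        return self.df[self.df["chromosome"] == chromosome]

    def markers_in(self, chromosome: int, start: int, end: int) -> list[str]:
        """Marker ids with start <= position <= end on a chromosome."""
        sub = self.markers_on(chromosome)
        hit = sub[(sub["position"] >= start) & (sub["position"] <= end)]
        return hit["marker_id"].tolist()


@dataclass
class IntensityTable:
    """Per sample x marker LRR, BAF, total intensity R and genotype call.

    All four layers are DataFrames indexed by sample id with marker ids as
    columns, in marker-map order. Missing LRR/BAF/R are NaN; missing
    genotypes are ``"NC"``. Missing values are excluded from every statistic
    and never imputed.
    """

    markers: MarkerMap
    lrr: pd.DataFrame
    baf: pd.DataFrame
    r_total: pd.DataFrame
    genotype: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.markers.marker_ids
        for name in ("lrr", "baf", "r_total", "genotype"):
            layer = getattr(self, name)
            if list(layer.columns) != ids:
                raise ValueError(f"{name} columns do not match the marker map")
            if list(layer.index) != list(self.lrr.index):
                raise ValueError(f"{name} sample index inconsistent")
        baf = self.baf.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((baf < 0) | (baf > 1)):
                raise ValueError("BAF outside [0, 1]")
        r = self.r_total.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(r <= 0):
                raise ValueError("r_total must be positive or missing")
        bad = ~self.genotype.isin(GENOTYPES)
        if bad.to_numpy().any():
            raise ValueError("genotype layer contains tokens outside AA/AB/BB/NC")

    @property
    def samples(self) -> list[str]:
        return list(self.lrr.index)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class SampleQC:
    """Per-sample noise and completeness summary."""

    sample_id: str
    sd_lrr: float
    call_rate: float

    def __post_init__(self) -> None:
        if self.sd_lrr < 0:
            raise ValueError("sd_lrr must be non-negative")
        if not 0 <= self.call_rate <= 1:
            raise ValueError("call_rate must be in [0, 1]")


@dataclass(frozen=True)
class PedigreePair:
    """A sire (parent) / steer (offspring) duo."""

    sire_id: str
    steer_id: str

    def __post_init__(self) -> None:
        if self.sire_id == self.steer_id:
            raise ValueError("sire and steer must be distinct samples")


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in internal coordinates (half-open on 1-based start)."""

    gene_id: str
    chromosome: int
    start: int
    end: int


def _parse_chromosome(tokens: pd.Series, max_chromosome: int) -> pd.Series:
    as_num = pd.to_numeric(tokens, errors="coerce")
    bad = as_num.isna() | (as_num < 1) | (as_num > max_chromosome) | (as_num % 1 != 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FinalReportError(
            f"line {line}: unknown chromosome token {tokens[bad.idxmax()]!r}"
        )
    return as_num.astype(int)


def _parse_float(tokens: pd.Series, name: str) -> pd.Series:
    stripped = tokens.fillna("").astype(str).str.strip()
    missing = stripped.isin(_NC_TOKENS)
    out = pd.to_numeric(stripped.where(~missing, other=np.nan), errors="coerce")
    bad = out.isna() & ~missing
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FinalReportError(
            f"line {line}: malformed {name} value {tokens[bad.idxmax()]!r}"
        )
    return out


def read_final_report(path, max_chromosome: int = 29) -> IntensityTable:
    """Read a Final-Report-like TSV into an :class:`IntensityTable`.

    The header must name ``SNP Name``, ``Sample ID``, ``Chr``, ``Position``,
    ``Log R Ratio``, ``B Allele Freq`` and ``GType``; the total-intensity
    column ``R`` is optional (missing -> all-NaN layer). Malformed rows raise
    :class:`FinalReportError` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [v for k, v in FINAL_REPORT_COLUMNS.items() if k != "r_total"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FinalReportError(f"missing required columns: {missing_cols}")
    df = df.reset_index(drop=True)

    chrom = _parse_chromosome(df["Chr"], max_chromosome)
    pos = pd.to_numeric(df["Position"], errors="coerce")
    if pos.isna().any() or (pos < 1).any():
        line = int((pos.isna() | (pos < 1)).idxmax()) + 2
        raise FinalReportError(f"line {line}: malformed position")
    lrr = _parse_float(df["Log R Ratio"], "Log R Ratio")
    baf = _parse_float(df["B Allele Freq"], "B Allele Freq")
    out_of_range = baf.notna() & ((baf < 0) | (baf > 1))
    if out_of_range.any():
        line = int(out_of_range.idxmax()) + 2
        raise FinalReportError(f"line {line}: B Allele Freq outside [0, 1]")
    if "R" in df.columns:
        r = _parse_float(df["R"], "R")
        if (r.notna() & (r <= 0)).any():
            line = int((r.notna() & (r <= 0)).idxmax()) + 2
            raise FinalReportError(f"line {line}: R must be positive")
    else:
        r = pd.Series(np.nan, index=df.index)
    gt = df["GType"].fillna("NC").astype(str).str.strip()
    gt = gt.where(~gt.isin(_NC_TOKENS), other="NC")
    bad_gt = ~gt.isin(GENOTYPES)
    if bad_gt.any():
        line = int(bad_gt.idxmax()) + 2
        raise FinalReportError(f"line {line}: unknown genotype {gt[bad_gt.idxmax()]!r}")

    long = pd.DataFrame(
        {
            "marker_id": df["SNP Name"],
            "sample_id": df["Sample ID"],
            "chromosome": chrom,
            "position": pos.astype(int),
            "lrr": lrr,
            "baf": baf,
            "r_total": r,
            "genotype": gt,
        }
    )
    mk = long.drop_duplicates("marker_id")[["marker_id", "chromosome", "position"]]
    conflict = long.groupby("marker_id")[["chromosome", "position"]].nunique()
    if (conflict > 1).any().any():
        raise FinalReportError("marker mapped to conflicting positions")
    marker_map = MarkerMap(mk)
    return _pivot_long(long, marker_map)


def _pivot_long(long: pd.DataFrame, marker_map: MarkerMap) -> IntensityTable:
    samples = long["sample_id"].drop_duplicates().tolist()
    ids = marker_map.marker_ids
    layers = {}
    for name in ("lrr", "baf", "r_total", "genotype"):
        wide = long.pivot(index="sample_id", columns="marker_id", values=name)
        wide = wide.reindex(index=samples, columns=ids)
        if name == "genotype":
            wide = wide.fillna("NC").astype(str)
        else:
            wide = wide.astype(float)
        wide.columns.name = None
        wide.index.name = None
        layers[name] = wide
    return IntensityTable(markers=marker_map, **layers)


def write_final_report(table: IntensityTable, path) -> None:
    """Write an :class:`IntensityTable` back to the Final-Report TSV dialect.

    Floats are printed with 4 decimals, which is the round-trip precision.
    """
    chrom = table.markers.chromosome_of()
    pos = table.markers.position_of()
    rows = []
    for sample in table.samples:
        for marker in table.markers.marker_ids:
            lrr = table.lrr.at[sample, marker]
            baf = table.baf.at[sample, marker]
            r = table.r_total.at[sample, marker]
            rows.append(
                (
                    marker,
                    sample,
                    chrom[marker],
                    pos[marker],
                    "" if math.isnan(lrr) else f"{lrr:.4f}",
                    "" if math.isnan(baf) else f"{baf:.4f}",
                    table.genotype.at[sample, marker],
                    "" if math.isnan(r) else f"{r:.4f}",
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "SNP Name",
            "Sample ID",
            "Chr",
            "Position",
            "Log R Ratio",
            "B Allele Freq",
            "GType",
            "R",
        ],
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def compute_sample_qc(table: IntensityTable) -> list[SampleQC]:
    """Per-sample LRR noise (population SD over non-missing values) and
    genotype call rate (called / total markers)."""
    if not table.samples:
        raise ValueError("empty intensity table")
    lrr = table.lrr.to_numpy(dtype=float)
    called = (table.genotype != "NC").to_numpy()
    out = []
    for i, sample in enumerate(table.samples):
        vals = lrr[i][~np.isnan(lrr[i])]
        if vals.size == 0:
            raise ValueError(f"sample {sample!r} has no non-missing LRR values")
        out.append(
            SampleQC(
                sample_id=sample,
                sd_lrr=float(np.std(vals)),  # population SD (divide by n)
                call_rate=float(called[i].mean()),
            )
        )
    return out


def filter_samples(qc: Sequence[SampleQC], sd_threshold: float = 0.30) -> list[str]:
    """Samples with sd_lrr strictly below the threshold (default < 0.30)."""
    if not qc:
        raise ValueError("empty QC list")
    return [q.sample_id for q in qc if q.sd_lrr < sd_threshold]


def read_pedigree(path) -> list[PedigreePair]:
    """Read a two-column sire<TAB>steer TSV; each steer may appear once."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 2:
        raise ValueError("pedigree file must have two tab-separated columns")
    pairs = [PedigreePair(str(s), str(t)) for s, t in zip(df[0], df[1])]
    steers = [p.steer_id for p in pairs]
    if len(set(steers)) != len(steers):
        dup = next(s for i, s in enumerate(steers) if s in steers[:i])
        raise ValueError(f"steer {dup!r} appears in more than one pair")
    return pairs


def write_pedigree(pairs: Iterable[PedigreePair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.sire_id}\t{p.steer_id}\n")


def write_bed(intervals: Iterable, path) -> None:
    """Write intervals as BED (0-based half-open).

    Accepts any objects with ``chromosome``, ``start``, ``end`` attributes
    (1-based internal coordinates) or ``(chromosome, start, end[, name])``
    tuples. Internal [101, 200] becomes the BED line ``chr1 100 200``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            if isinstance(iv, tuple):
                chrom, start, end = iv[0], iv[1], iv[2]
                name = iv[3] if len(iv) > 3 else "."
            else:
                chrom, start, end = iv.chromosome, iv.start, iv.end
                name = getattr(iv, "sample_id", None) or "."
            fh.write(f"chr{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_gene_bed(path) -> list[GeneInterval]:
    """Read gene annotation intervals from BED (chrom start end name).

    BED's 0-based half-open (s0, e0) becomes internal (s0 + 1, e0 + 1) so
    half-open comparisons on internal coordinates cover the same bases.
    """
    genes: list[GeneInterval] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = int(parts[0].removeprefix("chr"))
            s0, e0 = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{s0}-{e0}"
            genes.append(GeneInterval(name, chrom, s0 + 1, e0 + 1))
    return genes
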