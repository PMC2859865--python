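"""Per-sample CNV segmentation from LRR/BAF signals.

A four-state hidden Markov model over copy numbers {0, 1, 2, 3} is decoded
per sample per chromosome by Viterbi. Emissions combine a Gaussian
log R ratio term (per-state means, shared SD) with a B-allele-frequency
mixture whose cluster positions follow the allelic geometry of each copy
state: diploid {0, 1/2, 1}, hemizygous {0, 1} (the heterozygote cluster
disappears under deletion), triploid {0, 1/3, 2/3, 1}, and uniform BAF for
copy 0. Transition probabilities depend on the physical gap between
adjacent markers: the probability of switching state decays as
``exp(-gap/d0)``. Maximal runs of non-diploid states with at least
``min_markers`` markers become calls.

This is a deliberately simple, fully documented caller in the tradition of
PennCNV-style segmentation; it does not reproduce any trained parameter
set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .array_io import IntensityTable, MarkerMap

STATES = (0, 1, 2, 3)  # copy numbers; index == copy number here
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class CNVCall:
    """One per-sample copy-number event bounded by marker positions."""

    sample_id: str
    chromosome: int
    start: int
    end: int
    copy_state: int
    n_markers: int
    mean_lrr: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("call end must be >= start")
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError("copy_state of a call must be 0, 1, 3 or 4 (never 2)")
        if self.n_markers < 1:
            raise ValueError("a call must span at least one marker")

    @property
    def is_loss(self) -> bool:
        return self.copy_state < 2


@dataclass
class CallerParams:
    """Emission and transition parameters of the segmentation HMM.

    ``lrr_means`` are the per-copy-state LRR cluster centres; ``pfb`` is the
    population frequency of the B allele used to weight BAF clusters
    (cohort-level estimation is out of scope; a flat 0.5 is the default).
    ``p_enter_cnv`` is the per-step probability of leaving the diploid
    state at zero gap, ``p_stay_cnv`` the zero-gap persistence of a CNV
    state; both decay with the inter-marker gap as exp(-gap/transition_decay_bp).
    """

    lrr_means: tuple[float, float, float, float] = (-3.0, -0.66, 0.0, 0.40)
    lrr_sd: float = 0.20
    baf_sd: float = 0.05
    pfb: float = 0.5
    p_enter_cnv: float = 0.01
    p_stay_cnv: float = 0.95
    p_cnv_to_cnv: float = 0.01
    transition_decay_bp: float = 500_000.0
    min_markers: int = 3

    def baf_clusters(self, state: int) -> tuple[np.ndarray, np.ndarray]:
        """(cluster means, HWE weights) of the BAF mixture for a state."""
        p = self.pfb
        q = 1.0 - p
        if state == 1:
            return np.array([0.0, 1.0]), np.array([q, p])
        if state == 2:
            return np.array([0.0, 0.5, 1.0]), np.array([q * q, 2 * p * q, p * p])
        if state == 3:
            return (
                np.array([0.0, 1 / 3, 2 / 3, 1.0]),
                np.array([q**3, 3 * p * q * q, 3 * p * p * q, p**3]),
            )
        raise ValueError(f"unknown copy state {state}")


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI


def log_emissions(
    lrr: np.ndarray, baf: np.ndarray, params: CallerParams
) -> np.ndarray:
    """Per-marker log emission likelihood, shape (n_markers, 4).

    Missing LRR or BAF contribute zero log likelihood (uninformative).
    Copy state 0 has no allelic signal: its BAF term is the uniform density
    on [0, 1] (log 1 = 0).
    """
    n = lrr.shape[0]
    out = np.zeros((n, len(STATES)))
    lrr_ok = ~np.isnan(lrr)
    baf_ok = ~np.isnan(baf)
    for s in STATES:
        le = np.zeros(n)
        le[lrr_ok] = _norm_logpdf(lrr[lrr_ok], params.lrr_means[s], params.lrr_sd)
        be = np.zeros(n)
        if s != 0:
            mus, ws = params.baf_clusters(s)
            dens = np.zeros(baf_ok.sum())
            b = baf[baf_ok]
            for mu, w in zip(mus, ws):
                dens += w * np.exp(_norm_logpdf(b, mu, params.baf_sd))
            be[baf_ok] = np.log(np.maximum(dens, 1e-300))
        out[:, s] = le + be
    return out


def log_transition_matrix(gap_bp: float, params: CallerParams) -> np.ndarray:
    """Log transition matrix for one inter-marker step of ``gap_bp``."""
    decay = math.exp(-gap_bp / params.transition_decay_bp)
    leave2 = params.p_enter_cnv * decay
    stay_cnv = params.p_stay_cnv * decay
    mat = np.empty((4, 4))
    for s in STATES:
        if s == 2:
            mat[s] = leave2 / 3.0
            mat[s, 2] = 1.0 - leave2
        else:
            others = [t for t in STATES if t not in (s, 2)]
            mat[s] = 0.0
            mat[s, s] = stay_cnv
            mat[s, 2] = (1.0 - stay_cnv) * (1.0 - params.p_cnv_to_cnv)
            for t in others:
                mat[s, t] = (1.0 - stay_cnv) * params.p_cnv_to_cnv / 2.0
    return np.log(mat)


def log_initial(params: CallerParams) -> np.ndarray:
    pi = np.full(4, params.p_enter_cnv / 3.0)
    pi[2] = 1.0 - params.p_enter_cnv
    return np.log(pi)


def viterbi_path(
    log_emis: np.ndarray, log_trans: list[np.ndarray], log_pi: np.ndarray
) -> np.ndarray:
    """Most likely state sequence; exact log-likelihood ties resolve to the
    lowest copy state (argmax returns the first maximiser)."""
    n, k = log_emis.shape
    delta = log_pi + log_emis[0]
    back = np.zeros((n, k), dtype=np.int8)
    for i in range(1, n):
        scores = delta[:, None] + log_trans[i - 1]  # (from, to)
        back[i] = np.argmax(scores, axis=0)
        delta = scores[back[i], np.arange(k)] + log_emis[i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1][path[i + 1]]
    return path


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (state, start_index, end_index inclusive)."""
    runs = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            runs.append((int(path[start]), start, i - 1))
            start = i
    return runs


def call_cnvs(
    table: IntensityTable,
    markers: MarkerMap | None = None,
    params: CallerParams | None = None,
    samples: list[str] | None = None,
) -> list[CNVCall]:
    """Segment every sample chromosome-by-chromosome and emit CNV calls.

    Call boundaries are the first and last marker positions of the
    non-diploid run; a call never spans a chromosome boundary because each
    chromosome is decoded independently.
    """
    markers = table.markers if markers is None else markers
    params = params or CallerParams()
    calls: list[CNVCall] = []
    lrr_all = table.lrr
    baf_all = table.baf
    log_pi = log_initial(params)
    for chrom in markers.chromosomes:
        sub = markers.markers_on(chrom)
        pos = sub["position"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"marker map unsorted on chromosome {chrom}")
        ids = sub["marker_id"].tolist()
        trans = [log_transition_matrix(float(g), params) for g in np.diff(pos)]
        lrr_c = lrr_all[ids].to_numpy(dtype=float)
        baf_c = baf_all[ids].to_numpy(dtype=float)
        for si, sample in enumerate(table.samples):
            if samples is not None and sample not in samples:
                continue
            emis = log_emissions(lrr_c[si], baf_c[si], params)
            path = viterbi_path(emis, trans, log_pi)
            for state, a, b in _runs(path):
                if state == 2 or (b - a + 1) < params.min_markers:
                    continue
                seg_lrr = lrr_c[si, a : b + 1]
                mean_lrr = float(np.nanmean(seg_lrr)) if np.any(~np.isnan(seg_lrr)) else float("nan")
                calls.append(
                    CNVCall(
                        sample_id=sample,
                        chromosome=chrom,
                        start=int(pos[a]),
                        end=int(pos[b]),
                        copy_state=state,
                        n_markers=b - a + 1,
                        mean_lrr=mean_lrr,
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.chromosome, c.start))
    return calls


def _overlaps(a: CNVCall, b: CNVCall) -> bool:
    # half-open comparison, consistent with the end - start length convention
    return a.chromosome == b.chromosome and a.start < b.end and b.start < a.end


def compare_callsets(a: list[CNVCall], b: list[CNVCall]) -> float:
    """Fraction of calls in ``a`` overlapping (same sample, same chromosome,
    >= 1 bp) any call in ``b``. Used to reproduce cross-caller concordance
    checks. Empty ``a`` yields 0.0."""
    if not a:
        return 0.0
    by_key: dict[tuple[str, int], list[CNVCall]] = {}
    for call in b:
        by_key.setdefault((call.sample_id, call.chromosome), []).append(call)
    hit = 0
    for call in a:
        candidates = by_key.get((call.sample_id, call.chromosome), [])
        if any(_overlaps(call, other) for other in candidates):
            hit += 1
    return hit / len(a)


def filter_calls(
    calls: list[CNVCall], min_markers: int = 0, min_length_bp: int = 0
) -> list[CNVCall]:
    """Retain calls meeting both minima (marker support and bp length),
    preserving input order."""
    if min_markers < 0 or min_length_bp < 0:
        raise ValueError("minima must be non-negative")
    return [
        c
        for c in calls
        if c.n_markers >= min_markers and (c.end - c.start) >= min_length_bp
    ]


def write_calls_tsv(calls: list[CNVCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tchromosome\tstart\tend\tcopy_state\tn_markers\tmean_lrr\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chromosome}\t{c.start}\t{c.end}\t"
                f"{c.copy_state}\t{c.n_markers}\t{c.mean_lrr:.4f}\n"
            )
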