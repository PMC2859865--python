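"""Comparative-CT (delta-delta-CT) copy-number quantification.

TaqMan assays co-amplify the target locus with an internal-control gene
(BTF3) in triplicate. Per replicate, delta CT = CT_target - CT_control;
the three deltas are averaged. Against a designated two-copy calibrator
sample, delta-delta CT = delta CT_sample - delta CT_calibrator, and the
copy number is 2 x 2^(-delta-delta CT): one extra cycle means half the
template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass(frozen=True)
class QPCRAssay:
    """CT triplicates for one sample at one marker plus internal control."""

    sample_id: str
    marker_id: str
    ct_target: tuple[float, float, float]
    ct_reference: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, reps in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if len(reps) != 3:
                raise ValueError(f"{name} needs exactly three replicates")
            if any(v is None or math.isnan(v) for v in reps):
                raise ValueError(f"{name} has a missing replicate")
            if any(v <= 0 for v in reps):
                raise ValueError(f"{name} values must be positive cycles")


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    copy_number: float

    @property
    def rounded_copy(self) -> int:
        # round-half-up so the x.5 boundary goes to the higher copy class
        return int(math.floor(self.copy_number + 0.5))


def delta_ct(assay: QPCRAssay) -> float:
    """Mean over replicates of (target CT - control CT).

    Averaging per-replicate deltas equals the delta of the averaged CTs for
    equal replicate counts; the per-replicate form is used for clarity.
    """
    return sum(t - r for t, r in zip(assay.ct_target, assay.ct_reference)) / 3.0


def copy_number(
    delta_ct_sample: float, delta_ct_calibrator: float, sample_id: str = ""
) -> CopyNumberEstimate:
    """Copy number relative to a two-copy calibrator: 2 x 2^(-ddCT)."""
    ddct = delta_ct_sample - delta_ct_calibrator
    return CopyNumberEstimate(
        sample_id=sample_id,
        delta_ct=delta_ct_sample,
        delta_delta_ct=ddct,
        copy_number=2.0 * 2.0 ** (-ddct),
    )


def estimate_copy_numbers(
    assays: Sequence[QPCRAssay], calibrator_sample: str
) -> list[CopyNumberEstimate]:
    """Run the comparative-CT method for a batch of assays at one marker.

    The calibrator must be present among the assays and is assumed to carry
    two copies; its own estimate is exactly 2.0 by construction.
    """
    dcts = {a.sample_id: delta_ct(a) for a in assays}
    if calibrator_sample not in dcts:
        raise ValueError(f"calibrator {calibrator_sample!r} not among the assays")
    cal = dcts[calibrator_sample]
    return [copy_number(d, cal, sample_id=s) for s, d in dcts.items()]


def concordance_with_expected(
    estimates: Sequence[CopyNumberEstimate], expected: Mapping[str, int]
) -> float:
    """Fraction of samples whose rounded copy number matches the expected
    copy class (from genoplot inspection or simulation truth)."""
    shared = [e for e in estimates if e.sample_id in expected]
    if not shared:
        raise ValueError("no samples shared between estimates and expected classes")
    hits = sum(e.rounded_copy == expected[e.sample_id] for e in shared)
    return hits / len(shared)


def write_estimates_tsv(estimates: Sequence[CopyNumberEstimate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tdelta_ct\tdelta_delta_ct\tcopy_number\trounded_copy\n")
        for e in estimates:
            fh.write(
                f"{e.sample_id}\t{e.delta_ct:.4f}\t{e.delta_delta_ct:.4f}\t"
                f"{e.copy_number:.4f}\t{e.rounded_copy}\n"
            )
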