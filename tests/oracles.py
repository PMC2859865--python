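"""Independent oracles used to cross-check the implementation.

Each oracle takes a route deliberately different from the library code:
exhaustive enumeration over all HMM state sequences, an O(n^2)
transitive-closure interval merger, and a closed-form enumeration of
sire/dam haplotype combinations for the Mendelian-error frequency.
"""

from __future__ import annotations

import itertools

import numpy as np


def exhaustive_viterbi(
    log_emis: np.ndarray, log_trans: list[np.ndarray], log_pi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Best state sequence by scoring all k^n sequences (vectorised).

    Sequences are encoded base-k with the first state in the most
    significant digit; ties resolve to the smallest encoded sequence, i.e.
    lexicographically lowest states.
    """
    n, k = log_emis.shape
    scores = log_pi + log_emis[0]  # shape (k,)
    for i in range(1, n):
        # last state of each partial sequence is its lowest base-k digit
        last = np.arange(scores.shape[0]) % k
        scores = (scores[:, None] + log_trans[i - 1][last] + log_emis[i]).ravel()
    best = int(np.argmax(scores))
    path = np.empty(n, dtype=np.int8)
    for i in range(n - 1, -1, -1):
        path[i] = best % k
        best //= k
    return path, float(np.max(scores))


def brute_force_union(
    intervals: list[tuple[int, int, int]],
) -> list[tuple[int, int, int, int]]:
    """Transitive closure of pairwise half-open overlap, O(n^2).

    ``intervals`` are (chromosome, start, end); returns merged spans
    (chromosome, start, end, n_members) sorted by (chromosome, start).
    """
    groups: list[set[int]] = [{i} for i in range(len(intervals))]

    def overlaps(a, b):
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            gi, gj = groups[i], groups[j]
            if any(
                overlaps(intervals[a], intervals[b]) for a in gi for b in gj
            ):
                groups[i] = gi | gj
                del groups[j]
                changed = True
                break
    out = []
    for g in groups:
        members = [intervals[i] for i in g]
        out.append(
            (
                members[0][0],
                min(m[1] for m in members),
                max(m[2] for m in members),
                len(members),
            )
        )
    return sorted(out)


def expected_pc_error_freq(
    p_b: float, f_del: float, null_genotype: str = "nc"
) -> float:
    """Expected P-C error frequency among informative duos at a marker
    inside a deletion segregating at frequency ``f_del``.

    Enumerates every combination of the sire's two haplotypes, the
    transmitted haplotype choice, and the dam haplotype (allele x deletion
    status each), applying the same reporting rule as the generator:
    surviving-allele homozygote for hemizygotes, NC (or random homozygote)
    for null genotypes. Returns P(opposite homozygotes | both called).
    """
    alleles = [("A", 1 - p_b), ("B", p_b)]
    dels = [(False, 1 - f_del), (True, f_del)]
    haps = [
        ((a, d), pa * pd_) for a, pa in alleles for d, pd_ in dels
    ]

    def report(hs):
        surviving = [a for (a, d) in hs if not d]
        if len(surviving) == 2:
            x, y = sorted(surviving)
            return x + y
        if len(surviving) == 1:
            return surviving[0] * 2
        return None if null_genotype == "nc" else "null_hom"

    p_err = p_inf = 0.0
    for (h1, p1), (h2, p2) in itertools.product(haps, haps):
        sire_gt = report([h1, h2])
        for t, pt in ((h1, 0.5), (h2, 0.5)):
            for hd, pd_ in haps:
                prob = p1 * p2 * pt * pd_
                steer_gt = report([t, hd])
                weight_err = 0.0
                weight_inf = 0.0
                for sg, ps in _expand(sire_gt):
                    for tg, ptg in _expand(steer_gt):
                        if sg is None or tg is None:
                            continue
                        weight_inf += ps * ptg
                        if {sg, tg} == {"AA", "BB"}:
                            weight_err += ps * ptg
                p_err += prob * weight_err
                p_inf += prob * weight_inf
    return p_err / p_inf if p_inf > 0 else float("nan")


def _expand(gt):
    """Resolve the random-homozygote reporting of null genotypes."""
    if gt == "null_hom":
        return [("AA", 0.5), ("BB", 0.5)]
    return [(gt, 1.0)]
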