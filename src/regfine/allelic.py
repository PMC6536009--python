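"""Allele-aware regulatory annotation.

Binding-affinity comparison between the two alleles of a SNP follows the
affinity-p-value convention: a motif's match to a sequence window is scored
additively with log-likelihood ratios log((p_ij + c) / bg_j), the best score
over all windows covering the SNP (both strands) is converted to the
probability that a random background sequence scores at least as high, and
the allelic fold-change is the ratio of the two alleles' affinity p-values.

The background score distribution is exact for a lattice score model: each
position's four scores are rounded to an integer grid at a configurable
resolution (default 1e-3 log-likelihood units) and the distribution of
their sum is built by dynamic programming (discrete convolution across
positions). The observed best score lives on the same grid, so the reported
tail probability is exact for the binned score.

Also here: the >= fold-change filter used to shortlist affected TF binding
sites, enhancer-interval collocation counting, and the exact-binomial
allele-specific-binding test on allele-resolved read counts.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    ASBObservation,
    ASBResult,
    AllelicMotifHit,
    COMPLEMENT,
    PWM,
)

__all__ = [
    "score_distribution",
    "affinity_p_value",
    "scan_allelic_pwm",
    "fold_change_filter",
    "enhancer_overlap",
    "asb_test",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_RESOLUTION = 1e-3
DEFAULT_PSEUDOCOUNT = 0.01


def _int_score_matrix(pwm: PWM, pseudocount: float,
                      resolution: float) -> np.ndarray:
    """Per-position integer lattice scores, shape (L, 4)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if np.any(pwm.background <= 0):
        raise ValueError("background frequencies must be positive")
    s = np.log(pwm.probs + pseudocount) - np.log(pwm.background)[None, :]
    return np.rint(s / resolution).astype(np.int64)


def score_distribution(
    pwm: PWM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    resolution: float = DEFAULT_RESOLUTION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact lattice-score distribution under the background model.

    Returns ``(K, support, pmf)``: the (L, 4) integer score matrix, the
    integer support of the total score, and its probability mass function.
    """
    K = _int_score_matrix(pwm, pseudocount, resolution)
    lo = int(K.min(axis=1).sum())
    hi = int(K.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # DP over positions: start from the all-mass-at-zero distribution,
    # offset tracks the minimum achievable partial sum.
    cur = np.array([1.0])
    offset = 0
    for i in range(pwm.length):
        row = K[i]
        rlo, rhi = int(row.min()), int(row.max())
        nxt = np.zeros(len(cur) + rhi - rlo)
        for j in range(4):
            shift = int(row[j]) - rlo
            nxt[shift:shift + len(cur)] += pwm.background[j] * cur
        cur = nxt
        offset += rlo
    pmf[offset - lo: offset - lo + len(cur)] = cur
    support = np.arange(lo, hi + 1)
    return K, support, pmf


def affinity_p_value(support: np.ndarray, pmf: np.ndarray, k: int) -> float:
    """P(lattice score >= k) under the background distribution."""
    tail = pmf[support >= k].sum()
    return float(min(max(tail, 0.0), 1.0))


def _best_window_score(
    K: np.ndarray, seq: str, snp_pos: int
) -> tuple[int, int, str]:
    """Best lattice score over all windows covering ``snp_pos``, both strands.

    Returns (score, window offset, strand).
    """
    L = K.shape[0]
    n = len(seq)
    base_idx = [_BASE_INDEX[b] for b in seq]
    best = None
    for o in range(max(0, snp_pos - L + 1), min(n - L, snp_pos) + 1):
        fwd = int(sum(K[i, base_idx[o + i]] for i in range(L)))
        # reverse strand: motif read 3'->5' on the complement
        rev = int(sum(K[i, 3 - base_idx[o + L - 1 - i]] for i in range(L)))
        for score, strand in ((fwd, "+"), (rev, "-")):
            if best is None or score > best[0]:
                best = (score, o, strand)
    if best is None:
        raise ValueError(
            "no motif window covers the SNP (flank shorter than the motif?)"
        )
    return best


def scan_allelic_pwm(
    pwm: PWM,
    flank: str,
    snp_pos: int,
    allele_a: str,
    allele_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    resolution: float = DEFAULT_RESOLUTION,
    snp_id: str = "",
) -> AllelicMotifHit:
    """Compare a motif's binding affinity between two alleles of a SNP.

    ``flank`` is the surrounding sequence with the SNP at 0-based index
    ``snp_pos``; each allele is substituted in turn, every motif window
    covering the SNP is scored on both strands, and the best score becomes
    an affinity p-value against the exact background score distribution.
    The fold-change is the larger p over the smaller.
    """
    flank = flank.upper()
    allele_a, allele_b = allele_a.upper(), allele_b.upper()
    if allele_a == allele_b:
        raise ValueError("alleles must differ")
    for al in (allele_a, allele_b):
        if al not in _BASE_INDEX:
            raise ValueError(f"allele {al!r} is not a single base")
    if not (0 <= snp_pos < len(flank)):
        raise ValueError("snp_pos outside the flank")
    if pwm.length > len(flank):
        raise ValueError("flank shorter than the motif")
    if any(b not in _BASE_INDEX for b in flank):
        raise ValueError("flank contains non-ACGT characters")

    K, support, pmf = score_distribution(pwm, pseudocount, resolution)
    results = []
    for allele in (allele_a, allele_b):
        seq = flank[:snp_pos] + allele + flank[snp_pos + 1:]
        score, offset, strand = _best_window_score(K, seq, snp_pos)
        results.append((affinity_p_value(support, pmf, score), offset, strand))
    (p_a, off_a, str_a), (p_b, off_b, str_b) = results
    fold = max(p_a, p_b) / min(p_a, p_b)
    return AllelicMotifHit(
        snp_id=snp_id, motif_id=pwm.motif_id,
        allele1=allele_a, allele2=allele_b,
        p_allele1=p_a, p_allele2=p_b,
        best_offset1=off_a, best_strand1=str_a,
        best_offset2=off_b, best_strand2=str_b,
        fold_change=fold,
        favored_allele=allele_a if p_a <= p_b else allele_b,
    )


def fold_change_filter(
    hits: Sequence[AllelicMotifHit],
    min_fold: float = 5.0,
) -> list[AllelicMotifHit]:
    """Hits whose allelic affinity fold-change is at least ``min_fold``,
    sorted by descending fold-change."""
    kept = [h for h in hits if h.fold_change >= min_fold]
    kept.sort(key=lambda h: (-h.fold_change, h.motif_id, h.snp_id))
    return kept


def enhancer_overlap(
    pos: int,
    interval_sets: Mapping[str, Sequence[tuple[str, int, int]]],
    chrom: Optional[str] = None,
) -> int:
    """Number of cell types whose intervals contain a 1-based position.

    Intervals are BED-convention (0-based, half-open); the position is
    converted to 0-based before the containment test, so a position equal
    to an interval's end coordinate is outside it.
    """
    pos0 = pos - 1
    count = 0
    for intervals in interval_sets.values():
        for c, start, end in intervals:
            if chrom is not None and c != chrom:
                continue
            if start <= pos0 < end:
                count += 1
                break
    return count


def _binom_p(k: int, n: int, _cache={}) -> float:
    """Two-sided exact binomial p against 0.5 (memoized; n+1 distinct values
    per depth makes large calibration runs cheap)."""
    key = (min(k, n - k), n)
    p = _cache.get(key)
    if p is None:
        p = stats.binomtest(key[0], n, 0.5).pvalue
        _cache[key] = p
    return float(min(p, 1.0))


def asb_test(
    observations: Sequence[ASBObservation],
    adjust: str = "bh",
) -> list[ASBResult]:
    """Test each observation's allelic imbalance against a 50:50 binomial.

    The alternate-allele fraction is tested two-sided against 0.5 with the
    exact binomial test; ``adjust`` ("bh", "bonferroni", "none") corrects
    across the testable observations of this call. Observations with zero
    total reads are flagged untestable and excluded from the family.
    """
    if adjust not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    results = []
    testable_idx = []
    for i, obs in enumerate(observations):
        if obs.total == 0:
            results.append(ASBResult(observation=obs, imbalance=float("nan"),
                                     p_binom=float("nan"), p_adj=float("nan"),
                                     testable=False))
            continue
        p = _binom_p(obs.alt_count, obs.total)
        results.append(ASBResult(observation=obs,
                                 imbalance=obs.alt_count / obs.total,
                                 p_binom=p, p_adj=p))
        testable_idx.append(i)
    if adjust != "none" and testable_idx:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        raw = [results[i].p_binom for i in testable_idx]
        _, adj, _, _ = multipletests(raw, method=method)
        for i, pa in zip(testable_idx, adj):
            results[i].p_adj = float(min(pa, 1.0))
    return results
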