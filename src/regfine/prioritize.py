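"""Weighted functional-annotation scoring and LD decomposition of signals.

The priority score integrates two composite regulatory scores and six
feature annotations per SNP:

* 3dSNP weight: over the candidate set's raw 3dSNP scores, a SNP scores 2
  if more than two standard deviations above the mean, 1 if above the mean,
  0 otherwise (population SD: both conventions agree on the packaged table;
  population is kept for determinism).
* RegulomeDB weight: the ordinal category's numeric prefix n (1 strongest
  evidence .. 7 none) maps to weight 7 - n, so "3a" -> 4 and "7" -> 0.
* The eQTL, enhancer, rSNP, promoter-capture Hi-C, TFBS and ASE/ASB columns
  are added at face value (count-valued features contribute their counts;
  a capped 0/1-per-feature variant is available via ``cap_features``).

The total is the plain sum; candidates at or above the nomination threshold
(default 10) are put forward for experimental validation.

``clump`` decomposes significant SNPs into independent signals by greedy
LD clumping: repeatedly take the most significant unassigned SNP as index
and absorb every unassigned SNP correlated with it at r^2 >= threshold.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np

from .models import AnnotationRecord, Clump, LDMatrix, MetaResult, PriorityScore

__all__ = [
    "weight_3d",
    "weight_regdb",
    "total_score",
    "score_table",
    "nominate",
    "clump",
]

NOMINATION_THRESHOLD = 10

_REGDB_RE = re.compile(r"^([1-7])[a-z]*$", re.IGNORECASE)


def weight_3d(raw_scores: Sequence[float]) -> list[int]:
    """Map raw 3dSNP scores to weights {0, 1, 2} relative to the supplied set.

    The mean and (population) SD are computed over ``raw_scores`` itself:
    > mean + 2 SD -> 2; > mean -> 1; else 0.
    """
    scores = np.asarray(raw_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("raw_scores must be non-empty")
    mean = scores.mean()
    sd = scores.std()  # population convention (ddof=0)
    return [2 if s > mean + 2 * sd else (1 if s > mean else 0) for s in scores]


def weight_regdb(category: str) -> int:
    """RegulomeDB category -> weight 7 - n (letters in sub-grades ignored)."""
    m = _REGDB_RE.match(str(category).strip())
    if not m:
        raise ValueError(
            f"unparseable RegulomeDB category {category!r}; expected a "
            "numeric prefix 1-7 with an optional letter sub-grade"
        )
    return 7 - int(m.group(1))


def _feature_sum(rec: AnnotationRecord, cap_features: bool) -> int:
    counts = (rec.eqtl_count, rec.enhancer_count, rec.rsnp_flag,
              rec.pchic_flag, rec.tfbs_flag, rec.asb_count)
    if cap_features:
        return sum(1 for c in counts if c > 0)
    return sum(counts)


def total_score(
    rec: AnnotationRecord,
    cohort_scores: Sequence[float],
    cap_features: bool = False,
) -> PriorityScore:
    """Priority score of one SNP in the context of its candidate set.

    ``cohort_scores`` is the raw 3dSNP score list of the whole candidate set
    (the record's own score included): the 3dSNP weight is relative to it.
    """
    scores = list(cohort_scores)
    try:
        idx = scores.index(rec.score_3d)
    except ValueError:
        raise ValueError(
            f"{rec.snp_id}: its 3D score {rec.score_3d} is not in the "
            "supplied score context"
        )
    w3 = weight_3d(scores)[idx]
    wr = weight_regdb(rec.regdb_category)
    feats = _feature_sum(rec, cap_features)
    return PriorityScore(snp_id=rec.snp_id, w3d=w3, wregdb=wr,
                         feature_sum=feats, total=w3 + wr + feats)


def score_table(
    records: Sequence[AnnotationRecord],
    cap_features: bool = False,
    threshold: Optional[int] = NOMINATION_THRESHOLD,
) -> list[PriorityScore]:
    """Score a candidate set jointly (the 3dSNP weights share one context).

    Returned in input order, with ``nominated`` set from ``threshold``
    (pass None to leave nomination unset).
    """
    raw = [r.score_3d for r in records]
    w3s = weight_3d(raw) if records else []
    out = []
    for rec, w3 in zip(records, w3s):
        wr = weight_regdb(rec.regdb_category)
        feats = _feature_sum(rec, cap_features)
        total = w3 + wr + feats
        out.append(PriorityScore(
            snp_id=rec.snp_id, w3d=w3, wregdb=wr, feature_sum=feats,
            total=total,
            nominated=(threshold is not None and total >= threshold),
        ))
    return out


def nominate(
    scores: Sequence[PriorityScore],
    threshold: Optional[int] = NOMINATION_THRESHOLD,
    top_k: Optional[int] = None,
) -> list[PriorityScore]:
    """Select candidates for validation by score threshold or by top-k.

    Exactly one rule may be active. ``top_k`` keeps the k highest totals,
    including every tie at the boundary. Output is sorted by
    (descending total, snp_id).
    """
    if top_k is not None and threshold is not None:
        raise ValueError("set either threshold or top_k, not both")
    ranked = sorted(scores, key=lambda s: (-s.total, s.snp_id))
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if len(ranked) > top_k:
            cutoff = ranked[top_k - 1].total
            ranked = [s for s in ranked if s.total >= cutoff]
    else:
        if threshold is None:
            raise ValueError("one of threshold or top_k must be set")
        ranked = [s for s in ranked if s.total >= threshold]
    for s in ranked:
        s.nominated = True
    return ranked


def clump(
    results: Sequence[MetaResult],
    ld: LDMatrix,
    r2_threshold: float = 0.1,
    p_threshold: float = 5e-8,
) -> list[Clump]:
    """Greedy LD clumping of significant SNPs into independent signals.

    Repeatedly take the smallest-p unassigned SNP as index and assign every
    unassigned SNP with r^2 >= ``r2_threshold`` to its clump. Clumps come
    back ordered by index p; members are sorted by their own p.
    """
    sig = [r for r in results if r.p_meta < p_threshold]
    missing = [r.snp_id for r in sig if r.snp_id not in ld]
    if missing:
        raise KeyError(
            f"SNP(s) missing from the LD matrix: {', '.join(missing)}"
        )
    order = sorted(sig, key=lambda r: (r.p_meta, r.chrom, r.pos, r.snp_id))
    unassigned = {r.snp_id: r for r in order}
    clumps: list[Clump] = []
    for r in order:
        if r.snp_id not in unassigned:
            continue
        members = [
            s for s in unassigned
            if ld.r2_between(r.snp_id, s) >= r2_threshold
        ]
        members.sort(key=lambda s: (unassigned[s].p_meta, s))
        for s in members:
            del unassigned[s]
        clumps.append(Clump(index_snp=r.snp_id, members=members,
                            index_p=r.p_meta))
    return clumps
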