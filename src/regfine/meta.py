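"""QC, allele harmonization, and fixed-effects meta-analysis.

Two combination schemes are provided, mirroring the two modes of METAL:

* Sample-size-weighted ("Stouffer"): per-cohort two-sided p-values are
  converted to signed z-scores, z_i = d_i * Phi^-1(1 - p_i/2), and combined
  as z = sum(w_i z_i) / sqrt(sum(w_i^2)) with weights w_i proportional to
  sqrt(N_i); the combined two-sided p is 2 Phi(-|z|).

* Inverse-variance: beta_hat = sum(b_i / se_i^2) / sum(1 / se_i^2),
  se_hat = (sum 1/se_i^2)^(-1/2), giving a pooled odds ratio exp(beta_hat)
  with Wald 95% CI, plus Cochran's Q = sum (b_i - beta_hat)^2 / se_i^2 and
  its chi-square(k-1) heterogeneity p.

Both assume a shared effect-allele orientation across cohorts, which
:func:`harmonize_alleles` establishes (allele swaps, strand flips, and
frequency-based resolution of palindromic SNPs).
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .models import (
    COMPLEMENT,
    AssociationRecord,
    CohortInfo,
    MetaResult,
    QCThresholds,
)

__all__ = [
    "qc_filter",
    "harmonize_alleles",
    "stouffer_meta",
    "ivw_meta",
    "IVWResult",
    "run_meta",
    "gws_filter",
]

GWS_ALPHA = 5e-8

#: Smallest two-sided p reported; protects the (0, 1] domain at extreme z.
_P_FLOOR = 5e-324


def qc_filter(
    records: Sequence[AssociationRecord],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[AssociationRecord], dict[str, int]]:
    """Drop records failing any available QC gate.

    Absent optional fields pass vacuously. The report counts exclusions per
    rule; a record failing several rules increments each of them.
    """
    kept: list[AssociationRecord] = []
    report = {"hwe": 0, "maf": 0, "missingness": 0, "info": 0}
    for rec in records:
        failed = []
        if rec.hwe_p is not None and rec.hwe_p < thresholds.hwe_min_p:
            failed.append("hwe")
        if rec.af1 is not None:
            maf = min(rec.af1, 1.0 - rec.af1)
            if maf < thresholds.maf_min:
                failed.append("maf")
        if (rec.missingness is not None
                and rec.missingness > thresholds.missingness_max):
            failed.append("missingness")
        if rec.info is not None and rec.info < thresholds.info_min:
            failed.append("info")
        if failed:
            for rule in failed:
                report[rule] += 1
        else:
            kept.append(rec)
    return kept, report


def _flip(record: AssociationRecord) -> AssociationRecord:
    """Swap effect and other allele, negating the effect."""
    return replace(
        record,
        allele1=record.allele2,
        allele2=record.allele1,
        af1=None if record.af1 is None else 1.0 - record.af1,
        beta=None if record.beta is None else -record.beta,
        direction=-record.direction,
    )


def _complement_alleles(record: AssociationRecord) -> AssociationRecord:
    return replace(record, allele1=COMPLEMENT[record.allele1],
                   allele2=COMPLEMENT[record.allele2])


def _is_palindromic(a1: str, a2: str) -> bool:
    return a1 in COMPLEMENT and COMPLEMENT[a1] == a2


def harmonize_alleles(
    record: AssociationRecord,
    ref_af: Mapping[str, tuple],
    palindrome_af_margin: float = 0.10,
) -> tuple[Optional[AssociationRecord], str]:
    """Orient a record to a reference allele pair.

    ``ref_af`` maps snp_id -> (ref_allele1, ref_allele2, ref_af1) where
    ref_af1 is the frequency of ref_allele1 in the reference panel.

    Returns ``(record, action)`` where action is one of ``match``, ``swap``,
    ``strand_flip``, ``strand_flip_swap``, ``palindromic_match``,
    ``palindromic_swap``, or ``missing`` (SNP absent from the panel:
    passed through with its ``unmatched`` flag set); and ``(None, action)``
    for ``drop_palindromic`` (allele frequencies too close to 0.5 to orient)
    and ``drop_mismatch`` (alleles irreconcilable with the reference pair).

    Palindromic pairs (A/T, C/G) are orientable only by allele frequency:
    both the record's and the panel's frequency must sit more than
    ``palindrome_af_margin`` away from 0.5. Indel alleles ("I"/"D" and other
    non-ACGT strings) pass through on exact or swapped string match only.
    """
    if record.snp_id not in ref_af:
        return replace(record, unmatched=True), "missing"
    ref_a1, ref_a2, ref_freq = ref_af[record.snp_id]
    a1, a2 = record.allele1, record.allele2

    snv = a1 in COMPLEMENT and a2 in COMPLEMENT
    if snv and _is_palindromic(a1, a2):
        if {a1, a2} != {ref_a1, ref_a2}:
            return None, "drop_mismatch"
        if (record.af1 is None or ref_freq is None
                or abs(record.af1 - 0.5) <= palindrome_af_margin
                or abs(ref_freq - 0.5) <= palindrome_af_margin):
            return None, "drop_palindromic"
        same_side = (record.af1 > 0.5) == (ref_freq > 0.5)
        if a1 == ref_a1:
            return (record, "palindromic_match") if same_side \
                else (_flip(record), "palindromic_swap")
        return (_flip(record), "palindromic_swap") if same_side \
            else (record, "palindromic_match")

    if (a1, a2) == (ref_a1, ref_a2):
        return record, "match"
    if (a2, a1) == (ref_a1, ref_a2):
        return _flip(record), "swap"
    if snv and ref_a1 in COMPLEMENT and ref_a2 in COMPLEMENT:
        c1, c2 = COMPLEMENT[a1], COMPLEMENT[a2]
        if (c1, c2) == (ref_a1, ref_a2):
            return _complement_alleles(record), "strand_flip"
        if (c2, c1) == (ref_a1, ref_a2):
            return _flip(_complement_alleles(record)), "strand_flip_swap"
    return None, "drop_mismatch"


def stouffer_meta(
    p_values: Sequence[float],
    directions: Sequence[int],
    weights: Sequence[float],
) -> tuple[float, float]:
    """Sample-size-weighted z-score combination of two-sided p-values.

    Returns ``(z_combined, p_meta)``. Invariant under uniform rescaling of
    the weights.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(directions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(p) == len(d) == len(w)) or len(p) == 0:
        raise ValueError("p_values, directions, weights must have equal length >= 1")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not np.all(np.isin(d, (1.0, -1.0))):
        raise ValueError("directions must be +1 or -1")
    z = d * stats.norm.isf(p / 2.0)
    z_combined = float(np.dot(w, z) / math.sqrt(np.dot(w, w)))
    p_meta = max(float(2.0 * stats.norm.sf(abs(z_combined))), _P_FLOOR)
    return z_combined, p_meta


class IVWResult(NamedTuple):
    beta: float
    se: float
    p: float
    or_meta: float
    ci_low: float
    ci_high: float
    q_stat: float
    het_p: Optional[float]


def ivw_meta(betas: Sequence[float], ses: Sequence[float]) -> IVWResult:
    """Fixed-effect inverse-variance-weighted pooling of log odds ratios."""
    b = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if len(b) != len(se) or len(b) == 0:
        raise ValueError("betas and ses must have equal length >= 1")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    prec = 1.0 / se**2
    beta_meta = float(np.dot(prec, b) / prec.sum())
    se_meta = float(prec.sum() ** -0.5)
    z = beta_meta / se_meta
    p = max(float(2.0 * stats.norm.sf(abs(z))), _P_FLOOR)
    q = float(np.dot(prec, (b - beta_meta) ** 2))
    k = len(b)
    het_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else None
    return IVWResult(
        beta=beta_meta, se=se_meta, p=p,
        or_meta=math.exp(beta_meta),
        ci_low=math.exp(beta_meta - 1.96 * se_meta),
        ci_high=math.exp(beta_meta + 1.96 * se_meta),
        q_stat=q, het_p=het_p,
    )


def _cohort_weight(cohort: CohortInfo, weight_mode: str) -> float:
    if weight_mode == "total_n":
        return math.sqrt(cohort.total_n)
    if weight_mode == "effective_n":
        return math.sqrt(cohort.effective_n)
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def run_meta(
    cohort_records: Mapping[CohortInfo, Sequence[AssociationRecord]],
    scheme: str = "stouffer",
    weight_mode: str = "total_n",
    min_cohorts: int = 2,
    allow_singleton: bool = False,
) -> list[MetaResult]:
    """Meta-analyze harmonized records joined across cohorts on SNP id.

    ``scheme`` is one of ``stouffer``, ``ivw``, ``both``: the headline
    z/p come from the Stouffer branch unless scheme is ``ivw``; the pooled
    OR, CI, and Cochran heterogeneity come from the IVW branch when every
    contributing cohort carries beta and se. Results are sorted by
    (p_meta, chrom, pos, snp_id) for deterministic output.
    """
    if scheme not in ("stouffer", "ivw", "both"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if allow_singleton:
        min_cohorts = 1
    cohorts = sorted(cohort_records, key=lambda c: c.name)
    by_snp: dict[str, dict[CohortInfo, AssociationRecord]] = {}
    for cohort in cohorts:
        for rec in cohort_records[cohort]:
            by_snp.setdefault(rec.snp_id, {})[cohort] = rec

    results: list[MetaResult] = []
    for snp_id, per_cohort in by_snp.items():
        present = [c for c in cohorts if c in per_cohort]
        if len(present) < min_cohorts:
            continue
        recs = [per_cohort[c] for c in present]
        weights = [_cohort_weight(c, weight_mode) for c in present]
        direction_string = "".join(
            "+" if r.direction > 0 else "-" for r in recs)

        z = p_meta = None
        or_meta = ci_low = ci_high = het_p = None
        q_stat = 0.0
        if scheme in ("stouffer", "both"):
            z, p_meta = stouffer_meta(
                [r.p for r in recs], [r.direction for r in recs], weights)
        if scheme in ("ivw", "both"):
            if all(r.beta is not None and r.se is not None for r in recs):
                ivw = ivw_meta([r.beta for r in recs], [r.se for r in recs])
                or_meta, ci_low, ci_high = ivw.or_meta, ivw.ci_low, ivw.ci_high
                q_stat, het_p = ivw.q_stat, ivw.het_p
                if scheme == "ivw":
                    z, p_meta = ivw.beta / ivw.se, ivw.p
            elif scheme == "ivw":
                continue  # no effect sizes to pool
        lead = recs[0]
        results.append(MetaResult(
            snp_id=snp_id, chrom=lead.chrom, pos=lead.pos,
            allele1=lead.allele1, allele2=lead.allele2,
            z_combined=z, p_meta=p_meta,
            or_meta=or_meta, ci_low=ci_low, ci_high=ci_high,
            q_stat=q_stat, het_p=het_p,
            direction_string=direction_string, n_cohorts=len(present),
        ))
    results.sort(key=lambda r: (r.p_meta, r.chrom, r.pos, r.snp_id))
    return results


def gws_filter(results: Sequence[MetaResult],
               alpha: float = GWS_ALPHA) -> list[MetaResult]:
    """Results below the significance threshold, sorted by ascending p
    (position, then SNP id, breaking ties)."""
    hits = [r for r in results if r.p_meta < alpha]
    hits.sort(key=lambda r: (r.p_meta, r.chrom, r.pos, r.snp_id))
    return hits
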