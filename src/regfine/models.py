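"""Core domain types for the fine-mapping pipeline.

The containers here mirror the objects a GWAS fine-mapping study passes
between its stages: per-cohort association summary statistics, combined
meta-analysis evidence, functional-annotation records with derived priority
weights, binding-motif models and their per-allele affinity comparisons,
read-count observations for allele-specific binding, and the LD structure
used to decompose an association peak into independent signals.

Validation is deliberately light-weight: constructors check the domain
invariants that downstream numerics rely on (p-values in (0, 1], positive
standard errors, stochastic PWM rows) and raise ``ValueError`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "COMPLEMENT",
    "CohortInfo",
    "AssociationRecord",
    "MetaResult",
    "AnnotationRecord",
    "PriorityScore",
    "PWM",
    "AllelicMotifHit",
    "ASBObservation",
    "ASBResult",
    "LDMatrix",
    "Clump",
    "QCThresholds",
    "SimulationConfig",
]

#: Watson-Crick complement for strand-flip logic. Indel codes ("I"/"D") are
#: deliberately absent: indel alleles are opaque strings and never flipped.
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CohortInfo:
    """One case-control cohort contributing summary statistics."""

    name: str
    n_cases: int
    n_controls: int
    ancestry: str = ""

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(
                f"cohort {self.name!r}: case/control counts must be positive"
            )

    @property
    def total_n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def effective_n(self) -> float:
        """Balanced-design-equivalent sample size, 4/(1/cases + 1/controls)."""
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class AssociationRecord:
    """One SNP's summary statistic in one cohort, with optional QC fields.

    ``allele1`` is the effect allele; ``direction`` is the sign of the
    effect (+1 risk, -1 protective) and must agree with ``beta`` when both
    are present. Positions are 1-based (hg19 convention in the packaged
    tables).
    """

    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str
    p: float
    direction: int
    af1: Optional[float] = None
    beta: Optional[float] = None
    se: Optional[float] = None
    hwe_p: Optional[float] = None
    missingness: Optional[float] = None
    info: Optional[float] = None
    cohort: Optional[CohortInfo] = None
    #: set by harmonization when the SNP is absent from the reference panel
    unmatched: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p-value {self.p} outside (0, 1]")
        if self.direction not in (1, -1):
            raise ValueError(f"{self.snp_id}: direction must be +1 or -1")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if self.beta is not None and self.beta != 0.0:
            if (self.beta > 0) != (self.direction > 0):
                raise ValueError(
                    f"{self.snp_id}: sign of beta disagrees with direction"
                )


@dataclass
class MetaResult:
    """Combined association evidence for one SNP across cohorts."""

    snp_id: str
    z_combined: float
    p_meta: float
    chrom: str = ""
    pos: int = 0
    allele1: str = ""
    allele2: str = ""
    or_meta: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    q_stat: float = 0.0
    het_p: Optional[float] = None
    direction_string: str = ""
    n_cohorts: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_meta <= 1.0):
            raise ValueError(f"{self.snp_id}: p_meta {self.p_meta} outside (0, 1]")
        if self.q_stat < 0:
            raise ValueError(f"{self.snp_id}: Q statistic must be nonnegative")
        if self.or_meta is not None and self.ci_low is not None:
            if not (self.ci_low <= self.or_meta <= (self.ci_high or np.inf)):
                raise ValueError(f"{self.snp_id}: OR outside its CI")


@dataclass
class AnnotationRecord:
    """Raw functional-annotation features for one SNP.

    ``score_3d`` is the composite 3dSNP functional score; ``regdb_category``
    the ordinal RegulomeDB evidence class ("7" weakest .. "1a" strongest);
    the remaining fields are feature counts/flags from eQTL, enhancer, rSNP,
    promoter-capture Hi-C, TF-binding-site, and allele-specific
    expression/binding annotation sources.
    """

    snp_id: str
    region_class: str
    score_3d: float
    regdb_category: str
    eqtl_count: int = 0
    enhancer_count: int = 0
    rsnp_flag: int = 0
    pchic_flag: int = 0
    tfbs_flag: int = 0
    asb_count: int = 0
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if self.score_3d < 0:
            raise ValueError(f"{self.snp_id}: 3D score must be nonnegative")
        for name in ("eqtl_count", "enhancer_count", "rsnp_flag",
                     "pchic_flag", "tfbs_flag", "asb_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.snp_id}: {name} must be nonnegative")


@dataclass
class PriorityScore:
    """Derived weights and total priority score for one SNP."""

    snp_id: str
    w3d: int
    wregdb: int
    feature_sum: int
    total: int
    nominated: bool = False

    def __post_init__(self) -> None:
        if self.total != self.w3d + self.wregdb + self.feature_sum:
            raise ValueError(f"{self.snp_id}: total != w3d + wregdb + features")


@dataclass
class PWM:
    """Position weight matrix over the DNA alphabet (columns A, C, G, T)."""

    motif_id: str
    tf_name: str
    probs: np.ndarray  # shape (L, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 1:
            raise ValueError(f"{self.motif_id}: probs must be an Lx4 matrix, L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: each position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return len(self.probs)


@dataclass
class AllelicMotifHit:
    """Best-window affinity comparison of one motif between two SNP alleles."""

    snp_id: str
    motif_id: str
    allele1: str
    allele2: str
    p_allele1: float
    p_allele2: float
    best_offset1: int
    best_strand1: str
    best_offset2: int
    best_strand2: str
    fold_change: float
    favored_allele: str

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")


@dataclass(frozen=True)
class ASBObservation:
    """Allele-resolved read counts at one heterozygous site in one cell line."""

    snp_id: str
    cell_line: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class ASBResult:
    """Exact binomial test of allelic imbalance for one observation."""

    observation: ASBObservation
    imbalance: float
    p_binom: float
    p_adj: float
    testable: bool = True


@dataclass
class LDMatrix:
    """Pairwise r-squared between an ordered list of SNPs."""

    snp_ids: Sequence[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass
class Clump:
    """One independent association signal: an index SNP and its LD partners."""

    index_snp: str
    members: list
    index_p: float


@dataclass(frozen=True)
class QCThresholds:
    """Summary-statistic QC gates (records failing any available gate drop)."""

    hwe_min_p: float = 1e-6
    maf_min: float = 0.005
    missingness_max: float = 0.10
    info_min: float = 0.70

    def __post_init__(self) -> None:
        for name in ("hwe_min_p", "maf_min", "missingness_max", "info_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions of the packaged tables: the four
    contributing cohorts (resolved from the packaged cohort table when
    ``cohorts`` is None), a causal odds ratio of 1.13 at MAF 0.30 (the
    strongest intronic signals), and 100 SNPs in five LD blocks of 20 with
    within-block correlation r = 0.9.
    """

    seed: int = 0
    cohorts: Optional[Sequence[CohortInfo]] = None
    n_snps: int = 100
    block_structure: Sequence = ((20, 0.9),) * 5
    causal_index: int = 10
    causal_or: float = 1.13
    causal_maf: float = 0.30
    null_fraction: float = 0.0
    asb_true_prop: float = 0.8
    asb_n_sites: int = 10
    asb_depth: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.causal_maf < 0.5):
            raise ValueError("causal_maf must lie in (0, 0.5)")
        for size, r in self.block_structure:
            if not (0.0 <= r <= 1.0):
                raise ValueError("within-block r must lie in [0, 1]")
            if size < 1:
                raise ValueError("block sizes must be positive")
        if sum(s for s, _ in self.block_structure) != self.n_snps:
            raise ValueError("block sizes must sum to n_snps")
        if not (0 <= self.causal_index < self.n_snps):
            raise ValueError("causal_index out of range")
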