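# Methods

This note documents the models implemented in `regfine`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic-data generators do and do not emulate.

## Summary-statistic QC and harmonization

Records are filtered by four gates, each applied only when the field is
present (absent optional fields pass vacuously): Hardy-Weinberg p > 1e-6,
minor allele frequency (min(af, 1−af)) > 0.5%, genotype missingness < 10%,
imputation quality ≥ 0.7. The exclusion report counts every rule a record
fails, so rule counts can exceed the number of dropped records.

Harmonization orients each record to a reference allele pair using the
eight possible orientations of a biallelic SNV: exact match, allele swap
(negate the effect, complement the frequency), strand flip (complement both
alleles), and flip+swap. Palindromic pairs (A/T, C/G) are strand-ambiguous
and are resolved by allele frequency alone: both the record's and the
panel's effect-allele frequency must be more than 0.10 away from 0.5
(default margin), otherwise the record is dropped as unresolvable. Indel
alleles (e.g. "I"/"D") are opaque strings: they match exactly or in swapped
order, and never enter complement logic. SNPs absent from the reference
panel pass through with an `unmatched` flag rather than being dropped —
the caller decides.

## Fixed-effects meta-analysis

Two schemes, selectable independently or together:

* **Sample-size-weighted z combination.** z_i = d_i Φ⁻¹(1 − p_i/2) from
  each cohort's two-sided p and effect direction d_i; combined
  z = Σ w_i z_i / √(Σ w_i²), p = 2 Φ(−|z|). The default weight is
  w_i = √(cases_i + controls_i) (`total_n`); w_i = √(4/(1/cases + 1/controls))
  (`effective_n`) is selectable. Both reproduce the packaged meta table
  within the suite's ±1 log10 band; total-N tracks it slightly more closely
  and is the default. One-sided inputs are not supported.
* **Inverse-variance weighting.** Precision-weighted mean of per-cohort log
  odds ratios with Wald 95% CI on the exponentiated scale, Cochran's
  Q = Σ (b_i − β̂)²/se_i² and its χ²_{k−1} upper tail (undefined at k = 1).
  Heterogeneity is only defined on this branch; the z-combination branch
  reports per-cohort sign consistency through the direction string instead,
  since per-cohort betas are not always available.

SNPs need ≥ 2 contributing cohorts by default (`allow_singleton` overrides).
Cohorts are processed in name-sorted order, and all sorted outputs break
ties lexicographically on (p, chromosome, position, SNP id), so outputs are
byte-stable and diffable. Two-sided p-values are floored at the smallest
positive double to keep the (0, 1] domain at extreme z.

On the packaged meta table, the recombined p-values agree with the
published column to within ±0.8 orders of magnitude but not exactly, for
two structural reasons: the per-cohort inputs are printed at 3 significant
figures, and the published discovery column is itself a pooled sub-meta of
three Asian cohorts that the recombination treats as one cohort (only its
combined p is printed). The suite's ±1.0 log10 tolerance encodes this.

## Priority scoring and nomination

The 3dSNP weight is computed relative to the candidate set under analysis:
mean and standard deviation are taken over the supplied raw score list
itself, with weight 2 above mean + 2 SD, 1 above the mean, 0 otherwise.
The population SD (divide by n) is used; on the packaged 19-SNP table the
sample-SD convention gives identical weights, and population SD is kept for
determinism of the tie cases. The RegulomeDB weight maps the category's
numeric prefix n ∈ {1..7} to 7 − n, ignoring letter sub-grades; this
mapping reproduces all 19 (category, weight) pairs of the packaged table.

Count-valued features (eQTL, enhancer, ASE/ASB) are summed at face value
because the packaged totals require it; a capped variant counting each
feature at most once (`cap_features=True`) is available for the stricter
presence/absence reading. The nomination default is total ≥ 10, which on
the packaged table selects exactly the five SNPs the study pursued
experimentally; a top-k rule (ties at the boundary included) is the
alternative, and the two rules are mutually exclusive.

LD clumping is greedy: the most significant unassigned SNP becomes an
index and absorbs every unassigned SNP with r² ≥ threshold (default 0.1 —
"uncorrelated" is not given a numeric definition in the source study, so
the threshold is configurable). The unit suite checks the greedy result
against a definition-level brute-force reference on random instances.

## Allelic binding affinity

Motif match scores are additive log-likelihood ratios
s(seq) = Σ_i log((p_{i,b} + c)/bg_b) with pseudocount c = 0.01 added to the
motif probabilities before the log (background untouched). Scores live on
an integer lattice: each per-position score is rounded to a resolution of
1e-3 log-likelihood units (configurable). The affinity of an allele is the
exact tail probability P(score ≥ best) under the background model, where
"best" is the maximum over all motif windows covering the SNP on both
strands, and the background distribution of the lattice score is built by
dynamic programming (discrete convolution across positions). Because the
observed score and the distribution share the lattice, the tail is exact
for the binned score model; the suite cross-checks it against brute-force
4^L enumeration. The allelic fold-change is the ratio of the larger to the
smaller affinity p-value — a p-value ratio, not a raw score ratio, since
the ratio of tail probabilities is comparable across motifs of different
lengths and information content. The shortlist filter keeps fold ≥ 5.

Flank length is the caller's choice; every window that covers the SNP and
fits in the flank is scored, so a flank of (2L − 1) bases centred on the
SNP exercises all L windows of a length-L motif.

## Allele-specific binding

Each (site, cell line) observation is one two-sided exact binomial test of
the alternate-allele read fraction against 0.5, with BH (default) or
Bonferroni adjustment across the observations of one call — a per-run,
not global, family. Observations with zero reads are flagged untestable
and excluded from the family. This is a simplification of read-window
aggregation approaches that pool counts around the site across cell lines;
the source study names no test statistic, so the exact per-observation
binomial with FDR control is used as the transparent default. The exact
test is conservative under discreteness: at 50 reads its null rejection
rate at nominal 0.05 is ≈ 0.033.

## Synthetic data

The simulator draws per-cohort z-score vectors from MVN(Rμ_c, R), where R
is the block-diagonal LD correlation matrix (compound-symmetric blocks) and
μ_c is zero except at the causal SNP, whose noncentrality is
log(OR)/se_c with se_c = 1/√(2·maf·(1−maf)·N_eff,c). Records carry
β = z·se and the two-sided p. Defaults are the study conditions of the
packaged tables: the four cohorts' sample sizes, causal OR 1.13 and MAF
0.30 (the strongest intronic association), and 100 SNPs in five blocks of
20 at within-block r = 0.9 (LD r² = 0.81, echoing the tight intronic
haplotype). Sampling is per block, so an independent-SNP null
configuration scales to many SNPs without materializing a dense matrix.

The annotation generator plants one high-priority SNP whose features are
drawn from the upper range observed in the packaged feature table
(RegulomeDB 3a, 3dSNP score 18–26, most features present) among nulls
drawn from the low range; the read-count generator plants one imbalanced
site (default 80:20 at 50 reads) across the seven emulated heterozygous
cell lines. All randomness derives from one seed sequence; sub-generators
take deterministic child seeds.

What the generators do *not* emulate: genotype-level sampling (no
case-control phenotype model beyond the log-OR noncentrality mapping), LD
estimated with error, allele-frequency differences between cohorts,
correlated annotation features, or read-depth variation and mapping bias
in ASB counts. Passing recovery tests therefore demonstrate that the
pipeline correctly extracts planted signals of realistic magnitude from
data satisfying its own model assumptions — not robustness to the
additional noise sources of real cohort data.

The parameter-recovery experiment runs the full chain
(simulate → QC → meta-analysis → significance filter → clumping → scoring
→ nomination) over repeated draws and reports how often the top clump's
index SNP falls in the causal LD block and how often the planted SNP is
nominated. At the default conditions the analytic combined noncentrality
is ≈ 12.8, so both rates are expected near 1; the suite uses 200 reps
(≈ seconds) as a stable operating size.

## Numerical and formatting choices

* p-values are written in scientific notation at 3 significant digits (the
  source tables' style); heterogeneity p at 4 digits; other floats at 6
  significant digits. Written tables are deterministic and re-readable;
  float columns round-trip to the written precision, all else exactly.
* Positions are 1-based in SNP tables and 0-based half-open in BED; the
  conversion happens only at the BED boundary, and a position equal to an
  interval's end coordinate is outside it.
* Degenerate inputs: all-equal 3dSNP scores give weight 0 everywhere
  (SD = 0, nothing strictly above the mean); compound-symmetric blocks with
  r = 1 are rejected as non-positive-definite; a motif position with
  all-zero counts and zero pseudocount is a parse error.

## Known limitations

* The z-combination branch cannot reproduce a pooled sub-meta cohort
  exactly from its combined p alone (see above); this is a property of the
  published inputs, not of the implementation.
* No random-effects meta-analysis, genomic control, imputation, liftover,
  or conditional/joint (COJO-style) analysis.
* Raw 3dSNP and RegulomeDB scores are inputs, not computed here; live
  annotation services are out of scope by design.
* The affinity p-value is exact for the lattice score model; coarsening
  the resolution trades accuracy of the underlying continuous score for
  speed on long motifs.
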