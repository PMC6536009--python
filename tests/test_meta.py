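import math

import numpy as np
import pytest
from scipy import stats

import regfine as rf
from regfine.meta import harmonize_alleles, ivw_meta, stouffer_meta
from regfine.models import AssociationRecord, QCThresholds


def _rec(**kw):
    base = dict(snp_id="rs1", chrom="15", pos=1000, allele1="A",
                allele2="G", p=0.5, direction=1)
    base.update(kw)
    return AssociationRecord(**base)


class TestQCFilter:
    def test_low_imputation_quality_excluded(self):
        kept, report = rf.qc_filter([_rec(info=0.69), _rec(info=0.70)])
        assert len(kept) == 1 and kept[0].info == 0.70
        assert report["info"] == 1

    def test_absent_fields_pass_vacuously(self):
        kept, report = rf.qc_filter([_rec()])
        assert len(kept) == 1 and sum(report.values()) == 0

    def test_rare_allele_excluded_on_minor_frequency(self):
        # maf = min(af1, 1 - af1), so af1 near 1 is also rare
        kept, report = rf.qc_filter([_rec(af1=0.004), _rec(af1=0.996),
                                     _rec(af1=0.3)])
        assert len(kept) == 1 and report["maf"] == 2

    def test_hwe_and_missingness_rules(self):
        kept, report = rf.qc_filter(
            [_rec(hwe_p=1e-7), _rec(missingness=0.2), _rec(hwe_p=1e-5)])
        assert len(kept) == 1
        assert report["hwe"] == 1 and report["missingness"] == 1


class TestHarmonizeAlleles:
    REF = {"rs1": ("C", "T", 0.21)}

    @pytest.mark.parametrize("a1,a2,action,out_alleles,dir_factor", [
        ("C", "T", "match", ("C", "T"), 1),
        ("T", "C", "swap", ("C", "T"), -1),
        ("G", "A", "strand_flip", ("C", "T"), 1),
        ("A", "G", "strand_flip_swap", ("C", "T"), -1),
        ("C", "A", "drop_mismatch", None, 0),
        ("G", "T", "drop_mismatch", None, 0),
    ])
    def test_orientation_enumeration(self, a1, a2, action, out_alleles,
                                     dir_factor):
        """Each allele-pair orientation maps to its documented action."""
        rec = _rec(allele1=a1, allele2=a2, direction=-1, af1=0.2)
        out, got = harmonize_alleles(rec, self.REF)
        assert got == action
        if out_alleles is None:
            assert out is None
        else:
            assert (out.allele1, out.allele2) == out_alleles
            assert out.direction == -1 * dir_factor
            expected_af = 0.2 if dir_factor == 1 else 0.8
            assert out.af1 == pytest.approx(expected_af)

    def test_unresolvable_palindrome_dropped(self):
        rec = _rec(allele1="A", allele2="T", af1=0.48)
        out, action = harmonize_alleles(rec, {"rs1": ("A", "T", 0.2)})
        assert out is None and action == "drop_palindromic"

    def test_palindrome_resolved_by_frequency(self):
        ref = {"rs1": ("A", "T", 0.2)}
        out, action = harmonize_alleles(_rec(allele1="A", allele2="T",
                                             af1=0.18, direction=1), ref)
        assert action == "palindromic_match" and out.direction == 1
        out, action = harmonize_alleles(_rec(allele1="A", allele2="T",
                                             af1=0.82, direction=1), ref)
        assert action == "palindromic_swap" and out.direction == -1
        assert out.af1 == pytest.approx(0.18)

    def test_missing_snp_passes_through_flagged(self):
        out, action = harmonize_alleles(_rec(snp_id="rsX"), self.REF)
        assert action == "missing" and out.unmatched

    def test_indel_exact_string_match_only(self):
        ref = {"rs1": ("I", "D", 0.3)}
        out, action = harmonize_alleles(_rec(allele1="I", allele2="D"), ref)
        assert action == "match"
        out, action = harmonize_alleles(_rec(allele1="D", allele2="I",
                                             direction=1), ref)
        assert action == "swap" and out.direction == -1
        out, action = harmonize_alleles(_rec(allele1="I", allele2="DD"), ref)
        assert out is None and action == "drop_mismatch"


class TestStouffer:
    def test_single_cohort_is_identity(self):
        z, p = stouffer_meta([0.01], [1], [123.0])
        assert p == pytest.approx(0.01)
        assert z > 0

    def test_two_identical_cohorts_scale_by_sqrt2(self):
        p_in = 2 * stats.norm.sf(2.0)
        z, _ = stouffer_meta([p_in, p_in], [1, 1], [5.0, 5.0])
        assert z == pytest.approx(2 * math.sqrt(2), rel=1e-9)

    def test_lead_snp_recombination(self, cohorts):
        """The lead SNP's four per-cohort p-values recombine to within an
        order of magnitude of the published combined p, and well past the
        genome-wide threshold."""
        ps = [1.40e-04, 5.81e-02, 1.03e-03, 4.35e-05]
        weights = [math.sqrt(c.total_n) for c in cohorts]
        z, p = stouffer_meta(ps, [-1] * 4, weights)
        assert z < 0 and p < 5e-8
        assert abs(math.log10(p) - math.log10(3.16e-11)) < 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stouffer_meta([0.0], [1], [1.0])
        with pytest.raises(ValueError):
            stouffer_meta([0.5], [1], [0.0])
        with pytest.raises(ValueError):
            stouffer_meta([0.5, 0.1], [1], [1.0, 1.0])

    def test_k_copies_scale_z_by_sqrt_k(self):
        p_in = 2 * stats.norm.sf(1.5)
        for k in (2, 3, 5, 8):
            z, _ = stouffer_meta([p_in] * k, [1] * k, [2.0] * k)
            assert z == pytest.approx(1.5 * math.sqrt(k), rel=1e-9)


class TestIVW:
    def test_single_study(self):
        res = ivw_meta([0.1], [0.05])
        assert res.beta == pytest.approx(0.1)
        assert res.q_stat == pytest.approx(0.0)
        assert res.het_p is None

    def test_two_studies_hand_arithmetic(self):
        res = ivw_meta([0.1, 0.3], [0.1, 0.1])
        assert res.beta == pytest.approx(0.2)
        assert res.q_stat == pytest.approx(2.0)
        assert res.het_p == pytest.approx(0.1573, abs=1e-4)
        assert res.ci_low < res.or_meta < res.ci_high

    def test_identical_effects_are_homogeneous(self):
        res = ivw_meta([0.2, 0.2], [0.1, 0.2])
        assert res.q_stat == pytest.approx(0.0)
        assert res.het_p == pytest.approx(1.0)

    def test_equal_ses_give_arithmetic_mean(self, rng):
        b = rng.normal(size=6)
        res = ivw_meta(b, [0.3] * 6)
        assert res.beta == pytest.approx(b.mean())

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta([0.1, 0.2], [0.1, 0.0])


class TestRunMeta:
    def test_published_table_recombines_with_consistent_directions(
            self, table2_records):
        results = rf.run_meta(table2_records)
        assert len(results) == 19
        for r in results:
            assert r.n_cohorts == 4
            assert r.direction_string in ("++++", "----")
            assert (r.z_combined > 0) == (r.direction_string == "++++")

    def test_singleton_snp_omitted_by_default(self, cohorts):
        grouped = {
            cohorts[0]: [_rec(snp_id="rs_a", cohort=cohorts[0]),
                         _rec(snp_id="rs_b", cohort=cohorts[0])],
            cohorts[1]: [_rec(snp_id="rs_a", cohort=cohorts[1])],
        }
        results = rf.run_meta(grouped)
        assert [r.snp_id for r in results] == ["rs_a"]
        results = rf.run_meta(grouped, allow_singleton=True)
        assert {r.snp_id for r in results} == {"rs_a", "rs_b"}

    def test_cohort_order_invariance(self, table2_records):
        forward = rf.run_meta(dict(table2_records))
        reversed_ = rf.run_meta(dict(reversed(list(table2_records.items()))))
        assert [(r.snp_id, r.p_meta) for r in forward] == \
               [(r.snp_id, r.p_meta) for r in reversed_]

    def test_ivw_scheme_pools_odds_ratios(self, cohorts):
        grouped = {
            cohorts[0]: [_rec(beta=0.1, se=0.05, cohort=cohorts[0])],
            cohorts[1]: [_rec(beta=0.2, se=0.05, cohort=cohorts[1])],
        }
        r, = rf.run_meta(grouped, scheme="ivw")
        assert r.or_meta == pytest.approx(math.exp(0.15))
        assert r.het_p is not None

    def test_no_overlap_gives_empty(self, cohorts):
        grouped = {cohorts[0]: [_rec(snp_id="rs_a", cohort=cohorts[0])],
                   cohorts[1]: [_rec(snp_id="rs_b", cohort=cohorts[1])]}
        assert rf.run_meta(grouped) == []


class TestGWSFilter:
    def _results(self, table2):
        return [
            rf.MetaResult(snp_id=row.snp, chrom="15", pos=int(row.position),
                          z_combined=0.0, p_meta=float(row.p_meta))
            for row in table2.itertuples()
        ]

    def test_published_pmeta_column(self, table2):
        hits = rf.gws_filter(self._results(table2))
        assert len(hits) == 18
        assert "rs12900339" not in {r.snp_id for r in hits}
        ps = [r.p_meta for r in hits]
        assert ps == sorted(ps)

    def test_suggestive_threshold_keeps_all(self, table2):
        assert len(rf.gws_filter(self._results(table2), alpha=5e-3)) == 19

    def test_empty_input(self):
        assert rf.gws_filter([]) == []


def test_null_type_one_error_rate():
    """With no causal effect, the significance filter at alpha = 0.05 fires
    at its nominal rate (within 3 binomial standard errors)."""
    cfg = rf.SimulationConfig(seed=11, causal_or=1.0,
                              block_structure=((1, 0.0),) * 100)
    n_tests = 0
    n_sig = 0
    for child in np.random.SeedSequence(77).spawn(30):
        c = rf.SimulationConfig(seed=int(child.generate_state(1)[0] % 2**31),
                                causal_or=1.0,
                                block_structure=((1, 0.0),) * 100)
        per_cohort, _ = rf.simulate_summary_stats(c)
        results = rf.run_meta(per_cohort)
        n_tests += len(results)
        n_sig += len(rf.gws_filter(results, alpha=0.05))
    rate = n_sig / n_tests
    se = math.sqrt(0.05 * 0.95 / n_tests)
    assert abs(rate - 0.05) <= 3 * se
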