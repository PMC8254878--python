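"""Somatic calling statistic, QC gate, rarity/severity flags and cascade."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amelonet import PipelineConfig
from amelonet.variants import (
    POPFREQ_DBS,
    AnnotatedVariant,
    DataError,
    SomaticCall,
    VariantCandidate,
    annotate_calls,
    apply_qc,
    call_somatic,
    fisher_somatic_test,
    flag_rare,
    flag_severe,
    recurrence_summary,
    run_cascade,
)

from _oracles import fisher_one_sided


def cand(nr, na, tr, ta, pid="E1", chrom="chr1", pos=100, ref="A", alt="T"):
    return VariantCandidate(pid, chrom, pos, ref, alt, nr, na, tr, ta)


def make_call(nr, na, tr, ta, fisher_p=None, **kw):
    c = cand(nr, na, tr, ta, **kw)
    p = fisher_somatic_test(c) if fisher_p is None else fisher_p
    return SomaticCall(
        candidate=c,
        fisher_p=p,
        normal_vaf=c.normal_vaf,
        tumor_vaf=c.tumor_vaf,
        qc_pass=False,
    )


def make_annotated(
    consequence="missense",
    popfreq=None,
    cadd=None,
    sift=None,
    polyphen=None,
    call=None,
    gene="GENE1",
):
    call = call or make_call(40, 0, 30, 20)
    return AnnotatedVariant(
        call=call,
        gene=gene,
        consequence=consequence,
        popfreq=popfreq or {db: None for db in POPFREQ_DBS},
        cadd_phred=cadd,
        sift_damaging=sift,
        polyphen_damaging=polyphen,
        is_rare=False,
        is_severe=False,
        is_final=False,
    )


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_somatic_test(cand(10, 0, 10, 0)) == 1.0

    def test_depletion_direction_gives_p_one(self):
        # alt reads only in normal: no evidence of tumor enrichment
        assert fisher_somatic_test(cand(0, 10, 10, 0)) == 1.0

    def test_enriched_table_matches_enumeration(self):
        p = fisher_somatic_test(cand(20, 0, 10, 10))
        assert p == pytest.approx(fisher_one_sided(20, 0, 10, 10), abs=1e-10)

    def test_zero_depth_raises(self):
        with pytest.raises(DataError):
            fisher_somatic_test(cand(0, 0, 10, 5))

    def test_two_sided_matches_scipy(self):
        from scipy.stats import fisher_exact

        p = fisher_somatic_test(cand(18, 2, 9, 11), alternative="two-sided")
        expected = fisher_exact([[18, 2], [9, 11]], alternative="two-sided")[1]
        assert p == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        nr=st.integers(0, 25),
        na=st.integers(0, 25),
        tr=st.integers(0, 25),
        ta=st.integers(0, 25),
    )
    def test_matches_enumeration_on_random_tables(self, nr, na, tr, ta):
        if nr + na == 0 or tr + ta == 0:
            return
        p = fisher_somatic_test(cand(nr, na, tr, ta))
        assert p == pytest.approx(fisher_one_sided(nr, na, tr, ta), abs=1e-10)
        assert 0.0 < p <= 1.0


class TestQC:
    def test_passing_call(self, cfg):
        # tumor VAF 3/50 = 0.06 just above 0.05; every criterion at or
        # beyond its threshold
        call = make_call(40, 0, 47, 3, fisher_p=0.01)
        assert apply_qc(call, cfg)

    def test_normal_depth_nine_fails(self, cfg):
        call = make_call(9, 0, 60, 40, fisher_p=0.001)
        assert not apply_qc(call, cfg)

    def test_two_normal_alt_reads_fail(self, cfg):
        call = make_call(98, 2, 60, 40, fisher_p=0.001)
        assert not apply_qc(call, cfg)

    @pytest.mark.parametrize(
        "nr,na,tr,ta,p",
        [
            (40, 0, 47, 3, 0.06),  # p not below 0.05
            (40, 0, 48, 2, 0.01),  # tumor alt below 3
            (30, 1, 60, 40, 0.001),  # normal VAF 1/31 > 0.03
            (95, 0, 97, 3, 0.01),  # tumor VAF 0.03 below 0.05
            (40, 0, 6, 3, 0.01),  # tumor depth 9 below 10
        ],
    )
    def test_each_criterion_can_fail_alone(self, cfg, nr, na, tr, ta, p):
        assert not apply_qc(make_call(nr, na, tr, ta, fisher_p=p), cfg)

    def test_nan_p_fails(self, cfg):
        call = make_call(40, 0, 60, 40, fisher_p=math.nan)
        assert not apply_qc(call, cfg)


class TestRarity:
    def test_never_observed_is_rare(self, cfg):
        # absent from every database = strongest rarity evidence
        v = make_annotated(popfreq={db: None for db in POPFREQ_DBS})
        assert flag_rare(v, cfg)

    def test_exactly_at_threshold_is_not_rare(self, cfg):
        pf = {db: None for db in POPFREQ_DBS}
        pf[POPFREQ_DBS[0]] = 0.005
        assert not flag_rare(make_annotated(popfreq=pf), cfg)

    def test_all_below_threshold_is_rare(self, cfg):
        pf = {db: 0.004 for db in POPFREQ_DBS}
        assert flag_rare(make_annotated(popfreq=pf), cfg)

    def test_frequency_outside_unit_interval_rejected(self, cfg):
        pf = {db: None for db in POPFREQ_DBS}
        pf[POPFREQ_DBS[1]] = 1.2
        with pytest.raises(DataError):
            flag_rare(make_annotated(popfreq=pf), cfg)


class TestSeverity:
    def test_three_damaging_tools(self, cfg):
        v = make_annotated(cadd=32.0, sift=True, polyphen=True)
        assert flag_severe(v, cfg)

    def test_two_tools_despite_cadd_below_30(self, cfg):
        # CADD 29.6 misses its cutoff but SIFT + PolyPhen suffice
        v = make_annotated(cadd=29.6, sift=True, polyphen=True)
        assert flag_severe(v, cfg)

    def test_single_tool_is_not_severe(self, cfg):
        v = make_annotated(cadd=35.0, sift=False, polyphen=False)
        assert not flag_severe(v, cfg)

    def test_frameshift_without_scores_is_severe(self, cfg):
        v = make_annotated(consequence="frameshift")
        assert flag_severe(v, cfg)

    def test_missing_predictions_count_as_benign(self, cfg):
        v = make_annotated(cadd=None, sift=None, polyphen=None)
        assert not flag_severe(v, cfg)

    def test_synonymous_raises(self, cfg):
        with pytest.raises(DataError):
            flag_severe(make_annotated(consequence="synonymous"), cfg)


class TestCascade:
    def test_empty_input(self, cfg):
        res = run_cascade([], cfg)
        counts = res.stage_counts()
        assert (counts["n_mutations"] == 0).all()
        assert (counts["n_genes"] == 0).all()

    def test_rare_but_benign_in_p_only(self, cfg):
        call = make_call(60, 0, 45, 15)
        call = SomaticCall(
            candidate=call.candidate,
            fisher_p=call.fisher_p,
            normal_vaf=call.normal_vaf,
            tumor_vaf=call.tumor_vaf,
            qc_pass=apply_qc(call, cfg),
        )
        v = make_annotated(cadd=5.0, sift=False, polyphen=False, call=call)
        res = run_cascade([v], cfg)
        assert len(res.qc) == 1 and len(res.rare) == 1
        assert len(res.severe) == 0 and len(res.final) == 0

    def test_monotone_under_tightened_thresholds(self, annotated_variants, cfg):
        base = run_cascade(annotated_variants, cfg)
        tight = PipelineConfig(
            qc_p_max=0.01,
            qc_depth_min=20,
            qc_tumor_alt_min=5,
            rare_freq_max=0.0005,
            severe_tool_min=3,
        )
        res = run_cascade(annotated_variants, tight)
        for stage in ("qc", "rare", "severe", "final"):
            base_keys = {v.candidate.key for v in getattr(base, stage)}
            tight_keys = {v.candidate.key for v in getattr(res, stage)}
            assert tight_keys <= base_keys

    def test_nesting_of_stages(self, cascade):
        qc = {v.candidate.key for v in cascade.qc}
        p = {v.candidate.key for v in cascade.rare}
        s = {v.candidate.key for v in cascade.severe}
        f = {v.candidate.key for v in cascade.final}
        assert f == p & s and p <= qc and s <= qc

    def test_permutation_invariance(self, annotated_variants, cfg):
        res_fwd = run_cascade(annotated_variants, cfg)
        res_rev = run_cascade(list(reversed(annotated_variants)), cfg)
        for stage in ("qc", "rare", "severe", "final"):
            assert [v.candidate.key for v in getattr(res_fwd, stage)] == [
                v.candidate.key for v in getattr(res_rev, stage)
            ]

    def test_synonymous_discarded_before_filters(self, cfg):
        v = make_annotated(consequence="synonymous")
        res = run_cascade([v], cfg)
        assert res.n_synonymous_discarded == 1
        assert len(res.qc) == 0


class TestRecurrence:
    def test_shared_and_private_genes(self, cascade, plan):
        rec = recurrence_summary(cascade.final).set_index("gene")
        assert rec.loc[plan.hub_gene, "n_patients"] == plan.n_patients
        # hub gene sorts first (max recurrence)
        assert recurrence_summary(cascade.final)["gene"].iloc[0] == plan.hub_gene
        assert (rec["n_patients"] >= 1).all()

    def test_mutation_counts_conserved(self, cascade):
        rec = recurrence_summary(cascade.final)
        assert rec["n_mutations"].sum() == len(cascade.final)

    def test_empty_input(self):
        assert recurrence_summary([]).empty


def test_annotation_join_errors(cfg):
    calls = call_somatic([cand(40, 0, 30, 20)], cfg)
    ann = pd.DataFrame(
        [
            {
                "chrom": "chrX", "pos": 5, "ref": "A", "alt": "T",
                "gene": "G", "consequence": "missense",
                **{db: None for db in POPFREQ_DBS},
                "cadd_phred": None, "sift_damaging": None,
                "polyphen_damaging": None,
            }
        ]
    )
    with pytest.raises(DataError, match="no annotation"):
        annotate_calls(calls, ann, cfg)


def test_candidate_validation():
    with pytest.raises(DataError):
        cand(10, 0, 10, 5, ref="A", alt="A")
    with pytest.raises(DataError):
        cand(-1, 0, 10, 5)
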