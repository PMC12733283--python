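"""Prioritization cascade: filters, gene tiers, funnel, oracle equivalence."""
import pytest

from cleftvar.cascade import (CascadeConfig, GeneTier, VariantStatus,
                              classify_variant, prioritize_gene,
                              rarity_filter, run_cascade)
from cleftvar.consensus import consensus_vote
from cleftvar.simulate import SimConfig, simulate_annotation_grid
from cleftvar.types import (Consequence, GeneEvidence, LOF_CONSEQUENCES,
                            PredictionProfile, VariantRecord)


def _variant(vid="v1", gene="G", csq="missense", **kw):
    return VariantRecord(vid, gene, csq, **kw)


class TestRarityFilter:
    def test_ultra_rare_passes(self):
        assert rarity_filter(_variant(maf_nfe=8.48e-7))

    def test_clinvar_rescue_overrides_frequency(self):
        v = _variant(maf_nfe=4.72e-3, clinvar_lp_for_trait=True)
        assert rarity_filter(v)
        assert not rarity_filter(
            _variant(maf_nfe=4.72e-3, clinvar_lp_for_trait=False))
        assert not rarity_filter(
            v, CascadeConfig(clinvar_rescue=False))

    def test_missing_maf_counts_as_rare_by_default(self):
        assert rarity_filter(_variant())
        assert not rarity_filter(
            _variant(), CascadeConfig(treat_missing_maf_as_rare=False))

    def test_threshold_is_strict(self):
        assert not rarity_filter(_variant(maf_nfe=1e-4))
        assert rarity_filter(_variant(maf_nfe=0.99e-4))


class TestClassifyVariant:
    def test_synonymous_rejected_despite_high_cadd(self):
        ok, reason = classify_variant(
            _variant(csq="synonymous"),
            PredictionProfile("v1", cadd_phred=30.0))
        assert not ok and reason == "synonymous_or_other"

    def test_lof_qualifies_by_class_by_default(self):
        znf = PredictionProfile("v1", mutpred_lof=0.45)
        ok, _ = classify_variant(_variant(csq="stop_gain"), znf)
        assert ok

    def test_strict_mode_enforces_mutpred_threshold(self):
        znf = PredictionProfile("v1", mutpred_lof=0.45)
        ok, reason = classify_variant(_variant(csq="stop_gain"), znf,
                                      CascadeConfig(lof_strict=True))
        assert not ok and reason == "lof_strict"
        # a supported or unscored LoF variant still qualifies in strict mode
        ok, _ = classify_variant(_variant(csq="stop_gain"),
                                 PredictionProfile("v1", mutpred_lof=0.50),
                                 CascadeConfig(lof_strict=True))
        assert ok
        ok, _ = classify_variant(_variant(csq="frameshift"),
                                 PredictionProfile("v1"),
                                 CascadeConfig(lof_strict=True))
        assert ok


class TestPrioritizeGene:
    def test_prior_evidence_outranks_constraint(self):
        ryr1 = GeneEvidence("RYR1", 0.0, "very_likely_dominant", 0.987,
                            ofc_syndromic=True, ofc_nonsyndromic=True,
                            ofc_ko_mouse=True)
        assert prioritize_gene(ryr1) is GeneTier.PRIOR_OFC_EVIDENCE

    def test_constrained_dominant(self):
        ago1 = GeneEvidence("AGO1", 1.0, "very_likely_dominant", 0.999)
        assert prioritize_gene(ago1) is GeneTier.CONSTRAINED_DOMINANT

    def test_recessive_unconstrained_is_other(self):
        g = GeneEvidence("G", 0.0, "very_likely_recessive", 0.05)
        assert prioritize_gene(g) is GeneTier.OTHER

    def test_pli_boundary(self):
        at = GeneEvidence("G", 0.95, "likely_dominant", 0.7)
        below = GeneEvidence("G", 0.94, "likely_dominant", 0.7)
        assert prioritize_gene(at) is GeneTier.CONSTRAINED_DOMINANT
        assert prioritize_gene(below) is GeneTier.OTHER

    def test_missing_evidence_is_other(self):
        assert prioritize_gene(None) is GeneTier.OTHER


class TestRunCascadeOnFixture:
    def test_default_reproduces_final_set(self, final_set):
        result = run_cascade(final_set.variants, final_set.profiles,
                             final_set.evidence)
        assert len(result.passed) == 31
        assert len(result.passed_genes) == 30

    def test_strict_lof_drops_only_the_unsupported_stop_gain(self, final_set):
        result = run_cascade(final_set.variants, final_set.profiles,
                             final_set.evidence,
                             CascadeConfig(lof_strict=True))
        assert len(result.passed) == 30
        dropped = [c for c in result.classifications
                   if c.status is VariantStatus.EXCLUDED_LOF_STRICT]
        assert [c.gene for c in dropped] == ["ZNF319"]

    def test_empty_input_gives_zero_funnel(self):
        result = run_cascade([], {}, {})
        assert result.classifications == []
        assert all(v == 0 for v in result.funnel.values())

    def test_funnel_counts_non_increasing(self, final_set):
        result = run_cascade(final_set.variants, final_set.profiles,
                             final_set.evidence)
        counts = list(result.funnel.values())
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def grid():
    return simulate_annotation_grid(SimConfig(), seed=11, n_variants=300)


class TestConfigSensitivity:

    def test_raising_maf_threshold_never_loses_survivors(self, grid):
        loose = run_cascade(grid.variants, grid.profiles,
                            config=CascadeConfig(maf_threshold=1e-3))
        tight = run_cascade(grid.variants, grid.profiles,
                            config=CascadeConfig(maf_threshold=1e-4))
        assert {c.variant_id for c in tight.passed} <= \
            {c.variant_id for c in loose.passed}

    def test_raising_cadd_min_never_gains_survivors(self, grid):
        low = run_cascade(grid.variants, grid.profiles,
                          config=CascadeConfig(cadd_min=15.0))
        high = run_cascade(grid.variants, grid.profiles,
                           config=CascadeConfig(cadd_min=25.0))
        assert {c.variant_id for c in high.passed} <= \
            {c.variant_id for c in low.passed}

    def test_funnel_monotone_on_simulated_grid(self, grid):
        result = run_cascade(grid.variants, grid.profiles)
        counts = list(result.funnel.values())
        assert counts == sorted(counts, reverse=True)


def _brute_force_survivors(variants, profiles, config):
    """Independent per-variant re-evaluation of every published rule."""
    survivors = set()
    for v in variants:
        p = profiles[v.variant_id]
        if v.consequence in (Consequence.SYNONYMOUS, Consequence.OTHER):
            continue
        rare = (v.clinvar_lp_for_trait and config.clinvar_rescue) or (
            v.maf_nfe is None if config.treat_missing_maf_as_rare
            else False) or (v.maf_nfe is not None
                            and v.maf_nfe < config.maf_threshold)
        if not rare:
            continue
        if v.consequence is Consequence.MISSENSE:
            vote = consensus_vote(p)
            if p.cadd_phred is not None and p.cadd_phred >= config.cadd_min \
                    and vote.majority:
                survivors.add(v.variant_id)
        elif v.consequence is Consequence.SPLICING:
            if p.ada is not None and p.ada >= config.ada_min:
                survivors.add(v.variant_id)
        elif v.consequence in LOF_CONSEQUENCES:
            if config.lof_strict and p.mutpred_lof is not None \
                    and p.mutpred_lof < 0.50:
                continue
            survivors.add(v.variant_id)
    return survivors


@pytest.mark.parametrize("lof_strict", [False, True])
def test_cascade_matches_brute_force_on_small_inputs(lof_strict):
    """Staged cascade equals an independent flat re-check of every rule."""
    config = CascadeConfig(lof_strict=lof_strict)
    grid = simulate_annotation_grid(SimConfig(), seed=23, n_variants=50)
    result = run_cascade(grid.variants, grid.profiles, config=config)
    expected = _brute_force_survivors(grid.variants, grid.profiles, config)
    assert {c.variant_id for c in result.passed} == expected
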