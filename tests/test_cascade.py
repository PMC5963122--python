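"""Cascade predicates and the staged funnel."""

import dataclasses

import pytest

from exocascade.cascade import (
    CascadeConfig,
    consensus_damaging,
    is_rare,
    passes_combined_gate,
    passes_primary,
    run_cascade,
)
from exocascade.model import (
    AnnotationBundle,
    ConfigError,
    FuncClass,
    GenotypeCall,
    PredictorCall,
    PREDICTOR_TOOLS,
    Zygosity,
)
from exocascade.simulate import SimulationParams, simulate_cohort

CFG = CascadeConfig()


def ann(maf_by_db=None, n_damaging=0, n_unknown=0, cadd=None, revel=None):
    calls = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_damaging:
            calls[tool] = PredictorCall.DAMAGING
        elif i < n_damaging + n_unknown:
            calls[tool] = PredictorCall.UNKNOWN
        else:
            calls[tool] = PredictorCall.TOLERATED
    return AnnotationBundle(maf_by_db or {}, calls, cadd, revel)


class TestPrimary:
    def test_passing_het(self):
        assert passes_primary(GenotypeCall("S", Zygosity.HET, 99, 75), CFG)

    def test_zygosity_gate(self):
        assert not passes_primary(GenotypeCall("S", Zygosity.HOM_ALT, 99, 200), CFG)

    def test_gq_boundary(self):
        assert not passes_primary(GenotypeCall("S", Zygosity.HET, 98, 75), CFG)

    def test_missing_fields_fail(self):
        assert not passes_primary(GenotypeCall("S", Zygosity.HET, None, 75), CFG)
        assert not passes_primary(GenotypeCall("S", Zygosity.HET, 99, None), CFG)


class TestRarity:
    def test_rare_with_one_db_missing(self):
        assert is_rare(ann(maf_by_db={"kg1000": 0.0098}), CFG)

    def test_novel_variant_is_rare(self):
        assert is_rare(ann(), CFG)
        assert is_rare(None, CFG)

    def test_common_fails(self):
        assert not is_rare(ann(maf_by_db={"kg1000": 0.02}), CFG)

    def test_threshold_inclusive(self):
        assert is_rare(ann(maf_by_db={"kg1000": 0.01, "esp": 0.01}), CFG)

    def test_only_consulted_databases_count(self):
        # common in a database outside the configured pair does not disqualify
        assert is_rare(ann(maf_by_db={"gnomad": 0.2}), CFG)
        cfg4 = dataclasses.replace(
            CFG, maf_databases=("kg1000", "esp", "exac", "gnomad")
        )
        assert not is_rare(ann(maf_by_db={"gnomad": 0.2}), cfg4)


class TestConsensus:
    @pytest.mark.parametrize(
        "n_damaging,n_unknown,expected",
        [(4, 0, (4, True)), (3, 7, (3, False)), (10, 0, (10, True)), (0, 10, (0, False))],
    )
    def test_vote_counting(self, n_damaging, n_unknown, expected):
        assert consensus_damaging(ann(n_damaging=n_damaging, n_unknown=n_unknown), CFG) == expected

    def test_missing_annotation_is_zero_votes(self):
        assert consensus_damaging(None, CFG) == (0, False)


class TestCombinedGate:
    @pytest.mark.parametrize(
        "cadd,revel",
        [(17.33, 0.595), (24.3, 0.175), (22.2, 0.731)],
    )
    def test_known_risk_variants_fail(self, cadd, revel):
        """Published GBA/LRRK2 risk-factor score pairs all fail the joint
        CADD>20 and REVEL>=0.75 gate."""
        assert not passes_combined_gate(ann(cadd=cadd, revel=revel), CFG)

    def test_boundary_semantics(self):
        assert not passes_combined_gate(ann(cadd=20.0, revel=0.75), CFG)
        assert passes_combined_gate(ann(cadd=20.01, revel=0.75), CFG)
        assert not passes_combined_gate(ann(cadd=30.0, revel=0.7499), CFG)

    def test_missing_score_policies(self):
        missing_revel = ann(cadd=25.0)
        assert not passes_combined_gate(missing_revel, CFG)
        cfg_pass = dataclasses.replace(CFG, missing_score_policy="pass")
        assert passes_combined_gate(missing_revel, cfg_pass)
        cfg_ns = dataclasses.replace(CFG, missing_score_policy="pass_if_nonsense")
        assert passes_combined_gate(missing_revel, cfg_ns, FuncClass.NONSENSE)
        assert not passes_combined_gate(missing_revel, cfg_ns, FuncClass.MISSENSE)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"consensus_k": 0},
            {"consensus_k": 11},
            {"maf_max": 0.0},
            {"maf_max": 1.0},
            {"missing_score_policy": "maybe"},
            {"maf_databases": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            dataclasses.replace(CFG, **kwargs).validate()

    def test_round_trips_through_dict(self):
        cfg = CascadeConfig.from_dict(CFG.to_dict())
        assert cfg == CFG


def conjunction_oracle(variant, cfg=CFG):
    """One-shot conjunction of all cascade predicates, written independently."""
    carrier = any(
        c.zygosity is Zygosity.HET
        and c.gq is not None
        and c.gq >= cfg.gq_min
        and c.dp is not None
        and c.dp >= cfg.dp_min
        and c.ad1 is not None
        and c.ad2 is not None
        and abs(c.ad1 - c.ad2) / c.dp < cfg.ratio_max
        for c in variant.calls
    )
    if not carrier:
        return False
    if variant.site.func_class not in cfg.func_classes_kept:
        return False
    a = variant.annotation
    mafs = a.maf_by_db if a else {}
    if any(
        mafs.get(db) is not None and mafs[db] > cfg.maf_max
        for db in cfg.maf_databases
    ):
        return False
    votes = sum(
        1 for v in (a.predictor_calls.values() if a else ()) if v.value == "damaging"
    )
    if votes < cfg.consensus_k:
        return False
    if a is None or a.cadd_phred is None or a.revel is None:
        return False
    return a.cadd_phred > cfg.cadd_min and a.revel >= cfg.revel_min


class TestRunCascade:
    def test_empty_cohort(self):
        survivors, report = run_cascade([], CFG)
        assert survivors == []
        assert all(s.n_variants == 0 for s in report.stages)

    def test_planted_survives_and_is_tagged(self, make_variant):
        v = make_variant(
            n_damaging=5, cadd=25.0, revel=0.9, maf_by_db={"kg1000": 0.001}
        )
        survivors, report = run_cascade([v], CFG)
        assert len(survivors) == 1
        assert survivors[0].cascade_stage == 5
        assert report.counts() == [1, 1, 1, 1, 1, 1]

    def test_monotone_attrition_and_oracle_agreement(self):
        for seed in range(10):
            params = SimulationParams(
                n_samples=6, n_variants=300, seed=seed, n_planted=2
            )
            cohort, _ = simulate_cohort(params)
            survivors, report = run_cascade(cohort, CFG)
            counts = report.counts()
            assert all(x >= y for x, y in zip(counts, counts[1:]))
            expected = {v.site.key for v in cohort if conjunction_oracle(v)}
            assert {v.site.key for v in survivors} == expected

    def test_idempotent_on_survivors(self):
        cohort, _ = simulate_cohort(
            SimulationParams(n_samples=6, n_variants=300, seed=5, n_planted=2)
        )
        survivors, _ = run_cascade(cohort, CFG)
        again, report = run_cascade(survivors, CFG)
        assert [v.site.key for v in again] == [v.site.key for v in survivors]
        assert report.counts()[-1] == len(survivors)

    def test_input_not_mutated(self, make_variant):
        v = make_variant(n_damaging=5, cadd=25.0, revel=0.9)
        cohort = [v]
        run_cascade(cohort, CFG)
        assert cohort[0].cascade_stage is None

    def test_deterministic_report(self):
        cohort, _ = simulate_cohort(
            SimulationParams(n_samples=4, n_variants=200, seed=9)
        )
        _, r1 = run_cascade(cohort, CFG)
        _, r2 = run_cascade(cohort, CFG)
        assert r1 == r2

    def test_same_gene_recurrence_reported_not_filtered(self, make_variant):
        kwargs = dict(
            n_damaging=5, cadd=25.0, revel=0.9, gene="GENEX",
            calls=(("S1", "het", 99, 80, 40, 40),),
        )
        v1 = make_variant(pos=100, **kwargs)
        v2 = make_variant(pos=200, **kwargs)
        survivors, report = run_cascade([v1, v2], CFG)
        assert len(survivors) == 2
        assert report.n_patients_two_variants_same_gene == 1
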