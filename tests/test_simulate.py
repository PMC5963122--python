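"""Synthetic-cohort generator: determinism, construction guarantees, screen
evaluation against closed-form binomial oracles."""

import hashlib

import pytest
from scipy.stats import binom

from exocascade.cascade import CascadeConfig, run_cascade
from exocascade.model import ConfigError, ExocascadeError, Zygosity
from exocascade.simulate import (
    SimulationParams,
    evaluate_screen,
    generate_cohort,
    read_truth,
    simulate_cohort,
    write_truth,
)


def sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self, tmp_path):
        params = SimulationParams(n_samples=4, n_variants=40, seed=7, n_planted=2)
        v1, s1, t1 = generate_cohort(params, tmp_path / "a")
        v2, s2, t2 = generate_cohort(params, tmp_path / "b")
        assert sha(v1) == sha(v2)
        assert sha(s1) == sha(s2)
        assert t1 == t2

    def test_different_seeds_differ(self, tmp_path):
        p1 = SimulationParams(n_samples=4, n_variants=40, seed=7)
        p2 = SimulationParams(n_samples=4, n_variants=40, seed=8)
        v1, _, _ = generate_cohort(p1, tmp_path / "a")
        v2, _, _ = generate_cohort(p2, tmp_path / "b")
        assert sha(v1) != sha(v2)

    def test_planted_candidates_pass_cascade(self):
        params = SimulationParams(n_samples=8, n_variants=200, seed=7, n_planted=5)
        cohort, truth = simulate_cohort(params)
        planted = {t.key for t in truth if t.is_planted_candidate}
        assert len(planted) == 5
        survivors, _ = run_cascade(cohort, CascadeConfig())
        assert planted <= {v.site.key for v in survivors}

    def test_no_false_hets_when_fraction_zero(self):
        params = SimulationParams(
            n_samples=6, n_variants=100, seed=3, false_het_fraction=0.0
        )
        _, truth = simulate_cohort(params)
        assert not any(any(t.is_false_het.values()) for t in truth)

    def test_invalid_params_rejected_before_writing(self, tmp_path):
        params = SimulationParams(n_variants=10, n_planted=11)
        out = tmp_path / "never"
        with pytest.raises(ConfigError):
            generate_cohort(params, out)
        assert not out.exists()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"false_het_alt_fraction": 0.5},
            {"true_het_fraction": 0.7, "false_het_fraction": 0.7},
            {"dp_mean": 0.0},
            {"maf_tail_shape": 0.0},
        ],
    )
    def test_param_validation(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationParams(**kwargs).validate()

    def test_truth_tsv_round_trip(self, tmp_path):
        params = SimulationParams(n_samples=3, n_variants=20, seed=5, n_planted=1)
        _, _, truth = generate_cohort(params, tmp_path)
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert back == truth

    def test_stricter_thresholds_never_add_false_positives(self):
        """Tightening consensus_k, cadd_min or revel_min can only shrink the
        set of non-planted survivors."""
        cohort, truth = simulate_cohort(
            SimulationParams(n_samples=6, n_variants=400, seed=21, n_planted=3)
        )
        planted = {t.key for t in truth if t.is_planted_candidate}
        base_cfg = CascadeConfig()
        base, _ = run_cascade(cohort, base_cfg)
        base_fp = {v.site.key for v in base} - planted
        import dataclasses

        for kwargs in ({"consensus_k": 6}, {"cadd_min": 25.0}, {"revel_min": 0.9}):
            tighter, _ = run_cascade(
                cohort, dataclasses.replace(base_cfg, **kwargs)
            )
            assert {v.site.key for v in tighter} - planted <= base_fp


class TestEvaluateScreen:
    def test_matches_binomial_oracles_at_fixed_depth(self):
        """At DP=100 the screen's operating point has a closed form: a het is
        rejected iff its minor depth leaves |AD1-AD2|/DP >= 0.3, i.e. the
        binomial tail below 35 (or above 65)."""
        params = SimulationParams(
            n_samples=25,
            n_variants=200,
            seed=123,
            dp_mean=100.0,
            dp_dispersion=0.0,
            true_het_fraction=0.5,
            false_het_fraction=0.5,
            false_het_alt_fraction=0.1,
            low_gq_fraction=0.0,
            n_planted=0,
        )
        cohort, truth = simulate_cohort(params)
        sens, spec = evaluate_screen(cohort, truth)
        p_keep_true = 1.0 - (binom.cdf(35, 100, 0.5) + binom.sf(64, 100, 0.5))
        p_reject_false = binom.cdf(35, 100, 0.1) + binom.sf(64, 100, 0.1)
        n_calls = params.n_samples * params.n_variants
        se_sens = (p_keep_true * (1 - p_keep_true) / (n_calls / 2)) ** 0.5
        se_spec = (p_reject_false * (1 - p_reject_false) / (n_calls / 2)) ** 0.5
        assert abs(sens - p_keep_true) <= 3 * se_sens + 1e-9
        assert abs(spec - p_reject_false) <= 3 * se_spec + 1e-9
        assert sens >= 0.99 and spec >= 0.95

    def test_true_hets_only(self):
        params = SimulationParams(
            n_samples=10,
            n_variants=100,
            seed=9,
            dp_mean=100.0,
            dp_dispersion=0.0,
            true_het_fraction=1.0,
            false_het_fraction=0.0,
            low_gq_fraction=0.0,
            n_planted=0,
        )
        cohort, truth = simulate_cohort(params)
        sens, spec = evaluate_screen(cohort, truth)
        assert sens >= 0.99
        assert spec == 1.0  # vacuous: no false hets to reject

    def test_empty_cohort_is_error(self):
        with pytest.raises(ExocascadeError):
            evaluate_screen([], [])

    def test_truth_mismatch_is_error(self):
        cohort, truth = simulate_cohort(
            SimulationParams(n_samples=2, n_variants=5, seed=1)
        )
        with pytest.raises(ExocascadeError):
            evaluate_screen(cohort, truth[:-1])

    def test_via_vcf_path(self, tmp_path):
        params = SimulationParams(n_samples=4, n_variants=50, seed=13)
        vcf_path, _, truth = generate_cohort(params, tmp_path)
        sens, spec = evaluate_screen(vcf_path, truth)
        cohort, _ = simulate_cohort(params)
        assert (sens, spec) == evaluate_screen(cohort, truth)


class TestSimulatedStructure:
    def test_true_zygosity_consistent_with_calls(self):
        cohort, truth = simulate_cohort(
            SimulationParams(n_samples=5, n_variants=100, seed=31)
        )
        by_key = {t.key: t for t in truth}
        for v in cohort:
            t = by_key[v.site.key]
            for c in v.calls:
                if t.is_false_het[c.sample_id]:
                    # caller says het, truth says hom
                    assert c.zygosity is Zygosity.HET
                    assert t.true_zygosity[c.sample_id] is not Zygosity.HET
                else:
                    assert t.true_zygosity[c.sample_id] is c.zygosity
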