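import numpy as np
import pytest

import s2f.synthetic_data as sd


class TestSimulateReference:
    def test_deterministic_given_seed(self):
        a = sd.simulate_reference(8, 0.5, seed=1)
        b = sd.simulate_reference(8, 0.5, seed=1)
        assert a.sequence == b.sequence

    def test_different_seeds_differ(self):
        a = sd.simulate_reference(200, 0.5, seed=1)
        b = sd.simulate_reference(200, 0.5, seed=2)
        assert a.sequence != b.sequence

    def test_gc_fraction_within_binomial_bound(self):
        # 95% binomial bound at n=4096: |p_hat - 0.4| < 1.96*sqrt(0.4*0.6/4096) ~ 0.015
        ref = sd.simulate_reference(4096, 0.4, seed=7)
        gc = sum(ref.sequence.count(b) for b in "GC") / 4096
        assert abs(gc - 0.4) < 0.03

    def test_tss_at_floor_half_length(self):
        assert sd.simulate_reference(11, 0.5, seed=0).tss_offset == 5
        assert sd.simulate_reference(4096, 0.5, seed=0).tss_offset == 2048

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (10, 0.0), (10, 1.0)])
    def test_invalid_arguments_rejected(self, length, gc):
        with pytest.raises(ValueError):
            sd.simulate_reference(length, gc, seed=1)

    def test_one_hot_round_trip(self):
        ref = sd.simulate_reference(64, 0.5, seed=3)
        oh = ref.one_hot()
        assert oh.shape == (64, 4)
        assert np.all(oh.sum(axis=1) == 1)
        decoded = "".join("ACGT"[i] for i in oh.argmax(axis=1))
        assert decoded == ref.sequence


class TestSimulateCohort:
    def test_no_monomorphic_records(self):
        ref = sd.simulate_reference(2048, seed=0)
        vt = sd.simulate_cohort(ref, 50, 200, seed=1)
        assert np.all(vt.maf > 0)
        assert np.all(vt.recompute_maf() > 0)

    def test_dosage_mean_matches_allele_frequency(self):
        ref = sd.simulate_reference(2048, seed=0)
        vt = sd.simulate_cohort(ref, 300, 100, seed=2)
        af = vt.dosages.mean(axis=0) / 2.0
        assert np.allclose(af, vt.alt_allele_frequency(), atol=1e-12)
        assert np.allclose(vt.maf, np.minimum(af, 1 - af), atol=1e-12)

    def test_ref_alleles_match_reference(self):
        ref = sd.simulate_reference(2048, seed=0)
        vt = sd.simulate_cohort(ref, 40, 60, seed=3)
        vt.validate_against_reference(ref)  # does not raise

    def test_rare_variant_count_grows_with_cohort_size(self):
        # resample property over 5 seeds: strictly more MAF<0.01 variants at
        # n=10,000 than at n=500
        ref = sd.simulate_reference(4096, seed=0)
        for seed in range(5):
            big = sd.simulate_cohort(ref, 10_000, 200, seed=seed)
            small = sd.simulate_cohort(ref, 500, 200, seed=seed)
            n_big = int(np.sum(big.maf < 0.01))
            n_small = int(np.sum(small.maf < 0.01))
            assert n_big > n_small

    def test_too_many_sites_rejected(self):
        ref = sd.simulate_reference(64, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_cohort(ref, 10, 64, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_cohort(ref, 1, 10, seed=0)

    def test_block_ld_mode_creates_correlated_columns(self):
        ref = sd.simulate_reference(2048, seed=0)
        vt = sd.simulate_cohort(ref, 2000, 40, seed=4, ld_block_size=4,
                                ld_flip_prob=0.02)
        X = vt.dosages.astype(float)
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert r**2 > 0.5

    def test_nested_subsets(self):
        subsets = sd.nested_subsets(5000, [200, 500, 1000, 5000])
        assert set(subsets[200]) < set(subsets[500]) < set(subsets[1000]) < set(subsets[5000])
        with pytest.raises(ValueError):
            sd.nested_subsets(100, [200])


class TestPlantEffects:
    def _cohort(self, seed=0, n=2000, n_sites=120):
        ref = sd.simulate_reference(2048, seed=seed)
        return sd.simulate_cohort(ref, n, n_sites, seed=seed + 1)

    def test_zero_heritability_zeroes_all_betas(self):
        vt = self._cohort()
        truth = sd.plant_effects(vt, 10, 0.0, seed=2)
        assert np.all(truth.beta == 0.0)
        assert truth.sigma_e == 1.0

    def test_realized_h2_matches_target(self):
        vt = self._cohort()
        truth = sd.plant_effects(vt, 15, 0.5, rare_var_share=0.5, seed=3)
        assert abs(sd.realized_h2(truth, vt) - 0.5) < 0.05

    def test_h2_calibration_across_seeds(self):
        # mean realized h2 over 10 seeds at n=2,000 within +/- 0.03 of target
        vals = []
        for seed in range(10):
            vt = self._cohort(seed=seed * 17)
            truth = sd.plant_effects(vt, 12, 0.4, seed=seed)
            vals.append(sd.realized_h2(truth, vt))
        assert abs(np.mean(vals) - 0.4) < 0.03

    def test_rare_share_of_genetic_variance(self):
        vt = self._cohort()
        truth = sd.plant_effects(vt, 20, 0.5, rare_var_share=0.5, seed=4)
        X = vt.dosages.astype(float)
        rare = vt.maf < 0.05
        v_rare = (X[:, rare] @ truth.beta[rare]).var()
        g = truth.genetic_component(vt)
        assert abs(v_rare / g.var() - 0.5) < 0.05

    def test_interaction_term_is_literal(self):
        vt = self._cohort()
        c = 0.3
        with_int = sd.plant_effects(vt, 5, 0.5, interactions=[(0, 1, c)], seed=5)
        without = sd.SyntheticTruth(
            causal_indices=with_int.causal_indices, beta=with_int.beta,
            interaction_pairs=[], h2=0.5, sigma_e=with_int.sigma_e,
            covariate_effects=with_int.covariate_effects)
        diff = with_int.genetic_component(vt) - without.genetic_component(vt)
        expected = c * vt.dosages[:, 0] * vt.dosages[:, 1]
        assert np.allclose(diff, expected, atol=1e-12)

    def test_causal_subset_of_records(self):
        vt = self._cohort()
        truth = sd.plant_effects(vt, 7, 0.3, seed=6)
        assert truth.causal_indices.size == 7
        assert truth.causal_indices.max() < vt.n_variants
        assert np.all(truth.beta[np.setdiff1d(np.arange(vt.n_variants),
                                              truth.causal_indices)] == 0)

    def test_explicit_causal_indices(self):
        vt = self._cohort()
        truth = sd.plant_effects(vt, 0, 0.4, seed=7, causal_indices=[3, 8, 11])
        assert list(truth.causal_indices) == [3, 8, 11]

    def test_infeasible_rare_share_rejected(self):
        vt = self._cohort()
        common_only = np.flatnonzero(vt.maf >= 0.1)[:5]
        with pytest.raises(ValueError):
            sd.plant_effects(vt, 0, 0.5, rare_var_share=0.5, seed=8,
                             causal_indices=common_only)

    def test_invalid_h2_rejected(self):
        vt = self._cohort()
        for h2 in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                sd.plant_effects(vt, 5, h2, seed=9)


class TestSimulateExpression:
    def _setup(self, seed=0):
        ref = sd.simulate_reference(1024, seed=seed)
        vt = sd.simulate_cohort(ref, 500, 60, seed=seed + 1)
        truth = sd.plant_effects(vt, 8, 0.5, seed=seed + 2)
        return vt, truth

    def test_noise_free_expression_is_linear_in_dosages(self):
        vt, truth = self._setup()
        ds = sd.simulate_expression(truth, vt, sigma_e=0.0, seed=3)
        expected = vt.dosages.astype(float) @ truth.beta
        assert np.allclose(ds.expression, expected, atol=1e-12)

    def test_seeds_change_noise_not_genetic_component(self):
        vt, truth = self._setup()
        a = sd.simulate_expression(truth, vt, seed=1)
        b = sd.simulate_expression(truth, vt, seed=2)
        assert not np.allclose(a.expression, b.expression)
        # noise-free versions coincide regardless of seed
        a0 = sd.simulate_expression(truth, vt, sigma_e=0.0, seed=1)
        b0 = sd.simulate_expression(truth, vt, sigma_e=0.0, seed=2)
        assert np.allclose(a0.expression, b0.expression)

    def test_negative_sigma_rejected(self):
        vt, truth = self._setup()
        with pytest.raises(ValueError):
            sd.simulate_expression(truth, vt, sigma_e=-0.1, seed=0)

    def test_protein_altering_fraction_binomial(self):
        vt, truth = self._setup()
        counts = []
        for seed in range(5):
            ds = sd.simulate_expression(truth, vt, seed=seed,
                                        protein_altering_fraction=0.1)
            counts.append(len(ds.consequence_table))
        total, n = sum(counts), 5 * vt.n_individuals
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(total - 0.1 * n) < 4 * sigma

    def test_covariate_effects_applied(self):
        vt, truth = self._setup()
        cov, names = sd.simulate_covariates(vt.n_individuals, seed=5)
        ds = sd.simulate_expression(truth, vt, cov, names, sigma_e=0.0, seed=6)
        base = sd.simulate_expression(truth, vt, sigma_e=0.0, seed=6)
        delta = ds.expression - base.expression
        assert np.allclose(delta, cov @ np.full(cov.shape[1], sd.DEFAULT_COVARIATE_EFFECT))


class TestSimulateAnnotations:
    def test_tiling_track_partitions_window(self):
        ref = sd.simulate_reference(2048, seed=0)
        tiling, _, _ = sd.simulate_annotations(ref, seed=1)
        assert tiling.tiling  # validated as disjoint cover in __post_init__
        covered = sum(e - s for s, e, _ in tiling.intervals)
        assert covered == ref.length

    def test_state_coverage_near_target(self):
        ref = sd.simulate_reference(4096, seed=0)
        tiling, _, _ = sd.simulate_annotations(ref, state_config={"Enh": 0.5},
                                               seed=2, mean_interval=128)
        cov = tiling.coverage_fraction("Enh")
        assert abs(cov - 0.5) < 128 * 3 / 4096  # within a few intervals' rounding

    def test_pwm_columns_sum_to_one(self):
        ref = sd.simulate_reference(1024, seed=0)
        _, _, pwms = sd.simulate_annotations(ref, n_pwms=4, seed=3)
        for p in pwms:
            assert np.allclose(p.matrix.sum(axis=0), 1.0, atol=1e-9)
            assert np.all(p.effective_matrix() > 0)

    def test_overfull_coverage_rejected(self):
        ref = sd.simulate_reference(1024, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_annotations(ref, state_config={"A": 0.7, "B": 0.5}, seed=0)

    def test_deterministic(self):
        ref = sd.simulate_reference(1024, seed=0)
        t1, c1, p1 = sd.simulate_annotations(ref, seed=9)
        t2, c2, p2 = sd.simulate_annotations(ref, seed=9)
        assert t1.intervals == t2.intervals
        assert c1.intervals == c2.intervals
        assert all(np.allclose(a.matrix, b.matrix) for a, b in zip(p1, p2))


class TestTypes:
    def test_reference_window_invariants(self):
        with pytest.raises(ValueError):
            sd.ReferenceWindow("c", 0, 4, 0, "ACGTT")
        with pytest.raises(ValueError):
            sd.ReferenceWindow("c", 0, 4, 4, "ACGT")
        with pytest.raises(ValueError):
            sd.ReferenceWindow("c", 0, 4, 0, "ACGN")

    def test_variant_record_ref_ne_alt(self):
        with pytest.raises(ValueError):
            sd.VariantRecord(pos=0, ref="A", alt="A")

    def test_duplicate_record_rejected(self):
        recs = [sd.VariantRecord(0, "A", "G"), sd.VariantRecord(0, "A", "G")]
        with pytest.raises(ValueError):
            sd.VariantTable(records=recs, dosages=np.zeros((2, 2)), maf=np.zeros(2))

    def test_annotation_track_gap_rejected(self):
        with pytest.raises(ValueError):
            sd.AnnotationTrack([(0, 5, "a"), (6, 10, "b")], window_length=10, tiling=True)

    def test_pwm_column_sums_enforced(self):
        bad = np.full((4, 3), 0.3)
        with pytest.raises(ValueError):
            sd.PWM("m", bad)
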