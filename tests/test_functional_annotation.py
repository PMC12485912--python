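import itertools

import numpy as np
import pytest
from scipy import stats

import s2f.synthetic_data as sd
from conftest import fit_baseline, make_gene, train_fast
from s2f.functional_annotation import (
    CCRE_PRIORITY,
    SCORE_STEP,
    aggregate_ld_redundancy,
    benjamini_hochberg,
    ccre_overlap_fraction,
    chromhmm_enrichment,
    estimate_background,
    ld_redundancy,
    log_odds_lattice,
    motif_effects,
    null_score_distribution,
    score_pvalue,
)
from s2f.ism_hsv import HSVMember, HSVSet, hsv_from_elastic_net, ism_map, select_hsv
from s2f.synthetic_data import PWM, AnnotationTrack, VariantRecord, VariantTable


def hsv_at(positions, gene="gene"):
    members = [HSVMember(variant_index=k, pos=int(p), score=1.0, rank=k + 1)
               for k, p in enumerate(positions)]
    return HSVSet(gene=gene, n_target=len(members), members=members)


def two_state_track(L, frac):
    cut = int(frac * L)
    return AnnotationTrack([(0, cut, "state"), (cut, L, "other")],
                           window_length=L, tiling=True)


class TestChromhmmEnrichment:
    def test_observed_equals_expected_ratio_one(self):
        track = two_state_track(100, 0.5)
        hsv = hsv_at([1, 2, 3, 4, 5, 60, 70, 80, 90, 99])  # 5 of 10 in state
        res = {r.state: r for r in chromhmm_enrichment({"g": hsv}, {"g": track})}
        assert res["state"].ratio == 1.0

    def test_excess_observed(self):
        track = two_state_track(100, 0.5)
        hsv = hsv_at([1, 2, 3, 4, 5, 6, 7, 8, 60, 70])  # 8 of 10 in state
        res = {r.state: r for r in chromhmm_enrichment({"g": hsv}, {"g": track})}
        assert res["state"].ratio == pytest.approx(1.6)

    def test_aggregation_across_genes_before_ratio(self):
        t1 = two_state_track(100, 0.5)
        t2 = two_state_track(100, 0.25)
        h1 = hsv_at([1, 2, 60, 70])       # 2 observed, expected 2
        h2 = hsv_at([1, 2, 3, 4])         # 4 observed, expected 1
        res = {r.state: r for r in chromhmm_enrichment({"a": h1, "b": h2},
                                                       {"a": t1, "b": t2})}
        assert res["state"].observed == 6
        assert res["state"].expected == pytest.approx(3.0)
        assert res["state"].ratio == pytest.approx(2.0)

    def test_state_groups_mapping(self):
        track = AnnotationTrack([(0, 30, "EnhA1"), (30, 60, "EnhA2"), (60, 100, "Quies")],
                                window_length=100, tiling=True)
        hsv = hsv_at([5, 35, 65, 75])
        groups = {"EnhA1": "enhancer", "EnhA2": "enhancer"}
        res = {r.state: r for r in chromhmm_enrichment({"g": hsv}, {"g": track},
                                                       state_groups=groups)}
        assert set(res) == {"enhancer", "other"}
        assert res["enhancer"].observed == 2

    def test_hsv_outside_window_rejected(self):
        track = two_state_track(100, 0.5)
        with pytest.raises(ValueError, match="outside window"):
            chromhmm_enrichment({"g": hsv_at([150])}, {"g": track})

    def test_non_tiling_track_rejected(self):
        track = AnnotationTrack([(0, 10, "x")], window_length=100, tiling=False)
        with pytest.raises(ValueError, match="tile"):
            chromhmmify = chromhmm_enrichment({"g": hsv_at([5])}, {"g": track})

    def test_uniform_placement_calibration(self):
        # Monte-Carlo null: mean ratio in [0.9, 1.1] for a 30%-coverage state
        L = 1000
        track = two_state_track(L, 0.3)
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(200):
            hsv = hsv_at(rng.integers(0, L, size=20))
            res = {r.state: r for r in chromhmm_enrichment({"g": hsv}, {"g": track})}
            ratios.append(res["state"].ratio)
        assert 0.9 < np.mean(ratios) < 1.1


class TestCcreOverlap:
    def test_no_intervals_fraction_zero(self):
        track = AnnotationTrack([], window_length=100)
        out = ccre_overlap_fraction({"g": hsv_at([5, 10])}, {"g": track})
        assert out["any"] == 0.0
        assert out["none"] == 1.0

    def test_all_in_one_class(self):
        track = AnnotationTrack([(0, 50, "pELS")], window_length=100)
        out = ccre_overlap_fraction({"g": hsv_at([5, 10, 20])}, {"g": track})
        assert out["any"] == 1.0
        assert out["pELS"] == 1.0

    def test_priority_resolution_with_warning(self):
        track = AnnotationTrack([(0, 50, "dELS"), (10, 30, "PLS")], window_length=100)
        with pytest.warns(UserWarning, match="priority"):
            out = ccre_overlap_fraction({"g": hsv_at([15])}, {"g": track})
        assert out["PLS"] == 1.0
        assert out["dELS"] == 0.0

    def test_random_placement_matches_coverage(self):
        L = 2000
        track = AnnotationTrack([(0, 500, "dELS")], window_length=L)  # coverage 0.25
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(200):
            hsv = hsv_at(rng.integers(0, L, size=20))
            fracs.append(ccre_overlap_fraction({"g": hsv}, {"g": track})["any"])
        assert abs(np.mean(fracs) - 0.25) < 0.02


def uniform_pwm_scores(pwm, bg=None):
    """Exhaustive null distribution oracle: enumerate all w-mers."""
    bg = np.full(4, 0.25) if bg is None else bg
    lat = log_odds_lattice(pwm, bg)
    w = pwm.width
    dist = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(lat[b, j] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        dist[s] = dist.get(s, 0.0) + p
    return dist


class TestPwmNullDistribution:
    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        cols = rng.dirichlet(np.ones(4) * 0.5, size=width).T
        pwm = PWM("m", cols, pseudocount=1e-3)
        bg = np.full(4, 0.25)
        lat = log_odds_lattice(pwm, bg)
        offset, probs = null_score_distribution(lat, bg)
        brute = uniform_pwm_scores(pwm)
        tv = 0.0
        for s, p in brute.items():
            tv += abs(p - probs[s - offset])
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert tv < 1e-9

    def test_consensus_pvalue_one_in_64(self):
        # width-3 PWM with a unique consensus: P(score >= max) = 1/64
        m = np.full((4, 3), 0.02)
        for j, b in enumerate((0, 2, 3)):  # consensus AGT
            m[b, j] = 0.94
        pwm = PWM("consensus", m, pseudocount=0.0)
        bg = np.full(4, 0.25)
        lat = log_odds_lattice(pwm, bg)
        offset, probs = null_score_distribution(lat, bg)
        smax = int(lat[(0, 2, 3), (0, 1, 2)].sum())
        assert score_pvalue(smax, offset, probs) == pytest.approx(1 / 64)

    def test_pvalue_extremes(self):
        pwm = PWM("m", np.full((4, 2), 0.25))
        bg = np.full(4, 0.25)
        lat = log_odds_lattice(pwm, bg)
        offset, probs = null_score_distribution(lat, bg)
        assert score_pvalue(-10_000, offset, probs) == 1.0
        assert score_pvalue(10_000, offset, probs) == 0.0

    def test_zero_probability_cell_without_pseudocount_rejected(self):
        m = np.zeros((4, 2))
        m[0] = 1.0
        with pytest.raises(ValueError, match="pseudocount"):
            PWM("m", m, pseudocount=0.0)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=40) ** 2
        q = benjamini_hochberg(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    def test_empty_input(self):
        assert benjamini_hochberg(np.array([])).size == 0


class TestMotifEffects:
    def _scene(self, seq="A" * 61, snp_pos=30, alt="C"):
        ref = sd.ReferenceWindow("c", 0, len(seq), len(seq) // 2, seq)
        rec = VariantRecord(snp_pos, seq[snp_pos], alt)
        vt = VariantTable(records=[rec], dosages=np.array([[1]], dtype=np.int8),
                          maf=np.array([0.25]))
        hsv = hsv_at([snp_pos])
        return ref, vt, hsv

    def test_delta_s_hand_value(self):
        # motif column A=0.85, C=0.05 at the SNP: A->C gives
        # deltaS = log2(0.05 / 0.85) ~ -4.087 bits
        ref, vt, hsv = self._scene()
        width = 5
        m = np.full((4, width), 0.02)
        m[0] = 0.94  # strongly A-matching everywhere
        m[:, 2] = [0.85, 0.05, 0.05, 0.05]  # the assayed column
        pwm = PWM("toy", m, pseudocount=0.0)
        calls, _ = motif_effects(hsv, vt, ref, [pwm], background=np.full(4, 0.25),
                                 prefilter_p=1.0)
        expected = np.log2(0.05 / 0.85)
        # exact on the 0.01-bit lattice
        assert calls[0].deltaS == pytest.approx(round(expected / SCORE_STEP) * SCORE_STEP)

    def test_loss_call_when_alt_destroys_motif(self):
        # width 8 so the consensus p-value 4^-8 clears the 1e-4 prefilter
        ref, vt, hsv = self._scene()
        m = np.full((4, 8), 1e-4 / 3)
        m[0] = 1 - 1e-4  # near-degenerate A-consensus motif
        m /= m.sum(axis=0, keepdims=True)
        pwm = PWM("amotif", m, pseudocount=0.0)
        calls, frac = motif_effects(hsv, vt, ref, [pwm], background=np.full(4, 0.25))
        assert calls[0].klass == "loss"
        assert frac == 1.0

    def test_gain_call_symmetry(self):
        # reference is all-A except the SNP introduces the C the motif wants
        seq = "A" * 61
        ref, vt, hsv = self._scene(seq=seq, snp_pos=30, alt="C")
        m = np.full((4, 9), 1e-4 / 3)
        m[0] = 1 - 1e-4
        m[:, 4] = [1e-4 / 3, 1 - 1e-4, 1e-4 / 3, 1e-4 / 3]  # wants C at centre
        m /= m.sum(axis=0, keepdims=True)
        pwm = PWM("cmotif", m, pseudocount=0.0)
        calls, _ = motif_effects(hsv, vt, ref, [pwm], background=np.full(4, 0.25))
        assert calls[0].klass == "gain"

    def test_none_when_no_significant_hit(self):
        ref, vt, hsv = self._scene()
        pwm = PWM("flat", np.full((4, 4), 0.25))  # uninformative motif
        calls, frac = motif_effects(hsv, vt, ref, [pwm], background=np.full(4, 0.25))
        assert calls[0].klass == "none"
        assert frac == 0.0

    def test_collapse_keeps_max_abs_delta(self):
        ref, vt, hsv = self._scene()
        strong = np.full((4, 8), 1e-4 / 3)
        strong[0] = 1 - 1e-4
        strong /= strong.sum(axis=0, keepdims=True)
        weak = np.full((4, 8), 0.02)
        weak[0] = 0.94
        calls, _ = motif_effects(
            hsv, vt, ref,
            [PWM("weak", weak, pseudocount=0.0), PWM("strong", strong, pseudocount=0.0)],
            background=np.full(4, 0.25))
        assert calls[0].motif_id == "strong"

    def test_background_estimated_from_window(self):
        ref = sd.simulate_reference(400, gc=0.6, seed=3)
        bg = estimate_background(ref)
        assert bg.sum() == pytest.approx(1.0)
        assert bg[1] + bg[2] > 0.5  # GC-rich window


class TestLdRedundancy:
    def _vt(self, dosages):
        d = np.asarray(dosages, dtype=np.int8)
        records = [VariantRecord(p, "A", "G") for p in range(d.shape[1])]
        vt = VariantTable(records=records, dosages=d, maf=np.zeros(d.shape[1]))
        vt.maf = vt.recompute_maf()
        return vt

    def test_identical_columns_full_redundancy(self):
        col = np.random.default_rng(0).binomial(2, 0.3, size=200)
        vt = self._vt(np.column_stack([col, col]))
        res = ld_redundancy(hsv_at([0, 1]), vt)
        assert res.r2[0, 1] == pytest.approx(1.0)
        assert res.redundancy_fraction == 1.0

    def test_independent_columns_no_redundancy(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(10_000, 4))
        vt = self._vt(X)
        res = ld_redundancy(hsv_at([0, 1, 2, 3]), vt)
        off = res.r2 - np.eye(4)
        assert off.max() < 0.01
        assert res.redundancy_fraction == 0.0

    def test_r2_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, rng.uniform(0.05, 0.5, size=6), size=(500, 6))
        vt = self._vt(X)
        res = ld_redundancy(hsv_at(list(range(6))), vt)
        for i in range(6):
            for j in range(i + 1, 6):
                r, _ = stats.pearsonr(X[:, i], X[:, j])
                assert abs(res.r2[i, j] - r**2) < 1e-10
        assert np.allclose(res.r2, res.r2.T)
        assert np.all(np.diag(res.r2) == 1.0)

    def test_zero_variance_column_warns(self):
        X = np.column_stack([np.zeros(100, dtype=np.int8) + 1,
                             np.random.default_rng(3).binomial(2, 0.3, 100)])
        vt = self._vt(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ld_redundancy(hsv_at([0, 1]), vt)
        assert res.r2[0, 1] == 0.0

    def test_single_hsv_fraction_zero(self):
        vt = self._vt(np.random.default_rng(4).binomial(2, 0.3, size=(50, 2)))
        assert ld_redundancy(hsv_at([0]), vt).redundancy_fraction == 0.0

    def test_aggregation_across_genes(self):
        col = np.random.default_rng(5).binomial(2, 0.3, size=100)
        vt_red = self._vt(np.column_stack([col, col]))
        rng = np.random.default_rng(6)
        vt_ind = self._vt(rng.binomial(2, 0.3, size=(100, 2)))
        r1 = ld_redundancy(hsv_at([0, 1]), vt_red)
        r2_ = ld_redundancy(hsv_at([0, 1]), vt_ind)
        assert aggregate_ld_redundancy([r1, r2_]) == pytest.approx(0.5)

    def test_block_ld_direction_en_vs_surrogate(self):
        # causal variants planted inside LD blocks, mixing learnable rare and
        # common sites: the l1/l2 baseline keeps more correlated common tags
        # than the ISM ranking, which upweights rare sites with few LD
        # partners (direction only, averaged over seeds)
        deep_fr, en_fr = [], []
        for seed in range(5):
            s = 7000 + seed * 131
            probe = make_gene(seed=s, length=1024, n=1500, n_sites=120, h2=0.6,
                              ld_block_size=4, ld_flip_prob=0.03)
            rng = np.random.default_rng(s + 6)
            rare_pool = np.flatnonzero((probe.vt.maf >= 0.01) & (probe.vt.maf < 0.05))
            common_pool = np.flatnonzero(probe.vt.maf >= 0.1)
            causal = np.concatenate([
                rng.choice(rare_pool, min(10, len(rare_pool)), replace=False),
                rng.choice(common_pool, 6, replace=False),
            ])
            bundle = make_gene(seed=s, length=1024, n=1500, n_sites=120, h2=0.6,
                               causal_indices=causal,
                               ld_block_size=4, ld_flip_prob=0.03)
            model = train_fast(bundle, seed=seed, epochs=25)
            en = fit_baseline(bundle)
            im = ism_map(model, bundle.ref.one_hot(),
                         covariates=bundle.covariates.mean(axis=0),
                         positions=bundle.vt.positions)
            hsv_deep = select_hsv(im, bundle.vt, en.n_nonzero)
            hsv_en = hsv_from_elastic_net(en, bundle.vt)
            deep_fr.append(ld_redundancy(hsv_deep, bundle.vt).redundancy_fraction)
            en_fr.append(ld_redundancy(hsv_en, bundle.vt).redundancy_fraction)
        assert np.mean(en_fr) > np.mean(deep_fr)
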