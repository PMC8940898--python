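"""Elastic-net expression models, CV heritability, segment comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import segment_scan as ss
from segment_scan.models import SegmentNullResult, TrainingConfig


def _single_tissue(geno, y, name="tissueA"):
    expr = ss.ExpressionMatrix(
        tissue=name,
        values=pd.DataFrame([y], index=["gene1"], columns=geno.samples),
    )
    return {name: expr}


class TestCvPerformance:
    def test_affine_invariance(self):
        r, r2, p = ss.cv_performance(
            np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])
        )
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_sign_retained_for_negative_correlation(self):
        obs = np.array([1.0, 2, 3, 4, 5])
        r, r2, _ = ss.cv_performance(obs, -obs)
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_zero_variance_prediction_scores_zero(self):
        r, r2, p = ss.cv_performance(np.array([1.0, 2, 3]), np.zeros(3))
        assert (r, r2, p) == (0.0, 0.0, 1.0)

    def test_null_r2_small_at_large_n(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            r, r2, _ = ss.cv_performance(
                rng.standard_normal(1000), rng.standard_normal(1000)
            )
            hits += r2 < 0.01
        assert hits >= 190  # 95% of draws


class TestIGeneFilter:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.2, 0.01, True),
            (0.1, 1e-9, False),   # boundary: strict inequality on r
            (0.2, 0.05, False),   # boundary: strict inequality on p
            (-0.5, 1e-9, False),  # signed r
        ],
    )
    def test_rule(self, r, p, expected):
        m = ss.ExpressionModel(
            gene="g", tissue="t", weights={}, scope="full",
            cv_r=r, cv_r2=r**2, cv_p=p, n_predictors=0,
        )
        assert ss.igene_filter(m) is expected


class TestConcentrationStatistic:
    def test_equal_per_snp_heritability_gives_one(self):
        assert ss.concentration_statistic(0.02, 100, 0.2, 10).psi == pytest.approx(1.0)

    def test_worked_example(self):
        assert ss.concentration_statistic(0.1, 100, 0.2, 10).psi == pytest.approx(5.0)

    def test_zero_numerator(self):
        assert ss.concentration_statistic(0.0, 50, 0.3, 5).psi == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ss.concentration_statistic(0.1, 10, 0.0, 5)


class TestTrainWeightedElasticNet:
    def test_perfect_predictor_selected(self, small_panel):
        geno = ss.maf_filter(small_panel, 0.05)
        y = geno.dosages[:, 4] * 0.5  # expression proportional to one variant
        model = ss.train_gene_model(
            geno, _single_tissue(geno, y), "gene1", "tissueA",
            TrainingConfig(seed=0, lambda_min_ratio=1e-4),
        )
        assert model.cv_r2 > 0.98
        top = max(model.weights, key=lambda v: abs(model.weights[v]))
        assert top == geno.variants[4].id

    def test_permuted_expression_fails_igene(self, small_panel):
        geno = ss.maf_filter(small_panel, 0.05)
        base = geno.dosages[:, 2].copy()
        r2s = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            y = rng.permutation(base) + rng.standard_normal(geno.n_samples) * 0.1
            m = ss.train_gene_model(
                geno, _single_tissue(geno, y), "gene1", "tissueA",
                TrainingConfig(seed=seed),
            )
            r2s.append(m.cv_r2)
        assert np.median(r2s) < 0.02

    def test_explicit_single_tissue_weights_match_default(self, multitissue_sim):
        geno, tissues, _ = multitissue_sim
        cfg = TrainingConfig(seed=3)
        a = ss.train_gene_model(geno, tissues, "gene1", "tissue0", cfg)
        b = ss.train_gene_model(
            geno, tissues, "gene1", "tissue0", cfg,
            weights_by_tissue={"tissue0": 1.0, "tissue1": 0.0},
        )
        assert a.weights.keys() == b.weights.keys()
        for k in a.weights:
            assert a.weights[k] == pytest.approx(b.weights[k], abs=1e-6)

    def test_cross_tissue_helps_small_tissue(self):
        """Borrowing from a similar, larger tissue improves prediction in
        the small one (cross-tissue vs single-tissue fit)."""
        gains = []
        for seed in range(8):
            geno, tissues, _ = ss.simulate_multitissue_expression(
                n_tissues=2, n_samples=[300, 60], similarity=0.9,
                h2_expr=0.4, n_causal=2, n_variants=20, seed=seed,
            )
            cfg = TrainingConfig(seed=seed)
            joint = ss.train_gene_model(
                geno, tissues, "gene1", "tissue1", cfg,
                weights_by_tissue={"tissue0": 0.8, "tissue1": 1.0},
            )
            single = ss.train_gene_model(geno, tissues, "gene1", "tissue1", cfg)
            gains.append(joint.cv_r2 - single.cv_r2)
        assert np.mean(gains) > 0

    def test_cv_r2_estimates_expression_heritability(self):
        """CV r^2 is an approximately unbiased estimate of the variance
        explained by the model's variants."""
        h2 = 0.4
        r2s = []
        for seed in range(30):
            geno, tissues, _ = ss.simulate_multitissue_expression(
                n_tissues=1, n_samples=400, similarity=1.0, h2_expr=h2,
                n_causal=1, n_variants=10, seed=100 + seed,
            )
            m = ss.train_gene_model(geno, tissues, "gene1", "tissue0",
                                    TrainingConfig(seed=seed))
            r2s.append(m.cv_r2)
        assert np.mean(r2s) == pytest.approx(h2, abs=0.05)

    def test_constant_expression_rejected(self, small_panel):
        y = np.ones(small_panel.n_samples)
        with pytest.raises(ValueError, match="constant"):
            ss.train_gene_model(small_panel, _single_tissue(small_panel, y),
                                "gene1", "tissueA", TrainingConfig())


class TestTissueSimilarity:
    def _sim(self):
        s = np.array([[1.0, 0.8], [0.8, 1.0]])
        return ss.TissueSimilarity(["a", "b"], s, s)

    def test_weight_exponents(self):
        w = self._sim().weights_for("a", 1.0, 1.0)
        assert w == {"a": 1.0, "b": pytest.approx(0.64)}

    def test_inf_exponent_hard_thresholds(self):
        w = self._sim().weights_for("a", np.inf, 0.0)
        assert w == {"a": 1.0, "b": 0.0}

    def test_asymmetric_rejected(self):
        s = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            ss.TissueSimilarity(["a", "b"], s, s)


class TestSegmentComparisons:
    @pytest.fixture(scope="class")
    def segment_setup(self):
        """Panel where all causal variants sit inside a focal segment."""
        rng = np.random.default_rng(8)
        template = ss.ar1_block_ld(30, rng, block_size=10)
        geno = ss.simulate_genotypes(250, target_ld=template, seed=9,
                                     start_pos=1_000_000, spacing=1000)
        x = geno.standardized()
        causal = [5, 7]  # inside positions 1_005_000 / 1_007_000
        genetic = x[:, causal] @ np.array([0.5, 0.4])
        y = genetic + rng.standard_normal(250) * 0.7
        segment = ss.Segment("chrS", 1_004_000, 1_008_500, label="focal")
        cis = ss.Segment("chrS", 999_000, 1_030_000, label="cis")
        return geno, y, segment, cis

    def test_focal_segment_beats_random(self, segment_setup):
        geno, y, segment, cis = segment_setup
        res = ss.random_segment_null(
            geno, _single_tissue(geno, y), "gene1", "tissueA", segment, cis,
            n_segments=12, seed=0, config=TrainingConfig(seed=0),
        )
        assert res.observed_r2 > res.null_median

    def test_no_signal_wilcoxon_p_is_one(self):
        results = [
            SegmentNullResult(gene=f"g{i}", observed_r2=0.1,
                              null_r2=np.full(5, 0.1), null_median=0.1)
            for i in range(5)
        ]
        assert ss.segment_null_wilcoxon(results) == 1.0

    def test_segment_longer_than_cis_rejected(self, segment_setup):
        geno, y, segment, cis = segment_setup
        with pytest.raises(ValueError, match="longer"):
            ss.random_segment_null(
                geno, _single_tissue(geno, y), "gene1", "tissueA",
                cis, segment, n_segments=2,
            )

    def test_dilation_zero_extension_reproduces_reduced(self, segment_setup):
        geno, y, segment, cis = segment_setup
        cfg = TrainingConfig(seed=0)
        table = ss.dilation_experiment(
            geno, _single_tissue(geno, y), ["gene1"], "tissueA", segment,
            extensions=(0,), config=cfg,
        )
        reduced = ss.train_gene_model(
            geno, _single_tissue(geno, y), "gene1", "tissueA", cfg,
            segment=segment,
        )
        assert table.loc[0, "cv_r2"] == pytest.approx(reduced.cv_r2, abs=1e-12)

    def test_dilation_to_full_cis_matches_full_model(self, segment_setup):
        geno, y, segment, cis = segment_setup
        cfg = TrainingConfig(seed=0)
        table = ss.dilation_experiment(
            geno, _single_tissue(geno, y), ["gene1"], "tissueA", segment,
            extensions=(10_000_000,), config=cfg,
        )
        full = ss.train_gene_model(geno, _single_tissue(geno, y), "gene1",
                                   "tissueA", cfg)
        assert table.loc[0, "cv_r2"] == pytest.approx(full.cv_r2, abs=1e-12)
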