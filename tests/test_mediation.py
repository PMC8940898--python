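"""Mediated-effect decomposition, pi_c, and GDE scores."""

import numpy as np
import pytest

import segment_scan as ss
from segment_scan.mediation import ARCHAIC_MIN_PREDICTORS


class TestMediatedDecomposition:
    def test_fully_mediated(self):
        beta = np.array([0.5, -0.2])
        med, ind = ss.mediated_decomposition(0.4 * beta, 0.4, beta)
        np.testing.assert_allclose(ind, 0.0, atol=1e-15)

    def test_zero_alpha_all_indirect(self):
        theta = np.array([0.3, 0.1])
        med, ind = ss.mediated_decomposition(theta, 0.0, np.array([0.5, 0.0]))
        np.testing.assert_array_equal(ind, theta)
        np.testing.assert_array_equal(med, 0.0)

    def test_worked_example(self):
        med, ind = ss.mediated_decomposition(
            np.array([0.3, 0.1]), 0.4, np.array([0.5, 0.0])
        )
        np.testing.assert_allclose(ind, [0.1, 0.1])

    def test_conservation(self, rng):
        theta = rng.standard_normal(12)
        beta = rng.standard_normal(12)
        med, ind = ss.mediated_decomposition(theta, 0.7, beta)
        np.testing.assert_allclose(med + ind, theta, atol=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.mediated_decomposition(np.zeros(3), 1.0, np.zeros(2))


class TestPiC:
    def test_reduced_equals_full_gives_one(self, rng):
        beta = rng.normal(0, 0.05, 6)
        C = np.eye(6)
        res = ss.pi_c(0.8, beta, beta, C, C, 10_000)
        assert res.pi_c == pytest.approx(1.0, abs=1e-12)
        assert not res.out_of_range_flag

    def test_worked_example(self):
        beta_full = np.full(4, 0.1)
        res = ss.pi_c(1.0, beta_full, beta_full[:2], np.eye(4), np.eye(2), 10_000)
        # (0.02 - 2e-4)/(0.04 - 4e-4) * (10000-4)/(10000-2) = 0.49990 (4 dp)
        assert res.pi_c == pytest.approx(0.4998999799959992, abs=1e-12)
        assert res.psi_e == pytest.approx(res.pi_c * 4 / 2, abs=1e-12)

    def test_alpha_zero_rank_ratio_flagged_degenerate(self):
        res = ss.pi_c(0.0, np.full(3, 0.1), np.full(3, 0.1), np.eye(3),
                      np.eye(3), 1000)
        assert res.pi_c == pytest.approx(1.0)
        assert res.degenerate

    def test_alpha_invariance_in_large_n_limit(self, rng):
        beta_full = rng.normal(0, 0.1, 8)
        beta_red = beta_full[:3]
        C_f, C_r = np.eye(8), np.eye(3)
        n = 10**9  # rank terms negligible
        r1 = ss.pi_c(0.5, beta_full, beta_red, C_f, C_r, n)
        r2 = ss.pi_c(5.0, beta_full, beta_red, C_f, C_r, n)
        assert r1.pi_c == pytest.approx(r2.pi_c, rel=1e-6)

    def test_out_of_range_flagged_not_clipped(self):
        # reduced quadratic form larger than full: ratio above 1
        res = ss.pi_c(1.0, np.array([0.1, 0.0]), np.array([0.2]), np.eye(2),
                      np.eye(1), 10_000)
        assert res.pi_c > 1.0
        assert res.out_of_range_flag

    def test_fully_segment_mediated_simulation(self):
        """All trait effect flows through expression driven by segment
        variants: pi_c concentrates at 1."""
        rng = np.random.default_rng(3)
        vals = []
        n = 50_000
        for _ in range(40):
            beta_red = rng.normal(0, 0.2, 3)
            beta_full = np.concatenate([beta_red, np.zeros(5)])
            # noisy estimates of eQTL effects at GWAS scale
            bf_hat = beta_full + rng.normal(0, 1 / np.sqrt(n), 8)
            br_hat = bf_hat[:3]
            res = ss.pi_c(0.4, bf_hat, br_hat, np.eye(8), np.eye(3), n)
            vals.append(res.pi_c)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)


class TestGDEScore:
    def _model(self):
        variants = [
            ss.Variant(f"v{i}", "1", i + 1, "A", "G", 0.2) for i in range(3)
        ]
        return ss.ExpressionModel(
            gene="g", tissue="t", weights={"v0": 0.5, "v1": -1.0, "v2": 0.25},
            scope="full", cv_r=0.5, cv_r2=0.25, cv_p=1e-3, n_predictors=3,
            predictor_variants=variants,
        )

    def test_all_zero_dosages(self):
        s = ss.gde_score(self._model(), {"v0": 0, "v1": 0, "v2": 0})
        assert s.score == 0.0 and not s.suppressed

    def test_linear_in_dosages(self):
        m = self._model()
        d1 = {"v0": 1.0, "v1": 0.5, "v2": 2.0}
        d2 = {"v0": 0.0, "v1": 1.5, "v2": 1.0}
        mix = {k: 2 * d1[k] + 3 * d2[k] for k in d1}
        assert ss.gde_score(m, mix).score == pytest.approx(
            2 * ss.gde_score(m, d1).score + 3 * ss.gde_score(m, d2).score
        )

    def test_archaic_single_predictor_suppressed(self):
        s = ss.gde_score(self._model(), {"v0": 1.0},
                         min_predictors=ARCHAIC_MIN_PREDICTORS)
        assert s.suppressed and np.isnan(s.score)
        assert "2" in s.reason

    def test_missing_predictor_contributes_zero(self):
        m = self._model()
        s = ss.gde_score(m, {"v0": 2.0, "v1": 1.0})
        assert s.score == pytest.approx(0.5 * 2 - 1.0)
        assert s.n_predictors_used == 2


class TestPopulationDistributions:
    def _panel(self, rng, n=60):
        geno = ss.simulate_genotypes(n, mafs=np.array([0.3, 0.2, 0.4]), seed=rng)
        return geno

    def _model(self, geno, weights):
        return ss.ExpressionModel(
            gene="g", tissue="t",
            weights={v.id: w for v, w in zip(geno.variants, weights)},
            scope="full", cv_r=0.5, cv_r2=0.25, cv_p=1e-3,
            n_predictors=len(weights), predictor_variants=list(geno.variants),
        )

    def test_archaic_equal_to_subject_matches_quantile(self):
        rng = np.random.default_rng(5)
        geno = self._panel(rng)
        model = self._model(geno, [0.5, -0.3, 0.8])
        labels = {s: ("EUR" if i < 30 else "EAS")
                  for i, s in enumerate(geno.samples)}
        subj = {v.id: geno.dosages[0, j] for j, v in enumerate(geno.variants)}
        summary, quants, arch = ss.population_gde_distributions(
            model, geno, labels, archaic_dosages=subj
        )
        eur_scores = [
            ss.gde_score(model, {v.id: geno.dosages[i, j]
                                 for j, v in enumerate(geno.variants)}).score
            for i in range(30)
        ]
        expected = np.mean(np.array(eur_scores) <= arch.score)
        assert quants["EUR"] == pytest.approx(expected)

    def test_extreme_negative_archaic_profile_low_quantile(self):
        rng = np.random.default_rng(6)
        geno = self._panel(rng, n=200)
        # archaic carries two copies of the strongest negative-weight allele
        # and none of the positive-weight alleles: the minimal possible score
        model = self._model(geno, [0.5, -1.0, 0.8])
        labels = {s: "AFR" for s in geno.samples}
        archaic = {"snp0": 0.0, "snp1": 2.0, "snp2": 0.0}
        _, quants, arch = ss.population_gde_distributions(
            model, geno, labels, archaic_dosages=archaic
        )
        assert quants["AFR"] < 0.05

    def test_suppressed_archaic_propagates_absent(self):
        rng = np.random.default_rng(7)
        geno = self._panel(rng)
        model = self._model(geno, [0.5, -0.3, 0.8])
        labels = {s: ("EUR" if i % 2 else "SAS")
                  for i, s in enumerate(geno.samples)}
        _, quants, arch = ss.population_gde_distributions(
            model, geno, labels, archaic_dosages={geno.variants[0].id: 1.0}
        )
        assert arch.suppressed and quants is None
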