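import numpy as np
import pandas as pd
import pytest

from imodest.engine import (apply_deflation, compute_deflation,
                            fit_elastic_net, fit_ensemble, gene_seed,
                            null_press_r2, press_from_predictions,
                            press_r2, press_r2_loo, transfer_score,
                            FitResult)
from imodest.preprocess import PreparedCohort, preprocess_cohort
from imodest.regulators import CLASS_ORDER, ModelSpec, TF
from imodest.simulate import (SimulationConfig, simulate_annotations,
                              simulate_cohort)

from conftest import enet_objective, naive_elastic_net, naive_loo_press


class TestNullModel:
    @pytest.mark.parametrize("n", [3, 10, 100])
    def test_intercept_only_press_matches_closed_form(self, n):
        y = np.random.default_rng(n).normal(size=n)
        expected = 1 - (n / (n - 1)) ** 2
        assert abs(null_press_r2(y) - expected) < 1e-12

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            null_press_r2(np.ones(10))


class TestElasticNet:
    def test_objective_matches_independent_coordinate_descent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, -0.5, 0, 0, 0.2]) + rng.normal(size=30)
        lam = 0.1
        fit = fit_elastic_net(X, y, lam=lam)
        b_o, b0_o = naive_elastic_net(X, y, lam)
        ours = enet_objective(X, y, fit.coef, fit.intercept, lam)
        oracle = enet_objective(X, y, b_o, b0_o, lam)
        assert abs(ours - oracle) < 1e-6
        np.testing.assert_allclose(fit.coef, b_o, atol=1e-6)

    def test_objective_matches_sklearn_at_fixed_lambda(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8))
        y = X[:, 0] - 0.3 * X[:, 3] + rng.normal(size=40)
        lam = 0.05
        fit = fit_elastic_net(X, y, lam=lam)
        sk = sklearn.ElasticNet(alpha=lam, l1_ratio=0.5, tol=1e-12,
                                max_iter=500_000).fit(X, y)
        ours = enet_objective(X, y, fit.coef, fit.intercept, lam)
        theirs = enet_objective(X, y, sk.coef_, sk.intercept_, lam)
        assert abs(ours - theirs) < 1e-6

    def test_null_response_yields_sparse_coefficients(self):
        zero_frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 50))
            y = rng.normal(size=200)
            fit = fit_elastic_net(X, y, seed=seed)
            zero_frac.append(np.mean(fit.coef == 0.0))
        assert np.mean(zero_frac) >= 0.9

    def test_perfect_single_predictor_gets_positive_coefficient(self):
        y = np.random.default_rng(2).normal(size=50)
        fit = fit_elastic_net(y[:, None], y, seed=0)
        assert fit.coef[0] > 0

    def test_invalid_inputs_rejected(self):
        X = np.ones((2, 1))
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(2))
        X = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(10))


class TestLeaveOneOut:
    def test_matches_naive_per_fold_refits(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(10, 41))
            p = int(rng.integers(2, 12))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) * 0.5 + rng.normal(size=n)
            lam = float(rng.uniform(0.02, 0.3))
            fit = fit_elastic_net(X, y, lam=lam)
            ours, _ = press_r2_loo(X, y, lam, beta_init=fit.coef)
            oracle = naive_loo_press(X, y, lam)
            assert abs(ours - oracle) < 1e-8

    def test_perfect_predictions_give_press_of_one(self):
        y = np.random.default_rng(4).normal(size=20)
        assert press_from_predictions(y, y.copy()) == pytest.approx(1.0)


class TestDeflation:
    def test_random_predictions_always_negative_with_mean_near_minus_one(self):
        y = np.random.default_rng(5).normal(size=100)
        y = (y - y.mean()) / y.std(ddof=1)
        mean, runs = compute_deflation(y, runs=1000, seed=0,
                                       return_runs=True)
        assert runs.max() < 0
        assert -1.2 < mean < -0.8

    def test_seeded_rerun_is_identical(self):
        y = np.random.default_rng(6).normal(size=50)
        a = compute_deflation(y, runs=200, seed=42)
        b = compute_deflation(y, runs=200, seed=42)
        assert a == b

    def test_deflation_value_negative_over_100_seeded_draws(self):
        rng = np.random.default_rng(7)
        for seed in range(100):
            y = rng.normal(size=10)
            assert compute_deflation(y, runs=50, seed=seed) < 0

    @pytest.mark.parametrize("raw, defl, out", [(0.5, -0.8, 0.5),
                                                (0.5, 0.1, 0.4),
                                                (0.0, 0.0, 0.0)])
    def test_deflation_applied_only_when_positive(self, raw, defl, out):
        assert apply_deflation(raw, defl) == pytest.approx(out)


class TestTransfer:
    def test_all_zero_coefficients_score_mechanically(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=30)
        expr = pd.DataFrame({"gA": y},
                            index=[f"s{i}" for i in range(30)])
        adjacent = PreparedCohort("adj", "tumor-adjacent", expr, {}, None,
                                  "normal")
        coef = pd.Series([0.0], index=pd.MultiIndex.from_tuples(
            [("TF", "tf1")]))
        fit = FitResult("gA", "t", ModelSpec.from_classes(TF), coef,
                        intercept=0.0, lam=0.1, press_r2_raw=0.0,
                        deflation=-1.0, n_samples=30)
        tss = ((y - y.mean()) ** 2).sum()
        expected = 1 - (y ** 2).sum() / tss
        assert transfer_score(fit, adjacent) == pytest.approx(expected)

    def test_missing_features_warn_and_count_as_zero(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=20)
        expr = pd.DataFrame({"gA": y},
                            index=[f"s{i}" for i in range(20)])
        adjacent = PreparedCohort("adj", "tumor-adjacent", expr, {}, None,
                                  "normal")
        coef = pd.Series([0.7], index=pd.MultiIndex.from_tuples(
            [("TF", "tf_missing")]))
        fit = FitResult("gA", "t", ModelSpec.from_classes(TF), coef,
                        intercept=0.0, lam=0.1, press_r2_raw=0.0,
                        deflation=-1.0, n_samples=20)
        with pytest.warns(UserWarning, match="absent"):
            score = transfer_score(fit, adjacent)
        tss = ((y - y.mean()) ** 2).sum()
        assert score == pytest.approx(1 - (y ** 2).sum() / tss)


class TestEnsemble:
    def test_full_cohort_yields_63_fits_plus_null(self, small_prepared):
        prep, _adj = small_prepared
        ens = fit_ensemble(prep, "g0000", seed=1, deflation_runs=100)
        assert len(ens.fits) == 63
        assert not ens.skipped
        n = ens.n_samples
        assert ens.null_press_raw == pytest.approx(
            1 - (n / (n - 1)) ** 2, abs=1e-12)
        assert all(f.press_r2_raw <= 1 for f in ens.fits.values())

    def test_gene_with_only_tf_features_fits_single_spec(self):
        cfg = SimulationConfig(n_samples=60, n_genes=2, seed=3,
                               shares={TF: 0.4}, noise_share=0.6,
                               lncrna_per_gene=0, probes_per_gene=0,
                               snps_per_gene=0, n_mirna=0, n_tf=20,
                               mirna_targets_per_gene=0)
        ann = simulate_annotations(cfg)
        cohort = simulate_cohort(cfg, ann, "tumor")
        prep = preprocess_cohort(cohort)
        prep.matrices.pop("CNV")
        ens = fit_ensemble(prep, "g0000", seed=0, deflation_runs=50)
        assert list(ens.fits) == [ModelSpec.from_classes(TF)]
        assert len(ens.skipped) == 62
        assert all("no features" in r for r in ens.skipped.values())

    def test_tf_share_recovered_by_deflated_press(self):
        cfg = SimulationConfig(n_samples=300, n_genes=1, seed=21,
                               shares={TF: 0.4}, noise_share=0.6,
                               n_mirna=10, n_tf=30, probes_per_gene=4,
                               snps_per_gene=4)
        ann = simulate_annotations(cfg)
        prep = preprocess_cohort(simulate_cohort(cfg, ann, "tumor"))
        ens = fit_ensemble(prep, "g0000", seed=2, deflation_runs=200)
        press = ens.press(ModelSpec.from_classes(TF))
        assert abs(press - 0.4) < 0.1

    def test_press_r2_operation_agrees_with_ensemble(self, small_prepared):
        prep, _adj = small_prepared
        spec = ModelSpec.from_classes(TF)
        raw, coefs = press_r2(prep, "g0001", spec, seed=1)
        ens = fit_ensemble(prep, "g0001", seed=1, deflation_runs=10)
        assert raw == pytest.approx(ens.fits[spec].press_r2_raw)
        assert len(coefs) == len(ens.fits[spec].coefficients)

    def test_seed_determinism(self, small_prepared):
        prep, _adj = small_prepared
        a = fit_ensemble(prep, "g0002", seed=5, deflation_runs=50)
        b = fit_ensemble(prep, "g0002", seed=5, deflation_runs=50)
        assert a.deflation == b.deflation
        for spec in a.fits:
            assert a.fits[spec].press_r2_raw == b.fits[spec].press_r2_raw

    def test_gene_seed_is_stable_and_bounded(self):
        assert gene_seed(1, "g0001") == gene_seed(1, "g0001")
        assert gene_seed(1, "g0001") != gene_seed(2, "g0001")
        assert 0 <= gene_seed(12345, "ENSG00000141510") < 2**31


class TestBuildDesign:
    def test_block_sizes_match_admitted_features(self, small_prepared):
        from imodest.engine import build_design
        from imodest.annotations import admitted_features
        from imodest.regulators import METH, SNP
        prep, _ = small_prepared
        spec = ModelSpec.from_classes(TF)
        X, empty = build_design(prep, "g0000", spec)
        assert X.shape[1] == len(
            admitted_features(prep.annotations, "g0000", TF))
        assert empty == []
        spec2 = ModelSpec.from_classes(METH, SNP)
        X2, _ = build_design(prep, "g0000", spec2)
        n_meth = len(admitted_features(prep.annotations, "g0000", METH))
        n_snp = len(admitted_features(prep.annotations, "g0000", SNP))
        assert X2.shape[1] == n_meth + n_snp
        assert [c[0] for c in X2.columns] == [METH] * n_meth + [SNP] * n_snp

    def test_body_overlapping_lncrna_never_enters_design(
            self, small_prepared):
        from imodest.engine import build_design
        from imodest.regulators import LNCRNA
        prep, _ = small_prepared
        for gene in prep.genes:
            X, _ = build_design(prep, gene,
                                ModelSpec.from_classes(LNCRNA))
            assert f"lnc_{gene}_ov" not in [c[1] for c in X.columns]


def test_residualization_improves_share_recovery_under_confounding():
    """With strong covariate confounding of both regulators and
    expression, correcting for covariates brings the estimated gains
    closer to the true variance shares than skipping the correction."""
    from imodest.model import RegulatorDecomposition
    from imodest.regulators import METH
    cfg = SimulationConfig(n_samples=200, n_genes=5, seed=77,
                           shares={TF: 0.3, METH: 0.2}, noise_share=0.5,
                           covariate_effect=0.8, n_mirna=10, n_tf=30,
                           probes_per_gene=5, snps_per_gene=4)
    ann = simulate_annotations(cfg)
    cohort = simulate_cohort(cfg, ann, "tumor")

    def _err(residualize):
        res = RegulatorDecomposition(cohort, seed=1, deflation_runs=50,
                                     residualize=residualize).fit()
        gm = res.gain_matrix
        truth = cohort.truth.shares[list(CLASS_ORDER)]
        return float((gm - truth).abs().mean(axis=None))

    assert _err(True) < _err(False)
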