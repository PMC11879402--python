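import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imodest.preprocess import (CovariateTable, OmicsMatrix, beta_to_m,
                                pc_outlier_filter, residualize, snp_qc,
                                standardize)


def _om(arr, cols=None, cls="TF"):
    arr = np.asarray(arr, float)
    df = pd.DataFrame(arr, columns=cols or [f"f{i}"
                                            for i in range(arr.shape[1])])
    df.index = [f"s{i}" for i in range(len(df))]
    return OmicsMatrix(df, cls)


class TestStandardize:
    def test_arithmetic_sequence_maps_to_unit_zscores(self):
        out, dropped = standardize(_om([[1], [2], [3]]))
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [-1, 0, 1])
        assert dropped == []
        assert out.state == "standardized"

    def test_constant_feature_dropped_and_reported(self):
        out, dropped = standardize(_om([[1, 5], [2, 5], [3, 5]]))
        assert dropped == ["f1"]
        assert out.feature_ids == ["f0"]

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(_om([[5], [5], [5]]))

    def test_random_matrix_columnwise_moments(self):
        rng = np.random.default_rng(0)
        out, _ = standardize(_om(rng.normal(2, 3, size=(50, 10))))
        vals = out.values.to_numpy()
        assert np.abs(vals.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(vals.std(axis=0, ddof=1), 1,
                                   atol=1e-12)

    def test_log_transform_requires_values_above_minus_one(self):
        with pytest.raises(ValueError, match="log"):
            standardize(_om([[-2], [0], [1]]), log_transform=True)
        out, _ = standardize(_om([[0], [1], [3]]), log_transform=True)
        expected = np.log1p([0, 1, 3])
        expected = (expected - expected.mean()) / expected.std(ddof=1)
        np.testing.assert_allclose(out.values.to_numpy().ravel(), expected)


def _cov_table(n, rng):
    return CovariateTable(pd.DataFrame({
        "sex": rng.choice(["F", "M"], size=n),
        "batch": rng.choice(["b1", "b2"], size=n),
        "PC1": rng.normal(size=n),
        "PC2": rng.normal(size=n),
        "purity": rng.uniform(0.3, 1, size=n),
        "age": rng.normal(60, 10, size=n),
        "histology": rng.choice(["h1", "h2"], size=n),
    }, index=[f"s{i}" for i in range(n)]))


class TestResidualize:
    def test_confounded_feature_becomes_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        cov = _cov_table(100, rng)
        feat = 2 * cov.table["PC1"].to_numpy() + 0.3 * rng.normal(size=100)
        om, _ = standardize(_om(feat[:, None]))
        res = residualize(om, cov, mode="tumor")
        r = np.corrcoef(res.values["f0"], cov.table["PC1"])[0, 1]
        assert abs(r) < 1e-8
        design = cov.design_matrix("tumor").to_numpy()
        corr = design[:, 1:].T @ res.values["f0"].to_numpy() / 100
        assert np.abs(corr).max() < 1e-6

    def test_residualization_is_idempotent(self):
        rng = np.random.default_rng(2)
        cov = _cov_table(60, rng)
        om, _ = standardize(_om(rng.normal(size=(60, 5))))
        once = residualize(om, cov)
        twice = residualize(once, cov)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-8)

    def test_null_design_returns_restandardized_input(self):
        rng = np.random.default_rng(3)
        n = 40
        cov = CovariateTable(pd.DataFrame({
            "sex": ["F"] * n, "batch": ["b1"] * n,
            "PC1": np.zeros(n), "PC2": np.zeros(n)},
            index=[f"s{i}" for i in range(n)]))
        om, _ = standardize(_om(rng.normal(size=(n, 3))))
        res = residualize(om, cov, mode="normal")
        np.testing.assert_allclose(res.values.to_numpy(),
                                   om.values.to_numpy(), atol=1e-10)

    def test_normal_mode_ignores_tumor_only_covariates(self):
        rng = np.random.default_rng(4)
        cov = _cov_table(80, rng)
        feat = 3 * cov.table["purity"].to_numpy() + rng.normal(size=80)
        om, _ = standardize(_om(feat[:, None]))
        res_n = residualize(om, cov, mode="normal")
        res_t = residualize(om, cov, mode="tumor")
        r_n = abs(np.corrcoef(res_n.values["f0"],
                              cov.table["purity"])[0, 1])
        r_t = abs(np.corrcoef(res_t.values["f0"],
                              cov.table["purity"])[0, 1])
        assert r_t < 1e-8 < r_n

    def test_more_covariates_than_samples_rejected(self):
        rng = np.random.default_rng(5)
        cov = _cov_table(5, rng)
        om, _ = standardize(_om(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="covariate columns"):
            residualize(om, cov, mode="tumor")


class TestBetaToM:
    @pytest.mark.parametrize("beta, m", [(0.5, 0.0), (0.8, 2.0),
                                         (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert beta_to_m(np.array([[beta]]))[0, 0] == pytest.approx(m)

    def test_boundary_values_clip_to_finite_m(self):
        out = beta_to_m(np.array([[0.0, 1.0, 0.999999]]))
        assert np.isfinite(out).all()
        assert out[0, 0] == beta_to_m(np.array([[1e-6]]))[0, 0]

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(np.array([[1.2]]))
        with pytest.raises(ValueError):
            beta_to_m(np.array([[-0.1]]))

    @settings(deadline=None)
    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_antisymmetric_about_half_and_increasing(self, b):
        m = beta_to_m(np.array([[b]]))[0, 0]
        m_ref = beta_to_m(np.array([[1 - b]]))[0, 0]
        assert m == pytest.approx(-m_ref, abs=1e-9)
        eps = 1e-6
        if b + eps < 1 - 1e-6:
            assert beta_to_m(np.array([[b + eps]]))[0, 0] >= m


class TestSnpQC:
    def _geno(self, cols):
        n = max(len(c) for c in cols.values())
        df = pd.DataFrame({k: pd.Series(v, dtype=float)
                           for k, v in cols.items()})
        df.index = [f"s{i}" for i in range(n)]
        return df

    def test_extreme_heterozygote_deficit_fails_hwe(self):
        # AA=50, Aa=0, aa=50 -> chi-square 100, p << 1e-5
        g = self._geno({"bad": [0] * 50 + [2] * 50,
                        "good": [0] * 25 + [1] * 50 + [2] * 25})
        filtered, report = snp_qc(g)
        assert list(filtered.columns) == ["good"]
        assert report.set_index("rule").loc["hwe", "items_removed"] == 1

    def test_maf_exactly_at_threshold_is_retained(self):
        # 10 alt alleles / 200 -> MAF = 0.05 exactly (strict < removes)
        g = self._geno({"edge": [1] * 10 + [0] * 90,
                        "rare": [1] * 9 + [0] * 91})
        filtered, report = snp_qc(g)
        assert "edge" in filtered.columns
        assert "rare" not in filtered.columns
        assert report.set_index("rule").loc["maf", "items_removed"] == 1

    def test_missingness_rules_apply_in_order(self):
        g = self._geno({
            "lost": [np.nan] * 30 + [1] * 70,      # 30% missing -> dropped
            "kept": [0] * 50 + [1] * 50})
        g.iloc[0, 1] = np.nan                       # sample s0: 100% missing
        filtered, report = snp_qc(g)
        rep = report.set_index("rule")["items_removed"]
        assert rep["snp_missingness"] == 1
        assert rep["sample_missingness"] == 1
        assert "s0" not in filtered.index

    def test_clean_common_snps_pass_untouched(self):
        rng = np.random.default_rng(6)
        g = pd.DataFrame(rng.binomial(2, 0.3, size=(200, 8)).astype(float),
                         index=[f"s{i}" for i in range(200)],
                         columns=[f"snp{i}" for i in range(8)])
        filtered, report = snp_qc(g)
        assert filtered.shape == g.shape
        assert report["items_removed"].sum() == 0

    def test_removal_counts_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        g = pd.DataFrame(rng.binomial(2, 0.08, size=(150, 10)).astype(float),
                         index=[f"s{i}" for i in range(150)],
                         columns=[f"snp{i}" for i in range(10)])
        _, rep1 = snp_qc(g)
        perm = rng.permutation(len(g))
        _, rep2 = snp_qc(g.iloc[perm])
        pd.testing.assert_frame_equal(rep1, rep2)

    def test_everything_filtered_raises(self):
        g = self._geno({"rare": [1] + [0] * 99})
        with pytest.raises(ValueError, match="survived"):
            snp_qc(g)


class TestPCOutlierFilter:
    def test_spherical_cloud_keeps_essentially_everyone(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(500, 20)),
                         index=[f"s{i}" for i in range(500)])
        kept, pcs = pc_outlier_filter(X)
        assert len(kept) >= 498
        assert list(pcs.columns) == ["PC1", "PC2"]

    def test_planted_outlier_is_removed(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(200, 30)),
                         index=[f"s{i}" for i in range(200)])
        direction = rng.normal(size=30)
        X.iloc[0] = 30 * direction / np.linalg.norm(direction)
        kept, _ = pc_outlier_filter(X)
        assert "s0" not in kept
        assert len(kept) == 199

    def test_scores_are_orthogonal_and_unit_variance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(100, 12)),
                         index=[f"s{i}" for i in range(100)])
        _, pcs = pc_outlier_filter(X)
        v = pcs.to_numpy()
        np.testing.assert_allclose(v.std(axis=0, ddof=1), 1, atol=1e-8)
        assert abs(v[:, 0] @ v[:, 1]) / len(v) < 1e-8

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ValueError):
            pc_outlier_filter(X, n_pcs=5)
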