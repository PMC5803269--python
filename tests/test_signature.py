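import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from humisig import (
    ExpressionMatrix,
    bh_adjust,
    derive_signature,
    fold_change_contrast,
    moderated_t,
    residual_normalize,
)
from humisig.signature import shrink_variance

from conftest import make_log_matrix


def _annotation(n, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "symbol": genes,
            "gc_fraction": rng.uniform(0.3, 0.7, n),
            "length_bp": np.exp(rng.uniform(np.log(500), np.log(1e5), n)).astype(int),
            "has_uniprot": True,
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestResidualNormalize:
    def test_null_artifact_leaves_matrix_nearly_unchanged(self):
        rng = np.random.default_rng(4)
        n = 400
        ann = _annotation(n)
        vals = rng.normal(5, 1, (n, 1)) + rng.normal(0, 0.2, (n, 6))
        m = make_log_matrix(vals)
        normalized, fit = residual_normalize(m, ann)
        # no planted artifact: per-sample slopes within ~3 standard errors of 0
        resid_sd = 0.2 * np.sqrt(1 - 1 / 6)
        se_gc = resid_sd / (np.sqrt(n) * ann["gc_fraction"].std())
        se_len = resid_sd / (np.sqrt(n) * np.log10(ann["length_bp"]).std())
        assert np.abs(fit.coefficients["gc_fraction"]).max() < 3 * se_gc
        assert np.abs(fit.coefficients["log10_length"]).max() < 3 * se_len
        diff = normalized.values.to_numpy() - m.values.to_numpy()
        assert np.abs(diff).max() < 0.3

    def test_exact_recovery_of_planted_gc_slope(self):
        # sample 0 carries +2.0*gc relative to the others; the between-sample
        # contrast of fitted slopes recovers the planted value exactly
        rng = np.random.default_rng(5)
        n = 300
        ann = _annotation(n)
        base = rng.normal(5, 1, n)
        vals = np.tile(base[:, None], (1, 6)).astype(float)
        vals[:, 0] += 2.0 * ann["gc_fraction"].to_numpy()
        normalized, fit = residual_normalize(make_log_matrix(vals), ann)
        slopes = fit.coefficients["gc_fraction"]
        recovered = slopes.iloc[0] - slopes.iloc[1:].mean()
        np.testing.assert_allclose(recovered, 2.0, atol=1e-6)

    def test_robust_fit_beats_ols_under_outlier_contamination(self):
        # 10% of genes (the highest-GC ones, to bias the slope) get a gross
        # offset in the artifact-carrying sample
        rng = np.random.default_rng(6)
        n = 500
        ann = _annotation(n)
        base = rng.normal(5, 1, n)
        gc = ann["gc_fraction"].to_numpy()
        vals = np.tile(base[:, None], (1, 10)).astype(float)
        vals[:, 0] += 2.0 * gc
        outliers = np.argsort(gc)[-n // 10:]
        vals[outliers, 0] += 8.0
        m = make_log_matrix(vals)
        _, fit = residual_normalize(m, ann)
        slopes = fit.coefficients["gc_fraction"]
        robust = slopes.iloc[0] - slopes.iloc[1:].mean()
        # OLS on the same per-sample ratio for comparison
        ratios = m.values.to_numpy() - m.values.to_numpy().mean(axis=1, keepdims=True)
        X = np.column_stack([np.ones(n), gc, np.log10(ann["length_bp"])])
        ols_slopes = [np.linalg.lstsq(X, ratios[:, j], rcond=None)[0][1]
                      for j in range(10)]
        ols = ols_slopes[0] - np.mean(ols_slopes[1:])
        assert abs(robust - 2.0) / 2.0 < 0.05
        assert abs(ols - 2.0) > abs(robust - 2.0)

    def test_refuses_tiny_gene_sets(self):
        ann = _annotation(5)
        m = make_log_matrix(np.ones((5, 4)))
        with pytest.raises(ValueError, match="10 genes"):
            residual_normalize(m, ann)

    def test_artifact_invariance_of_downstream_contrast(self):
        # adding a*gc + b*log10(length) to every sample of the bulk dataset
        # must not change the purified-vs-bulk fold change (noiseless case)
        rng = np.random.default_rng(7)
        n = 300
        ann = _annotation(n)
        base = rng.normal(5, 1, n)
        pur_vals = np.tile(base[:, None], (1, 4)) + rng.normal(0, 0.1, (n, 4))
        bulk_vals = np.tile(base[:, None], (1, 8)) + rng.normal(0, 0.1, (n, 8))

        def contrast(bulk_extra):
            combined = np.hstack([pur_vals, bulk_vals + bulk_extra[:, None]])
            m = make_log_matrix(combined)
            normalized, _ = residual_normalize(m, ann)
            pur = ExpressionMatrix(normalized.values.iloc[:, :4], scale="normalized")
            bulk = ExpressionMatrix(normalized.values.iloc[:, 4:], scale="normalized")
            return fold_change_contrast(pur, bulk)

        artifact = 1.7 * ann["gc_fraction"].to_numpy() - 0.6 * np.log10(
            ann["length_bp"].to_numpy()
        )
        base_fc = contrast(np.zeros(n))
        biased_fc = contrast(artifact)
        np.testing.assert_allclose(biased_fc.to_numpy(), base_fc.to_numpy(),
                                   atol=1e-6)


class TestFoldChangeContrast:
    def test_arithmetic(self):
        pur = make_log_matrix(np.full((3, 2), 5.0), prefix="p")
        bulk = make_log_matrix(np.full((3, 4), 2.0), prefix="b")
        fc = fold_change_contrast(pur, bulk)
        np.testing.assert_allclose(fc.to_numpy(), 3.0)

    def test_identity_gives_zero(self):
        m = make_log_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_allclose(fold_change_contrast(m, m).to_numpy(), 0.0)

    def test_empty_intersection_rejected(self):
        a = make_log_matrix(np.ones((3, 2)))
        b = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 2)), index=["x1", "x2", "x3"],
                         columns=["u1", "u2"]),
            scale="log2",
        )
        with pytest.raises(ValueError, match="intersection"):
            fold_change_contrast(a, b)

    def test_planted_markers_pass_fc_threshold(self, small_bundle):
        from humisig import log_transform
        from humisig.synthgen import MICROGLIA

        pur = log_transform(small_bundle["purified"])
        bulk = log_transform(small_bundle["bulk"])
        fc = fold_change_contrast(pur, bulk)
        markers = sorted(small_bundle["truth"].marker_sets[MICROGLIA])
        assert (fc.loc[markers] >= 2.0).mean() >= 0.95


class TestModeratedT:
    def _pair(self, seed=0, n_genes=500, n1=4, n2=6, effect_genes=0, effect=0.0):
        rng = np.random.default_rng(seed)
        sd = rng.uniform(0.3, 1.2, n_genes)
        base = rng.normal(5, 1, (n_genes, 1))
        x1 = base + rng.normal(0, sd[:, None], (n_genes, n1))
        x2 = base + rng.normal(0, sd[:, None], (n_genes, n2))
        x1[:effect_genes] += effect
        return make_log_matrix(x1, prefix="a"), make_log_matrix(x2, prefix="b")

    def test_zero_prior_df_equals_ordinary_t(self):
        a, b = self._pair(seed=1)
        res = moderated_t(a, b, prior_df=0.0)
        t_ref, p_ref = stats.ttest_ind(a.values.to_numpy(), b.values.to_numpy(),
                                       axis=1, equal_var=True)
        np.testing.assert_allclose(res["mod_t"].to_numpy(), t_ref, atol=1e-9)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p_ref, atol=1e-9)

    def test_shrinkage_formula_hand_value(self):
        # s2=4, s0^2=1, d0=4, d=4 -> (4*1 + 4*4)/8 = 2.5
        np.testing.assert_allclose(shrink_variance([4.0], 4.0, 4.0, 1.0), [2.5])
        np.testing.assert_allclose(shrink_variance([4.0], 4.0, np.inf, 1.0), [1.0])

    def test_null_p_values_uniform(self):
        a, b = self._pair(seed=2, n_genes=2000)
        res = moderated_t(a, b)
        d = stats.kstest(res["p_value"], "uniform").statistic
        assert d < 0.05

    def test_matches_limma_ebayes(self, tmp_path):
        # independent oracle: R limma's eBayes on the identical matrix
        a, b = self._pair(seed=3, n_genes=200, n1=5, n2=5,
                          effect_genes=20, effect=2.0)
        mat = pd.concat([a.values, b.values], axis=1)
        mat.to_csv(tmp_path / "mat.csv")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'm <- as.matrix(read.csv("{tmp_path}/mat.csv", row.names=1))\n'
            'design <- cbind(Intercept=1, Group=c(rep(1,5), rep(0,5)))\n'
            'fit <- eBayes(lmFit(m, design))\n'
            'out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"])\n'
            f'write.csv(out, "{tmp_path}/limma_out.csv")\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        lim = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        res = moderated_t(a, b)
        np.testing.assert_allclose(res["mod_t"].to_numpy(), lim["t"].to_numpy(),
                                   rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(res["p_value"].to_numpy(), lim["p"].to_numpy(),
                                   rtol=1e-8, atol=1e-10)

    def test_zero_variance_zero_delta_gene_gets_p_one(self):
        vals = np.vstack([np.ones((1, 8)), np.random.default_rng(0).normal(5, 1, (20, 8))])
        a = make_log_matrix(vals[:, :4], prefix="a")
        b = make_log_matrix(vals[:, 4:], prefix="b")
        res = moderated_t(a, b)
        assert res["p_value"].iloc[0] == 1.0 or res["mod_t"].iloc[0] == 0.0

    def test_small_groups_rejected(self):
        a = make_log_matrix(np.ones((5, 1)), prefix="a")
        b = make_log_matrix(np.ones((5, 3)), prefix="b")
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t(a, b)

    def test_weighted_version_runs_and_matches_unweighted_at_unit_weights(self):
        a, b = self._pair(seed=4, n_genes=100)
        w = pd.DataFrame(1.0, index=a.gene_ids,
                         columns=list(a.sample_ids) + list(b.sample_ids))
        res_w = moderated_t(a, b, weights=w)
        res = moderated_t(a, b)
        np.testing.assert_allclose(res_w["mod_t"], res["mod_t"], atol=1e-12)


class TestBHAdjust:
    def test_hand_step_up_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_mixed_case(self):
        # step-up by hand: sorted (0.005,0.04,0.2,0.9) * 4/(1..4), cummin
        np.testing.assert_allclose(
            bh_adjust([0.9, 0.005, 0.2, 0.04]),
            [0.9, 0.02, 0.26666666666666666, 0.08],
        )

    def test_single_and_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_statsmodels_and_is_permutation_equivariant(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p[perm]), ours[perm], atol=1e-15)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestDeriveSignature:
    def test_boundary_fold_change_included(self):
        lfc = pd.Series([2.0, 1.999], index=["a", "b"])
        mod = pd.DataFrame(
            {"mod_t": [5.0, 5.0], "p_value": [0.001, 0.001]}, index=["a", "b"]
        )
        sig = derive_signature(lfc, mod, fc_threshold=4.0)
        assert bool(sig.loc["a", "in_fc_set"])
        assert not bool(sig.loc["b", "in_fc_set"])

    def test_pval_set_subset_of_fc_set(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(100)]
        lfc = pd.Series(rng.normal(1, 2, 100), index=genes)
        mod = pd.DataFrame(
            {"mod_t": rng.normal(size=100), "p_value": rng.uniform(size=100)},
            index=genes,
        )
        sig = derive_signature(lfc, mod)
        assert not (sig["in_pval_set"] & ~sig["in_fc_set"]).any()
        assert sig.attrs["n_fc_set"] == int(sig["in_fc_set"].sum())

    def test_recovers_planted_markers_on_synthetic_data(self, small_bundle):
        from humisig import log_transform
        from humisig.synthgen import MICROGLIA

        pur = log_transform(small_bundle["purified"])
        bulk = log_transform(small_bundle["bulk"])
        lfc = fold_change_contrast(pur, bulk)
        mod = moderated_t(pur, bulk)
        sig = derive_signature(lfc, mod)
        found = set(sig.index[sig["in_fc_set"]])
        markers = small_bundle["truth"].marker_sets[MICROGLIA]
        sens = len(found & markers) / len(markers)
        prec = len(found & markers) / max(len(found), 1)
        assert sens >= 0.95 and prec >= 0.95
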