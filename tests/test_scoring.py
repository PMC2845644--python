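"""Eigengene projection, variance moderation, and DE scores."""

import subprocess

import numpy as np
import pytest

from sagat import (
    ExpressionMatrix,
    SimConfig,
    WeightMatrix,
    align_genes,
    decompose,
    fold_change_scores,
    moderate_variances,
    moderated_t_scores,
    permutation_pvalues,
    project,
    sagat_pipeline,
    sagat_scores,
    sagat_scores_single,
    simulate_dataset,
    simulate_knowledge,
    standardize_rows,
    weight_matrix,
)


def identity_weights(gene_ids):
    n = len(gene_ids)
    return WeightMatrix(W=np.eye(n), M=n, gene_ids=list(gene_ids))


class TestProject:
    def test_identity_weight_recovers_data(self, matrix_factory):
        ds = matrix_factory([[1.0, 2.0], [3.0, 4.0]])
        proj = project(ds, identity_weights(ds.gene_ids))
        np.testing.assert_array_equal(proj.Ehat, ds.values)

    def test_null_data_gives_zero_moments(self, matrix_factory):
        ds = matrix_factory(np.zeros((3, 4)))
        proj = project(ds, identity_weights(ds.gene_ids))
        assert (proj.eigengene_means == 0).all()
        assert (proj.raw_variances == 0).all()

    def test_hand_matrix_product(self, matrix_factory):
        # 3 genes, 2 eigengenes, 2 replicates
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]) / np.sqrt(2)
        ds = matrix_factory([[1.0, 3.0], [2.0, 4.0], [0.0, 2.0]])
        w = WeightMatrix(W=W, M=2, gene_ids=list(ds.gene_ids))
        proj = project(ds, w)
        np.testing.assert_allclose(proj.Ehat, W.T @ ds.values)
        np.testing.assert_allclose(
            proj.eigengene_means, (W.T @ ds.values).mean(axis=1)
        )

    def test_single_replicate_has_no_variances(self, matrix_factory):
        ds = matrix_factory([[1.0], [2.0]])
        proj = project(ds, identity_weights(ds.gene_ids))
        assert proj.m == 1 and proj.raw_variances is None

    def test_unaligned_genes_rejected(self, matrix_factory):
        ds = matrix_factory([[1.0], [2.0]])
        w = WeightMatrix(W=np.eye(2), M=2, gene_ids=["X", "Y"])
        with pytest.raises(ValueError, match="align"):
            project(ds, w)


class TestModerateVariances:
    def test_equal_variances_unchanged(self):
        mv = moderate_variances(np.full(10, 3.0), df=4)
        np.testing.assert_allclose(mv.s_tilde_sq, 3.0, rtol=1e-6)

    def test_d0_zero_override_disables_shrinkage(self, rng):
        s2 = rng.chisquare(4, 20)
        mv = moderate_variances(s2, df=4, d0_override=0.0)
        np.testing.assert_array_equal(mv.s_tilde_sq, s2)

    def test_infinite_d0_collapses_to_prior(self, rng):
        s2 = rng.chisquare(4, 20)
        mv = moderate_variances(s2, df=4, d0_override=np.inf)
        assert np.unique(mv.s_tilde_sq).size == 1

    def test_shrinkage_lies_between_raw_and_prior(self, rng):
        s2 = rng.chisquare(3, 50) * 2.0
        mv = moderate_variances(s2, df=3)
        lo = np.minimum(s2, mv.s0_sq) - 1e-12
        hi = np.maximum(s2, mv.s0_sq) + 1e-12
        assert ((mv.s_tilde_sq >= lo) & (mv.s_tilde_sq <= hi)).all()

    def test_prior_parameter_recovery(self):
        # variances drawn from (s0^2 * d0 / chi2_d0) * (chi2_df / df) with
        # d0=4, s0^2=2: moment matching should land within 50% at n=200
        rng = np.random.default_rng(7)
        d0_true, s0_true, df = 4.0, 2.0, 3
        n = 200
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        mv = moderate_variances(s2, df=df)
        assert abs(mv.d0 - d0_true) / d0_true < 0.5
        assert abs(mv.s0_sq - s0_true) / s0_true < 0.5

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            moderate_variances(np.zeros(5), df=3)

    def test_matches_limma_squeezevar(self, tmp_path):
        """Cross-check prior fit and posterior variances against the
        Bioconductor reference implementation (finite-prior branch:
        variances drawn with real between-gene spread)."""
        rng = np.random.default_rng(11)
        sigma2 = 2.0 * 4.0 / rng.chisquare(4.0, 40)
        s2 = sigma2 * rng.chisquare(5, 40) / 5
        df = 5
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "squeeze.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path / "s2.txt"}", quiet=TRUE)\n'
            f'sq <- squeezeVar(s2, df={df})\n'
            'cat(sq$df.prior, sq$var.prior, "\\n")\n'
            'cat(sq$var.post, sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        d0_ref, s0_ref = float(out[0]), float(out[1])
        post_ref = np.array([float(v) for v in out[2:]])
        mv = moderate_variances(s2, df=df)
        assert np.isfinite(d0_ref)  # the interesting branch
        assert mv.d0 == pytest.approx(d0_ref, rel=1e-4)
        assert mv.s0_sq == pytest.approx(s0_ref, rel=1e-4)
        np.testing.assert_allclose(mv.s_tilde_sq, post_ref, rtol=1e-4)


class TestSagatScores:
    def test_hand_evaluated_formula(self, matrix_factory):
        # 2 genes, 1 eigengene, w = [.6, .8], stilde2 = 1, m = 4,
        # dbar = [1, -1] -> T = [1/sqrt(.36/4), -1/sqrt(.64/4)]
        from sagat import ModeratedVariances

        W = np.array([[0.6], [0.8]])
        w = WeightMatrix(W=W, M=1, gene_ids=["G0", "G1"])
        ds = matrix_factory(np.column_stack([np.full(2, 1.0)] * 4) *
                            np.array([[1.0], [-1.0]]))
        mv = ModeratedVariances(
            s_tilde_sq=np.array([1.0]), d0=4.0, s0_sq=1.0, df=3.0
        )
        t = sagat_scores(ds, w, mv).scores
        np.testing.assert_allclose(t, [1 / np.sqrt(0.36 / 4),
                                       -1 / np.sqrt(0.64 / 4)])
        np.testing.assert_allclose(t, [10 / 3, -2.5])

    def test_reduces_to_moderated_t_with_identity_weights(self, rng):
        ds = ExpressionMatrix(rng.normal(size=(200, 4)),
                              [f"G{i}" for i in range(200)],
                              [f"R{j}" for j in range(4)])
        w = identity_weights(ds.gene_ids)
        proj = project(ds, w)
        mv = moderate_variances(proj.raw_variances, df=3)
        sagat = sagat_scores(ds, w, mv).scores
        modt = moderated_t_scores(ds).scores
        np.testing.assert_allclose(sagat, modt, atol=1e-10)

    def test_null_numerator_gives_zero_score(self, matrix_factory):
        from sagat import ModeratedVariances

        ds = matrix_factory([[1.0, -1.0], [0.5, -0.5]])
        w = identity_weights(ds.gene_ids)
        mv = ModeratedVariances(np.ones(2), d0=1.0, s0_sq=1.0, df=1.0)
        assert (sagat_scores(ds, w, mv).scores == 0).all()

    def test_scale_invariance_multireplicate(self, rng):
        ds = ExpressionMatrix(rng.normal(size=(50, 5)),
                              [f"G{i}" for i in range(50)],
                              [f"R{j}" for j in range(5)])
        w = identity_weights(ds.gene_ids)
        t1 = sagat_pipeline(ds, w).scores
        scaled = ExpressionMatrix(ds.values * 3.0, list(ds.gene_ids),
                                  list(ds.array_ids))
        t2 = sagat_pipeline(scaled, w).scores
        np.testing.assert_allclose(t2, t1, atol=1e-8)

    def test_antisymmetry(self, rng):
        ds = ExpressionMatrix(rng.normal(size=(40, 3)),
                              [f"G{i}" for i in range(40)],
                              [f"R{j}" for j in range(3)])
        w = identity_weights(ds.gene_ids)
        neg = ExpressionMatrix(-ds.values, list(ds.gene_ids),
                               list(ds.array_ids))
        for fn in (lambda d: sagat_pipeline(d, w),
                   fold_change_scores,
                   moderated_t_scores):
            np.testing.assert_allclose(fn(neg).scores, -fn(ds).scores,
                                       atol=1e-10)

    def test_single_replicate_rejected(self, matrix_factory):
        from sagat import ModeratedVariances

        ds = matrix_factory([[1.0], [2.0]])
        w = identity_weights(ds.gene_ids)
        mv = ModeratedVariances(np.ones(2), d0=1.0, s0_sq=1.0, df=1.0)
        with pytest.raises(ValueError):
            sagat_scores(ds, w, mv)


class TestSagatSingleReplicate:
    def test_direct_evaluation(self, matrix_factory):
        # 1 gene, 1 eigengene, w=1, d=4 -> e=4, T = 4/sqrt(4) = 2
        ds = matrix_factory([[4.0]])
        w = WeightMatrix(W=np.array([[1.0]]), M=1, gene_ids=["G0"])
        assert sagat_scores_single(ds, w).scores[0] == pytest.approx(2.0)

    def test_null_data_scores_zero(self, matrix_factory):
        ds = matrix_factory(np.zeros((3, 1)))
        t = sagat_scores_single(ds, identity_weights(ds.gene_ids))
        assert (t.scores == 0).all()

    def test_antisymmetry(self, rng):
        ds = ExpressionMatrix(rng.normal(size=(30, 1)),
                              [f"G{i}" for i in range(30)], ["R0"])
        w = identity_weights(ds.gene_ids)
        neg = ExpressionMatrix(-ds.values, list(ds.gene_ids), ["R0"])
        np.testing.assert_allclose(
            sagat_scores_single(neg, w).scores,
            -sagat_scores_single(ds, w).scores,
            atol=1e-12,
        )

    def test_scaling_by_sqrt_c(self, rng):
        # m=1 scores are not scale-free: scaling data by c scales T by sqrt(c)
        ds = ExpressionMatrix(rng.normal(size=(30, 1)),
                              [f"G{i}" for i in range(30)], ["R0"])
        w = identity_weights(ds.gene_ids)
        t1 = sagat_scores_single(ds, w).scores
        scaled = ExpressionMatrix(4.0 * ds.values, list(ds.gene_ids), ["R0"])
        t2 = sagat_scores_single(scaled, w).scores
        np.testing.assert_allclose(t2, 2.0 * t1, atol=1e-8)

    def test_multireplicate_rejected(self, matrix_factory):
        ds = matrix_factory([[1.0, 2.0]])
        w = WeightMatrix(W=np.array([[1.0]]), M=1, gene_ids=["G0"])
        with pytest.raises(ValueError):
            sagat_scores_single(ds, w)


class TestComparisonMetrics:
    def test_fold_change_is_row_mean(self, matrix_factory):
        ds = matrix_factory([[1.0, 3.0], [2.0, 2.0]])
        np.testing.assert_allclose(fold_change_scores(ds).scores, [2.0, 2.0])

    def test_fold_change_column_permutation_invariant(self, rng):
        vals = rng.normal(size=(10, 5))
        a = ExpressionMatrix(vals, [f"G{i}" for i in range(10)],
                             [f"R{j}" for j in range(5)])
        b = ExpressionMatrix(vals[:, ::-1], list(a.gene_ids),
                             [f"R{j}" for j in range(5)])
        np.testing.assert_allclose(fold_change_scores(a).scores,
                                   fold_change_scores(b).scores, atol=1e-12)

    def test_moderated_t_single_replicate_unsupported(self, matrix_factory):
        with pytest.raises(ValueError, match="two or more replicates"):
            moderated_t_scores(matrix_factory([[1.0], [2.0]]))

    def test_moderated_t_d0_zero_equals_ordinary_t(self, rng):
        ds = ExpressionMatrix(rng.normal(size=(30, 6)),
                              [f"G{i}" for i in range(30)],
                              [f"R{j}" for j in range(6)])
        t = moderated_t_scores(ds, d0_override=0.0).scores
        dbar = ds.values.mean(axis=1)
        s = ds.values.std(axis=1, ddof=1)
        np.testing.assert_allclose(t, dbar / (s / np.sqrt(6)), atol=1e-10)

    def test_equal_variances_match_fold_change_order(self, rng):
        # shared variance denominator: ordering must equal fold change's
        base = rng.normal(size=(20, 1))
        ds = ExpressionMatrix(
            base + np.array([[0.1, -0.1, 0.05, -0.05]]),
            [f"G{i}" for i in range(20)], [f"R{j}" for j in range(4)],
        )
        order_t = np.argsort(np.abs(moderated_t_scores(ds).scores))
        order_fc = np.argsort(np.abs(fold_change_scores(ds).scores))
        np.testing.assert_array_equal(order_t, order_fc)


class TestAlignGenes:
    def test_identical_sets_identity(self, matrix_factory):
        ds = matrix_factory([[1.0], [2.0]])
        w = identity_weights(ds.gene_ids)
        a_ds, a_w, dropped = align_genes(ds, w)
        assert a_ds.gene_ids == ds.gene_ids
        assert not dropped["dataset_only"] and not dropped["weights_only"]

    def test_extra_dataset_gene_reported(self, matrix_factory):
        ds = matrix_factory([[1.0], [2.0], [3.0]],
                            gene_ids=["G0", "G1", "EXTRA"])
        w = identity_weights(["G0", "G1"])
        _, _, dropped = align_genes(ds, w)
        assert dropped["dataset_only"] == ["EXTRA"]

    def test_values_follow_shuffled_ids(self, matrix_factory):
        ds = matrix_factory([[10.0], [20.0], [30.0]],
                            gene_ids=["C", "A", "B"])
        w = WeightMatrix(W=np.eye(3), M=3, gene_ids=["A", "B", "C"])
        a_ds, a_w, _ = align_genes(ds, w)
        assert a_ds.gene_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(a_ds.values[:, 0], [20.0, 30.0, 10.0])

    def test_empty_intersection_rejected(self, matrix_factory):
        ds = matrix_factory([[1.0]], gene_ids=["X"])
        w = identity_weights(["Y"])
        with pytest.raises(ValueError):
            align_genes(ds, w)


class TestBorrowing:
    def test_module_genes_have_smaller_standard_errors(self):
        """DE genes inside planted modules share eigengenes, so their
        pooled standard-error terms are on average smaller than those of
        identical-effect isolated DE genes."""
        cfg = SimConfig(m=1)
        knowledge, truth = simulate_knowledge(cfg)
        d = decompose(standardize_rows(knowledge))
        w = weight_matrix(d, d.rank)
        mod_de = (truth.module_assignment >= 0) & (truth.de_labels == 1)
        iso_de = (truth.module_assignment < 0) & (truth.de_labels == 1)
        rng = np.random.default_rng(99)
        se_mod, se_iso = [], []
        for _ in range(50):
            ds = simulate_dataset(cfg, truth, rng=rng)
            e = w.W.T @ ds.values[:, 0]
            se = np.sqrt((w.W**2) @ np.abs(e))
            se_mod.append(se[mod_de].mean())
            se_iso.append(se[iso_de].mean())
        assert np.mean(se_mod) < np.mean(se_iso)

    def test_module_genes_have_smaller_standard_errors_replicated(self):
        """The same borrowing effect through the moderated eigengene
        variances when replicates are available (m = 4)."""
        cfg = SimConfig(m=4)
        knowledge, truth = simulate_knowledge(cfg)
        d = decompose(standardize_rows(knowledge))
        w = weight_matrix(d, d.rank)
        mod_de = (truth.module_assignment >= 0) & (truth.de_labels == 1)
        iso_de = (truth.module_assignment < 0) & (truth.de_labels == 1)
        rng = np.random.default_rng(17)
        se_mod, se_iso = [], []
        for _ in range(50):
            ds = simulate_dataset(cfg, truth, rng=rng)
            proj = project(ds, w)
            mv = moderate_variances(proj.raw_variances, df=3)
            se = np.sqrt((w.W**2) @ mv.s_tilde_sq / 4)
            se_mod.append(se[mod_de].mean())
            se_iso.append(se[iso_de].mean())
        assert np.mean(se_mod) < np.mean(se_iso)


class TestPermutationPValues:
    def test_seeded_reproducibility_and_signal_detection(self, rng):
        vals = rng.normal(size=(60, 4)) * 0.3
        vals[:5] += 3.0  # strong DE genes
        ds = ExpressionMatrix(vals, [f"G{i}" for i in range(60)],
                              [f"R{j}" for j in range(4)])
        w = identity_weights(ds.gene_ids)
        p1 = permutation_pvalues(ds, w, n_perm=200, seed=5)
        p2 = permutation_pvalues(ds, w, n_perm=200, seed=5)
        np.testing.assert_array_equal(p1, p2)
        assert p1[:5].max() < 0.2
        assert (p1 >= 1 / 201).all() and (p1 <= 1.0).all()
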