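import numpy as np
import pytest

from snppca import (
    GenotypeError,
    PolarityMask,
    apply_mask,
    component_df,
    decompose,
    pca,
    reconstruct,
    source_df,
    transform,
    VARIANTS,
)
from snppca.pca_core import rank_bound
from conftest import make_matrix, random_polymorphic


class TestTransforms:
    def test_double_centering_annihilates_additive_structure(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        additive = 0.3 + a[:, None] + b[None, :]
        tm = transform(additive, "double_centered")
        np.testing.assert_allclose(tm.values, 0.0, atol=1e-12)

    def test_snp_centering_by_hand(self):
        tm = transform(np.array([[1.0, 0.0], [0.0, 1.0]]), "snp_centered")
        np.testing.assert_allclose(tm.values, [[0.5, -0.5], [-0.5, 0.5]])

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_centering_identities(self, rng, variant):
        m = random_polymorphic(rng, 9, 7)
        tm = transform(m, variant)
        v = tm.values
        if variant in ("snp_centered", "snp_standardized", "double_centered"):
            np.testing.assert_allclose(v.mean(axis=0), 0.0, atol=1e-9)
        if variant in ("individual_centered", "individual_standardized", "double_centered"):
            np.testing.assert_allclose(v.mean(axis=1), 0.0, atol=1e-9)
        if variant == "grand_mean_centered":
            assert abs(v.mean()) < 1e-9
        if variant == "snp_standardized":
            np.testing.assert_allclose(v.std(axis=0, ddof=1), 1.0, atol=1e-9)
        if variant == "individual_standardized":
            np.testing.assert_allclose(v.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_zero_variance_snp_rejected_with_name(self):
        m = make_matrix([[0, 1], [0, 0], [0, 1]])
        with pytest.raises(GenotypeError, match="snp0001"):
            transform(m, "snp_standardized")


class TestDecompose:
    def test_hand_svd_of_2x2_interaction(self, toy22):
        res = pca(toy22, "double_centered", 1)
        assert res.singular_values[0] == pytest.approx(1.0)
        assert res.component_ss[0] == pytest.approx(1.0)
        np.testing.assert_allclose(
            np.abs(res.scores("individuals")[:, 0]), [0.70710678, 0.70710678], atol=1e-8
        )
        # rank-1 reconstruction equals the interaction matrix exactly
        np.testing.assert_allclose(
            reconstruct(res, 1), [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12
        )

    def test_joint_sign_flip_leaves_products_unchanged(self, rng):
        m = random_polymorphic(rng, 6, 8)
        res = pca(m, "double_centered", 3)
        prods = res.scores("individuals") @ res.scores("snps").T
        flipped = (-res.scores("individuals")) @ (-res.scores("snps")).T
        np.testing.assert_allclose(prods, flipped)

    def test_sign_convention_largest_snp_loading_positive(self, rng):
        m = random_polymorphic(rng, 7, 9)
        res = pca(m, "double_centered", 4)
        for n in range(res.k):
            v = res.snp_eigenvectors[:, n]
            assert v[np.argmax(np.abs(v))] > 0

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(5, 4))
        tm = transform(x, "grand_mean_centered")
        res = decompose(tm, rank_bound(5, 4, "grand_mean_centered"))
        np.testing.assert_allclose(reconstruct(res, res.k), tm.values, atol=1e-10)
        np.testing.assert_allclose(reconstruct(res, 0), 0.0)

    def test_energy_conservation(self, rng):
        m = random_polymorphic(rng, 10, 8)
        for variant in VARIANTS:
            tm = transform(m, variant)
            res = decompose(tm, rank_bound(10, 8, variant))
            assert res.component_ss.sum() == pytest.approx(tm.total_ss, rel=1e-6)

    def test_oracle_equivalence_with_crossproduct_eigendecomposition(self, rng):
        """SVD route agrees with brute-force eig of X^T X on small matrices."""
        for _ in range(10):
            R, C = rng.integers(3, 9), rng.integers(3, 9)
            x = rng.normal(size=(R, C))
            tm = transform(x, "grand_mean_centered")
            res = decompose(tm, min(R, C))
            w = np.sort(np.linalg.eigvalsh(tm.values.T @ tm.values))[::-1]
            np.testing.assert_allclose(res.singular_values**2, np.clip(w[: res.k], 0, None), atol=1e-8)

    def test_sklearn_cross_check_snp_centered(self, rng):
        """Independent oracle: scikit-learn's PCA of the raw matrix equals
        the snp_centered route (same centering convention)."""
        from sklearn.decomposition import PCA as SkPCA

        m = random_polymorphic(rng, 12, 9)
        res = pca(m, "snp_centered", 3)
        sk = SkPCA(n_components=3, svd_solver="full").fit(m.values.astype(float))
        R = m.n_individuals
        np.testing.assert_allclose(
            res.component_ss / (R - 1), sk.explained_variance_, atol=1e-10
        )
        ours = res.scores("individuals", scaling="axis_principal")
        theirs = sk.transform(m.values.astype(float))
        for n in range(3):
            if np.dot(ours[:, n], theirs[:, n]) < 0:
                theirs[:, n] = -theirs[:, n]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_k_beyond_rank_bound_rejected(self, toy22):
        tm = transform(toy22, "double_centered")
        with pytest.raises(GenotypeError, match="outside"):
            decompose(tm, 2)

    def test_scaling_modes(self, rng):
        m = random_polymorphic(rng, 6, 5)
        res = pca(m, "snp_centered", 2)
        sym = res.scores("individuals", "symmetric_sqrt")
        prin = res.scores("individuals", "axis_principal")
        np.testing.assert_allclose(prin, sym * np.sqrt(res.singular_values))


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "p,n,k,variant,expected",
        [
            (1341, 635, 1, "double_centered", 1973),
            (1341, 635, 7, "double_centered", 1961),
            (1341, 635, 1, "snp_centered", 1974),
            (1341, 635, 7, "snp_centered", 1962),
            (1341, 635, 1, "individual_centered", 1974),
            (1341, 635, 1, "grand_mean_centered", 1975),
        ],
    )
    def test_gollob_rule(self, p, n, k, variant, expected):
        assert component_df(p, n, k, variant) == expected

    def test_oat_sized_df_bookkeeping_closes(self):
        """Source df equals the component dfs plus the residual df."""
        p, n = 1341, 635
        dc_dfs = [component_df(p, n, k, "double_centered") for k in range(1, 8)]
        assert source_df(p, n, "double_centered") == 849560
        assert 849560 - sum(dc_dfs) == 835791
        sc_dfs = [component_df(p, n, k, "snp_centered") for k in range(1, 8)]
        assert source_df(p, n, "snp_centered") == 850194
        assert 850194 - sum(sc_dfs) == 836418
        ic_dfs = [component_df(p, n, k, "individual_centered") for k in range(1, 8)]
        assert source_df(p, n, "individual_centered") == 850900
        assert 850900 - sum(ic_dfs) == 837124

    def test_nonpositive_df_rejected(self):
        with pytest.raises(GenotypeError, match="df"):
            component_df(4, 4, 4, "double_centered")

    def test_random_instance_df_closure(self, rng):
        m = random_polymorphic(rng, 11, 6)
        for variant in VARIANTS:
            res = pca(m, variant, 3)
            assert res.component_dfs.sum() + res.residual_df == res.source_df


class TestPolarityImmunity:
    def test_snp_centered_scores_invariant_under_any_mask(self, rng):
        """Flipping SNP polarities leaves Individual scores unchanged up to
        per-component sign for the SNP-centered and SNP-standardized variants."""
        worst = 0.0
        for t in range(25):
            m = random_polymorphic(rng, 8, 10)
            mask = PolarityMask(rng.random(10) < 0.5, m.snp_ids)
            flipped = apply_mask(m, mask)
            for variant in ("snp_centered", "snp_standardized"):
                a = pca(m, variant, 3).scores("individuals")
                b = pca(flipped, variant, 3).scores("individuals")
                for n in range(3):
                    if np.dot(a[:, n], b[:, n]) < 0:
                        b[:, n] = -b[:, n]
                worst = max(worst, float(np.max(np.abs(a - b))))
        assert worst < 1e-8

    def test_dc_scores_not_exactly_invariant_but_nearly_when_ind_main_small(self):
        from snppca import structured_bernoulli, three_source_anova

        m, _ = structured_bernoulli(60, 120, share_interaction=(0.3, 0.12), seed=7)
        an = three_source_anova(m)
        assert an.ss("Individuals") / an.ss("SxI") < 0.01
        rng = np.random.default_rng(77)
        mask = PolarityMask(rng.random(120) < 0.5, m.snp_ids)
        flipped = apply_mask(m, mask)
        a = pca(m, "double_centered", 2).scores("individuals")
        b = pca(flipped, "double_centered", 2).scores("individuals")
        for n in range(2):
            corr = abs(np.corrcoef(a[:, n], b[:, n])[0, 1])
            assert corr > 0.99
            # not exactly invariant: the theorem's commutator is nonzero
            aligned = b[:, n] if np.dot(a[:, n], b[:, n]) > 0 else -b[:, n]
            assert np.max(np.abs(a[:, n] - aligned)) > 1e-8
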