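import numpy as np
import pytest

from snppca import (
    GenotypeError,
    augmented_anova,
    classify_pc_outcomes,
    dc_pca_anova,
    recode,
    three_source_anova,
    VARIANTS,
)
from conftest import make_matrix, random_polymorphic, random_recode_stable


class TestThreeSource:
    def test_symmetric_2x2_is_pure_interaction(self, toy22):
        t = three_source_anova(toy22)
        assert t.ss("SNPs") == pytest.approx(0.0, abs=1e-12)
        assert t.ss("Individuals") == pytest.approx(0.0, abs=1e-12)
        assert t.ss("SxI") == pytest.approx(1.0)
        assert (t.df("SNPs"), t.df("Individuals"), t.df("SxI"), t.df("Total")) == (1, 1, 1, 3)

    def test_hand_anova_of_unbalanced_2x2(self):
        t = three_source_anova(np.array([[1.0, 1.0], [0.0, 1.0]]))
        assert t.ss("SNPs") == pytest.approx(0.25)
        assert t.ss("Individuals") == pytest.approx(0.25)
        assert t.ss("SxI") == pytest.approx(0.25)
        assert t.ss("Total") == pytest.approx(0.75)

    def test_orthogonality_on_random_matrices(self, rng):
        for _ in range(5):
            x = rng.normal(size=(rng.integers(3, 10), rng.integers(3, 10)))
            t = three_source_anova(x)
            parts = t.ss("SNPs") + t.ss("Individuals") + t.ss("SxI")
            assert parts == pytest.approx(t.ss("Total"), rel=1e-6)
            corrected = float(np.sum((x - x.mean()) ** 2))
            assert t.ss("Total") == pytest.approx(corrected, rel=1e-9)


class TestDcPcaAnova:
    def test_component_rows_close_the_interaction_subtotal(self, rng):
        m = random_polymorphic(rng, 10, 14)
        t = dc_pca_anova(m, 4)
        ipc = [t.ss(f"IPC{n}") for n in range(1, 5)]
        assert sum(ipc) + t.ss("Residual") == pytest.approx(t.ss("SxI"), rel=1e-9)
        dfs = [t.df(f"IPC{n}") for n in range(1, 5)] + [t.df("Residual")]
        assert sum(dfs) == t.df("SxI")
        assert ipc == sorted(ipc, reverse=True)

    def test_additive_matrix_has_zero_ipcs(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        additive = np.round(1 + a[:, None] + b[None, :], 6)
        t = dc_pca_anova(additive, 2)
        assert t.ss("IPC1") == pytest.approx(0.0, abs=1e-9)
        assert t.ss("IPC2") == pytest.approx(0.0, abs=1e-9)


class TestAugmented:
    def test_rows_close_and_columns_close_for_singly_centered(self, rng):
        m = random_polymorphic(rng, 10, 14)
        for variant in (
            "snp_centered",
            "individual_centered",
            "snp_standardized",
            "individual_standardized",
        ):
            t = augmented_anova(m, variant, 4)
            tb = t.table.set_index("source")
            comp_rows = [s for s in tb.index if s.startswith("PC") or s == "Residual"]
            for s in comp_rows:
                row = tb.loc[s]
                portions = sum(row[c] for c in t.portion_columns)
                assert portions == pytest.approx(row["ss"], abs=1e-9)
            combined = next(s for s in tb.index if s in ("I&SxI", "S&SxI"))
            for c in t.portion_columns:
                colsum = sum(tb.loc[s, c] for s in comp_rows)
                assert colsum == pytest.approx(tb.loc[combined, c], abs=1e-8)

    def test_grand_mean_centered_rows_close_with_mean_portion(self, rng):
        m = random_polymorphic(rng, 8, 9)
        t = augmented_anova(m, "grand_mean_centered", 3)
        assert "Mean" in t.portion_columns
        tb = t.table.set_index("source")
        for s in [x for x in tb.index if x.startswith("PC") or x == "Residual"]:
            row = tb.loc[s]
            assert sum(row[c] for c in t.portion_columns) == pytest.approx(row["ss"], abs=1e-9)

    def test_equal_row_means_give_zero_individual_portions(self):
        # every individual has the same mean -> no Individual main effects
        m = np.array(
            [
                [1, 0, 1, 0],
                [0, 1, 0, 1],
                [1, 1, 0, 0],
                [0, 0, 1, 1],
            ],
            dtype=float,
        )
        t = augmented_anova(m, "snp_centered", 2)
        tb = t.table.set_index("source")
        for s in ("PC1", "PC2", "Residual"):
            assert tb.loc[s, "Individuals"] == pytest.approx(0.0, abs=1e-12)

    def test_double_centered_input_returns_plain_table(self, rng):
        m = random_polymorphic(rng, 6, 8)
        t = augmented_anova(m, "double_centered", 2)
        assert not getattr(t, "portion_columns", ())
        assert "IPC1" in t.sources

    def test_portion_columns_need_not_be_monotone(self, rng):
        """Main-effect portions across successive PCs are not sorted - the
        bookkeeping must not assume monotonicity (only the PC totals are)."""
        seen_nonmonotone = False
        for seed in range(6):
            r = np.random.default_rng(seed)
            m = random_polymorphic(r, 12, 16)
            t = augmented_anova(m, "snp_centered", 5)
            tb = t.table.set_index("source")
            ind = [tb.loc[f"PC{n}", "Individuals"] for n in range(1, 6)]
            ss = [tb.loc[f"PC{n}", "ss"] for n in range(1, 6)]
            assert ss == sorted(ss, reverse=True)
            if ind != sorted(ind, reverse=True):
                seen_nonmonotone = True
        assert seen_nonmonotone

    def test_classifier_four_outcomes(self):
        # strong individual main effects -> PC1 main-dominated
        rng = np.random.default_rng(3)
        from snppca import structured_bernoulli

        m, _ = structured_bernoulli(40, 60, share_individual=0.35, seed=5)
        t = augmented_anova(m, "snp_centered", 2)
        out = classify_pc_outcomes(t)
        assert out["PC1"] == "main-dominated"
        m2, _ = structured_bernoulli(40, 60, share_interaction=0.35, seed=5)
        t2 = augmented_anova(m2, "snp_centered", 2)
        assert classify_pc_outcomes(t2)["PC1"] == "interaction-dominated"
        with pytest.raises(GenotypeError):
            classify_pc_outcomes(dc_pca_anova(m.values, 2))


class TestCodingInvariance:
    def test_rare1_and_common1_tables_identical_for_all_variants(self, rng):
        m = random_recode_stable(rng, 9, 11)
        r1, _ = recode(m, "rare1")
        c1, _ = recode(m, "common1")
        for variant in VARIANTS:
            t1 = augmented_anova(r1, variant, 3).table
            t2 = augmented_anova(c1, variant, 3).table
            assert list(t1["source"]) == list(t2["source"])
            np.testing.assert_allclose(t1["ss"], t2["ss"], atol=1e-9)
            np.testing.assert_array_equal(t1["df"], t2["df"])


class TestExports:
    def test_text_prints_three_decimals_and_tsv_full_precision(self, tmp_path, toy22):
        t = three_source_anova(toy22)
        text = t.to_text()
        assert "1.000" in text
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        assert "SxI" in p.read_text()
        assert '"source"' in t.to_json() or "source" in t.to_json()
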