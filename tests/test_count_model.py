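import numpy as np
import pytest

from nbbtest import CountTable, group_by_gene, nscore, proportions
from nbbtest.count_model import check_grand_totals

from conftest import make_table


class TestCountTableValidation:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_table([[1, -2, 3, 4]], ["g1"])

    def test_rejects_single_condition_replicate(self):
        counts = np.ones((1, 3))
        with pytest.raises(ValueError, match="replicate"):
            make_table(counts, ["g1"], m_a=1)

    def test_rejects_duplicate_feature_pairs(self):
        with pytest.raises(ValueError, match="unique"):
            make_table(np.ones((2, 4)), ["g1", "g1"], ["f", "f"])

    def test_condition_order_follows_design(self, two_gene_table):
        assert two_gene_table.condition_names == ("A", "B")
        mask_a, mask_b = two_gene_table.condition_columns()
        assert mask_a.sum() == 3 and mask_b.sum() == 3


class TestGroupByGene:
    def test_partition_sizes(self, two_gene_table):
        subs = group_by_gene(two_gene_table)
        assert [s.n_features for s in subs] == [2, 3]
        assert [s.gene_id for s in subs] == ["g1", "g2"]

    def test_single_gene_identity(self):
        counts = np.arange(8, dtype=float).reshape(2, 4)
        table = make_table(counts, ["g", "g"])
        (sub,) = group_by_gene(table)
        np.testing.assert_array_equal(sub.counts, counts)

    def test_interleaved_rows_match_brute_force(self, rng):
        genes = rng.choice(["ga", "gb", "gc"], size=12)
        counts = rng.integers(0, 100, (12, 4)).astype(float)
        table = make_table(counts, genes, [f"f{i}" for i in range(12)])
        subs = group_by_gene(table)
        # brute-force scan: per gene, rows in input order
        for sub in subs:
            expected = np.vstack([counts[i] for i in range(12) if genes[i] == sub.gene_id])
            np.testing.assert_array_equal(sub.counts, expected)

    def test_flatten_recovers_all_rows(self, two_gene_table):
        subs = group_by_gene(two_gene_table)
        flat = np.vstack([s.counts for s in subs])
        assert flat.shape == two_gene_table.counts.shape
        # row multiset identical (here order is preserved as well)
        np.testing.assert_array_equal(flat, two_gene_table.counts)


class TestProportions:
    def test_per_gene_library_column(self):
        table = make_table(
            np.array([[2, 2, 2, 2], [3, 3, 3, 3], [5, 5, 5, 5]], dtype=float),
            ["g", "g", "g"],
        )
        (sub,) = group_by_gene(table)
        pm = proportions(sub, "per_gene_library")
        np.testing.assert_allclose(pm.values[:, 0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(pm.values.sum(axis=0), 1.0)

    def test_per_gene_max_total_uses_largest_column_total(self):
        # condition A column totals 10 and 20 -> divisor 20 for both columns
        counts = np.array([[4, 8, 1, 1], [6, 12, 1, 1]], dtype=float)
        table = make_table(counts, ["g", "g"])
        (sub,) = group_by_gene(table)
        pm = proportions(sub, "per_gene_max_total")
        np.testing.assert_allclose(pm.values[:, 0], [4 / 20, 6 / 20])
        np.testing.assert_allclose(pm.values[:, 1], [8 / 20, 12 / 20])

    def test_gene_over_grand_total(self):
        counts = np.array([[30, 30, 30, 30], [70, 70, 70, 70]], dtype=float)
        table = make_table(counts, ["g1", "g2"], kind="gene")
        gene_tab = table.sum_to_genes()
        subs = group_by_gene(gene_tab)
        # treat the gene-level table as a single block for the grand total
        from nbbtest import GeneSubMatrix

        block = GeneSubMatrix(
            "all",
            gene_tab.counts[:, :2],
            gene_tab.counts[:, 2:],
            gene_tab.feature_ids,
        )
        pm = proportions(block, "gene_over_grand_total")
        np.testing.assert_allclose(pm.values[:, 0], [0.3, 0.7])
        assert len(subs) == 2

    def test_zero_library_column_flagged(self):
        counts = np.array([[0, 2, 3, 3], [0, 2, 3, 3]], dtype=float)
        table = make_table(counts, ["g", "g"])
        (sub,) = group_by_gene(table)
        pm = proportions(sub, "per_gene_library")
        np.testing.assert_array_equal(pm.values[:, 0], 0.0)
        assert pm.flagged.all()

    def test_scaling_invariance_per_gene_library(self, rng):
        counts = rng.integers(1, 50, (3, 4)).astype(float)
        table = make_table(counts, ["g"] * 3)
        (sub,) = group_by_gene(table)
        scaled = make_table(counts * 7.5, ["g"] * 3)
        (sub2,) = group_by_gene(scaled)
        np.testing.assert_allclose(
            proportions(sub, "per_gene_library").values,
            proportions(sub2, "per_gene_library").values,
        )


class TestNscore:
    def test_row_with_global_max_unchanged(self):
        y = np.array([[1.0, 10.0], [2.0, 5.0]])
        out = nscore(y)
        np.testing.assert_allclose(out[0], y[0])

    def test_scale_factors(self):
        y = np.array([[1.0, 2.0], [5.0, 10.0]])
        np.testing.assert_allclose(nscore(y), [[5.0, 10.0], [5.0, 10.0]])

    def test_every_row_max_equals_global_max(self, rng):
        y = rng.random((5, 4)) * 100
        out = nscore(y)
        np.testing.assert_allclose(out.max(axis=1), y.max())

    def test_idempotent(self, rng):
        y = rng.random((6, 3)) * 50
        once = nscore(y)
        np.testing.assert_allclose(nscore(once), once)

    def test_zero_row_left_alone(self):
        y = np.array([[0.0, 0.0], [1.0, 2.0]])
        out = nscore(y)
        np.testing.assert_array_equal(out[0], 0.0)

    def test_log2_input_inverted_first(self):
        logged = np.log2(np.array([[4.0, 8.0], [16.0, 32.0]]))
        np.testing.assert_allclose(
            nscore(logged, log2_input=True),
            nscore(np.array([[4.0, 8.0], [16.0, 32.0]])),
        )


def test_grand_total_warning():
    counts = np.array([[100, 100, 100, 100], [100, 50, 100, 100]], dtype=float)
    table = make_table(counts, ["g1", "g2"])
    with pytest.warns(UserWarning, match="grand totals"):
        assert not check_grand_totals(table)


def test_drop_all_zero(two_gene_table):
    counts = two_gene_table.counts.copy()
    counts[1] = 0.0
    table = make_table(counts, two_gene_table.gene_ids, two_gene_table.feature_ids)
    kept = table.drop_all_zero()
    assert kept.n_features == 4
    assert "i2" not in kept.feature_ids
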