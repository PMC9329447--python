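import numpy as np
import pytest

from nbbtest import bh_adjust
from nbbtest import test_genes as nbb_test_genes
from nbbtest import test_isoforms as nbb_test_isoforms
from nbbtest import test_sgrnas as nbb_test_sgrnas

from conftest import make_table


class TestBHAdjust:
    def test_three_values(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_matches_brute_force_step_up(self, rng):
        p = rng.random(50)

        def brute_force(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank_idx in range(n - 1, -1, -1):
                i = order[rank_idx]
                running = min(running, p[i] * n / (rank_idx + 1))
                adj[i] = running
            return adj

        np.testing.assert_allclose(bh_adjust(p), brute_force(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_monotone_after_rank_alignment(self, rng):
        p = rng.random(30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


@pytest.fixture
def effect_table(rng):
    """12 genes x 2 isoforms; gene g0's first isoform strongly shifted."""
    genes, counts = [], []
    for g in range(12):
        base = rng.integers(200, 2000)
        a = rng.poisson(base, (2, 3)).astype(float)
        b = rng.poisson(base, (2, 3)).astype(float)
        if g == 0:
            b[0] *= 6.0
        genes += [f"g{g}"] * 2
        counts.append(np.hstack([a, b]))
    table = make_table(np.vstack(counts), genes,
                       [f"g{g}.i{k}" for g in range(12) for k in range(2)])
    return table


class TestIsoformTest:
    def test_rho_equal_omega_leaves_t_unchanged(self, effect_table):
        res = nbb_test_isoforms(effect_table, omega=1.0)
        row = res.iloc[0]
        res2 = nbb_test_isoforms(effect_table, omega=float(row["rho"]))
        assert res2.iloc[0]["t_alpha"] == pytest.approx(row["t"])

    def test_t_alpha_identity_and_sign(self, effect_table):
        res = nbb_test_isoforms(effect_table, omega=2.0)
        np.testing.assert_allclose(
            res["t_alpha"], res["rho"] / 2.0 * res["t"], rtol=1e-12
        )
        sign_ok = (np.sign(res["t_alpha"]) == np.sign(res["t"])) | (res["t_alpha"] == 0)
        assert sign_ok.all()

    def test_zero_rho_gives_zero_statistic_p_one(self, rng):
        # noisy overlapping data: clamped zeta -> rho 0 for some features
        counts = rng.permuted(
            np.tile(np.array([10.0, 500.0, 30.0, 450.0, 20.0, 480.0]), (6, 1)), axis=1
        )
        table = make_table(counts, [f"g{i}" for i in range(6)])
        res = nbb_test_isoforms(table, omega=1.0)
        zero = res[res["rho"] == 0.0]
        assert len(zero) > 0
        assert (zero["t_alpha"] == 0.0).all()
        assert (zero["pvalue"] == 1.0).all()

    def test_identical_conditions_call_nothing(self, rng):
        half = rng.integers(50, 500, (10, 3)).astype(float)
        table = make_table(np.hstack([half, half]), [f"g{i//2}" for i in range(10)])
        res = nbb_test_isoforms(table, omega=1.0)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        assert (res["padj"] > 0.9999).all()
        assert (res["direction"] == "none").all()

    def test_condition_swap_flips_signs_keeps_p(self, effect_table):
        res = nbb_test_isoforms(effect_table, omega=1.0)
        swapped_design = {
            s: ("B" if c == "A" else "A")
            for s, c in effect_table.sample_condition.items()
        }
        # relabel so condition B's samples come first in the design ordering
        from nbbtest import CountTable

        reordered = [s for s in effect_table.samples if swapped_design[s] == "A"] + [
            s for s in effect_table.samples if swapped_design[s] == "B"
        ]
        idx = [effect_table.samples.index(s) for s in reordered]
        table2 = CountTable(
            effect_table.gene_ids,
            effect_table.feature_ids,
            effect_table.counts[:, idx],
            reordered,
            swapped_design,
            "isoform",
        )
        res2 = nbb_test_isoforms(table2, omega=1.0)
        np.testing.assert_allclose(res2["t"], -res["t"], rtol=1e-9)
        np.testing.assert_allclose(res2["pvalue"], res["pvalue"], rtol=1e-9)

    def test_detects_planted_shift(self, effect_table):
        res = nbb_test_isoforms(effect_table, omega=1.0)
        hit = res[res["feature_id"] == "g0.i0"]
        assert hit["padj"].iloc[0] < 0.05
        assert hit["direction"].iloc[0] == "down"  # B condition was raised

    def test_single_feature_gene_allowed(self, rng):
        counts = rng.integers(100, 300, (3, 6)).astype(float)
        table = make_table(counts, ["g1", "g2", "g3"])
        res = nbb_test_isoforms(table, omega=1.0)
        assert len(res) == 3

    def test_wrong_kind_rejected(self, two_gene_table):
        from nbbtest import CountTable

        sg = CountTable(
            two_gene_table.gene_ids, two_gene_table.feature_ids,
            two_gene_table.counts, two_gene_table.samples,
            two_gene_table.sample_condition, "sgrna",
        )
        with pytest.raises(ValueError, match="isoform"):
            nbb_test_isoforms(sg)
        with pytest.raises(ValueError, match="sgrna"):
            nbb_test_sgrnas(two_gene_table)


class TestSgrnaTest:
    def test_shared_gene_rho(self, rng):
        counts = rng.integers(50, 800, (6, 6)).astype(float)
        table = make_table(counts, ["g1"] * 3 + ["g2"] * 3,
                           [f"s{i}" for i in range(6)], kind="sgrna")
        res = nbb_test_sgrnas(table, omega=1.0)
        for g in ("g1", "g2"):
            assert res.loc[res["gene_id"] == g, "rho"].nunique() == 1


class TestGeneTest:
    def test_one_gene_table_degenerate(self, rng):
        counts = rng.integers(100, 200, (2, 6)).astype(float)
        table = make_table(counts, ["g1", "g1"])
        res = nbb_test_genes(table, omega=1.0)
        assert len(res) == 1
        assert res["t"].iloc[0] == 0.0  # proportions are 1 everywhere
        assert res["pvalue"].iloc[0] == 1.0

    def test_sum_to_genes_single_feature_identity(self, two_gene_table):
        gene_tab = two_gene_table.sum_to_genes()
        np.testing.assert_allclose(
            gene_tab.counts[0],
            two_gene_table.counts[:2].sum(axis=0),
        )

    def test_gene_level_detects_shift(self, rng):
        genes, rows = [], []
        for g in range(10):
            base = rng.integers(300, 3000)
            a = rng.poisson(base, (2, 3)).astype(float)
            b = rng.poisson(base, (2, 3)).astype(float)
            if g == 3:
                b *= 5.0
            genes += [f"g{g}"] * 2
            rows.append(np.hstack([a, b]))
        table = make_table(np.vstack(rows), genes,
                           [f"g{g}.i{k}" for g in range(10) for k in range(2)])
        res = nbb_test_genes(table, omega=1.0)
        assert res.loc[res["gene_id"] == "g3", "padj"].iloc[0] < 0.05
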