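import numpy as np
import pandas as pd
import pytest

from rdnsv.code_sites import aggregate, site_counts
from rdnsv.core import correction_factors, rdnsv_estimate
from rdnsv.genesets import (
    GENE_TABLE_COLUMNS,
    GeneSet,
    background_quantiles,
    build_gene_table,
    permutation_test,
    remove_shared,
    select_tissue_specific,
    set_statistic,
    tissue_specificity,
)


def make_table(rows):
    """rows: gene -> (ns_snv, s_snv, s_ts, s_tv, ns_ts, ns_tv)."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GENE_TABLE_COLUMNS))


UNIFORM = {f"g{i}": (5, 4, 10.0, 10.0, 8.0, 20.0) for i in range(12)}


class TestBuildGeneTable:
    def test_from_simulation(self, neutral_dataset, neutral_annotated):
        sites_by_gene = {c.gene_id: site_counts(c) for c in neutral_dataset.cds}
        table = build_gene_table(sites_by_gene, neutral_annotated)
        assert len(table) == len(neutral_dataset.cds)
        assert table["ns_snv"].sum() == neutral_dataset.truth["n_ns_snv"]
        assert table["s_snv"].sum() == neutral_dataset.truth["n_s_snv"]
        total = aggregate(sites_by_gene.values())
        assert table["s_site_ts"].sum() == pytest.approx(float(total.s_site_ts))


class TestSetStatistic:
    def test_rdnsv_matches_estimator(self, neutral_dataset, neutral_annotated):
        sites_by_gene = {c.gene_id: site_counts(c) for c in neutral_dataset.cds}
        table = build_gene_table(sites_by_gene, neutral_annotated)
        genes = list(table.index)
        pooled_sites = aggregate(sites_by_gene.values())
        factors = correction_factors(pooled_sites, w=4.0)
        ns = int(table["ns_snv"].sum())
        s = int(table["s_snv"].sum())
        expected = rdnsv_estimate(ns, s, pooled_sites, factors).rdnsv
        assert set_statistic(table, genes, "rdnsv", w=4.0) == pytest.approx(expected, rel=1e-12)


class TestPermutationTest:
    def test_identical_composition_gives_p_one(self):
        table = make_table(UNIFORM)
        a = GeneSet("a", tuple(f"g{i}" for i in range(6)))
        b = GeneSet("b", tuple(f"g{i}" for i in range(6, 12)))
        result = permutation_test(table, a, b, statistic="rdnsv", n_perm=200, seed=1)
        assert result.observed_diff == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_overlapping_sets_rejected(self):
        table = make_table(UNIFORM)
        a = GeneSet("a", ("g0", "g1"))
        b = GeneSet("b", ("g1", "g2"))
        with pytest.raises(ValueError, match="disjoint"):
            permutation_test(table, a, b)

    def test_exhaustive_matches_brute_force_3v3(self):
        rng = np.random.default_rng(3)
        rows = {
            f"g{i}": tuple(v)
            for i, v in enumerate(
                np.column_stack(
                    [
                        rng.poisson(8, 6), rng.poisson(10, 6),
                        rng.uniform(5, 15, 6), rng.uniform(5, 15, 6),
                        rng.uniform(5, 15, 6), rng.uniform(15, 30, 6),
                    ]
                )
            )
        }
        table = make_table(rows)
        a = GeneSet("a", ("g0", "g1", "g2"))
        b = GeneSet("b", ("g3", "g4", "g5"))
        result = permutation_test(table, a, b, statistic="Rn/Rs", exhaustive=True)
        assert result.n_perm == 20  # C(6,3) partitions
        # independent brute force over all partitions
        from itertools import combinations

        data = table.loc[[*a.members, *b.members]].to_numpy(dtype=float)

        def stat(mat):
            ns, s, sts, stv, nts, ntv = mat.sum(axis=0)
            return (ns / (nts + ntv)) / (s / (sts + stv))

        obs = stat(data[:3]) - stat(data[3:])
        hits = 0
        for idx in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            if abs(stat(data[list(idx)]) - stat(data[rest])) >= abs(obs) - 1e-12:
                hits += 1
        assert result.p_value == pytest.approx(hits / 20)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(9)
        rows = {
            f"g{i}": (rng.poisson(8), rng.poisson(10), 10.0, 10.0, 8.0, 22.0)
            for i in range(8)
        }
        table = make_table(rows)
        a = GeneSet("a", tuple(f"g{i}" for i in range(4)))
        b = GeneSet("b", tuple(f"g{i}" for i in range(4, 8)))
        exact = permutation_test(table, a, b, statistic="rdnsv", exhaustive=True)
        mc = permutation_test(table, a, b, statistic="rdnsv", n_perm=4000, seed=0)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2 / 4001

    def test_add_one_correction_keeps_p_positive(self):
        rows = dict(UNIFORM)
        rows["g0"] = (50, 1, 10.0, 10.0, 8.0, 20.0)  # extreme outlier in set a
        table = make_table(rows)
        a = GeneSet("a", ("g0", "g1"))
        b = GeneSet("b", ("g2", "g3"))
        result = permutation_test(table, a, b, n_perm=100, seed=0)
        assert result.p_value >= 1 / 101


class TestBackgroundQuantiles:
    def test_constant_statistic_collapses_envelope(self):
        table = make_table(UNIFORM)
        env = background_quantiles(table, set_size=5, n_draws=50, statistic="rdnsv", seed=0)
        assert env.q_low == pytest.approx(env.q_high)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        rows = {
            f"g{i}": (rng.poisson(8), rng.poisson(10), 10.0, 10.0, 8.0, 22.0)
            for i in range(30)
        }
        table = make_table(rows)
        env1 = background_quantiles(table, set_size=10, n_draws=10, seed=7)
        env2 = background_quantiles(table, set_size=10, n_draws=10, seed=7)
        assert (env1.q_low, env1.q_high) == (env2.q_low, env2.q_high)

    def test_set_size_exceeding_universe_rejected(self):
        table = make_table(UNIFORM)
        with pytest.raises(ValueError, match="exceeds universe"):
            background_quantiles(table, set_size=100, n_draws=5)

    def test_depressed_candidate_falls_below_envelope(self):
        rng = np.random.default_rng(12)
        rows = {}
        for i in range(200):
            depressed = i < 30
            lam_ns = 2 if depressed else 12
            rows[f"g{i}"] = (rng.poisson(lam_ns), rng.poisson(10), 10.0, 10.0, 8.0, 22.0)
        table = make_table(rows)
        candidate = [f"g{i}" for i in range(30)]
        value = set_statistic(table, candidate, "rdnsv")
        env = background_quantiles(table, set_size=30, n_draws=400, seed=1)
        assert value < env.q_low


class TestSelectTissueSpecific:
    def test_eightfold_overexpression_is_specific(self):
        expr = pd.DataFrame(
            {f"t{i}": [2.0] for i in range(9)} | {"brain": [16.0]}, index=["g1"]
        )
        specific = tissue_specificity(expr)
        assert bool(specific.loc["g1", "brain"])
        assert specific.loc["g1"].sum() == 1

    def test_constant_gene_specific_nowhere(self):
        expr = pd.DataFrame({f"t{i}": [4.0] for i in range(5)}, index=["flat"])
        assert tissue_specificity(expr).loc["flat"].sum() == 0

    def test_selection_ranks_by_target_tissue_count(self):
        rng = np.random.default_rng(0)
        tissues = [f"target{i}" for i in range(4)] + [f"other{i}" for i in range(6)]
        rows = {}
        rows["multi"] = [64.0] * 4 + [1.0] * 6  # specific in all 4 targets
        rows["single"] = [64.0] + [1.0] * 9  # specific in 1 target
        rows["none"] = [1.0] * 10
        expr = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
        selected = select_tissue_specific(expr, tissues[:4], k=2)
        assert selected.members == ("multi", "single")

    def test_nonpositive_values_rejected(self):
        expr = pd.DataFrame({"t1": [0.0], "t2": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="positive"):
            select_tissue_specific(expr, ["t1"], k=1)

    def test_remove_shared(self):
        a = GeneSet("a", ("g1", "g2", "g3"))
        b = GeneSet("b", ("g3", "g4"))
        new_a, new_b, shared = remove_shared(a, b)
        assert shared == ("g3",)
        assert new_a.members == ("g1", "g2")
        assert new_b.members == ("g4",)


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        # smaller replicate count than the acceptance suite; same construction
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            rows = {
                f"g{i}": (rng.poisson(8), rng.poisson(10), 10.0, 10.0, 8.0, 22.0)
                for i in range(16)
            }
            table = make_table(rows)
            a = GeneSet("a", tuple(f"g{i}" for i in range(8)))
            b = GeneSet("b", tuple(f"g{i}" for i in range(8, 16)))
            res = permutation_test(
                table, a, b, statistic="Rn/Rs", n_perm=199,
                seed=int(rng.integers(1 << 31)),
            )
            if res.p_value <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.09
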