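import numpy as np
import pytest

from renschrule import (
    FormatError,
    InsufficientDataError,
    MismatchError,
    SpeciesRecord,
    TraitTable,
    UnsupportedTopologyError,
    ValidationError,
    ancestral_values,
    compute_contrasts,
    prune_and_align,
    read_newick,
    simulate_traits,
    simulate_tree,
    standardization_check,
    write_newick,
)
from renschrule.simulate import SimulationConfig

from _oracles import pic_oracle


class TestNewickIO:
    def test_read_counts_nodes(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 2

    def test_missing_branch_lengths_stay_absent(self):
        tree = read_newick("((A,B),C);")
        assert all(n.edge.length is None for n in tree.preorder_node_iter())

    def test_malformed_newick_raises(self):
        with pytest.raises(FormatError):
            read_newick("((A:1,B:1:1,C;")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_round_trip_random_tree(self):
        tree = simulate_tree(SimulationConfig(seed=5, branch_lengths="exponential"))
        text = write_newick(tree)
        assert write_newick(read_newick(text)) == text


class TestAncestralValues:
    def test_cherry_algebraic_mean(self):
        anc = ancestral_values(read_newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0})
        assert anc[frozenset({"A", "B"})] == pytest.approx(2.0)

    def test_cherry_weighted_equal_branches_is_mean(self):
        anc = ancestral_values(
            read_newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0}, "felsenstein_weighted"
        )
        assert anc[frozenset({"A", "B"})] == pytest.approx(2.0)

    def test_cherry_weighted_unequal_branches(self):
        # (3/1 + 1/3) / (1 + 1/3) = 2.5: the shorter branch dominates
        anc = ancestral_values(
            read_newick("(A:1,B:3);"), {"A": 3.0, "B": 1.0}, "felsenstein_weighted"
        )
        assert anc[frozenset({"A", "B"})] == pytest.approx(2.5)

    def test_missing_tip_value_names_tip(self):
        with pytest.raises(ValidationError, match="B"):
            ancestral_values(read_newick("(A:1,B:1);"), {"A": 3.0})

    def test_polytomy_rejected(self):
        with pytest.raises(UnsupportedTopologyError):
            ancestral_values(read_newick("(A:1,B:1,C:1);"), {"A": 1, "B": 2, "C": 3})


class TestContrasts:
    def test_cherry_textbook_case(self):
        cs = compute_contrasts(
            read_newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0}, {"A": 1.0, "B": 3.0}
        )
        assert len(cs) == 1
        assert cs.x[0] == pytest.approx(2.0 / np.sqrt(2.0))
        assert cs.y[0] == pytest.approx(-2.0 / np.sqrt(2.0))
        raw = compute_contrasts(
            read_newick("(A:1,B:1);"),
            {"A": 3.0, "B": 1.0},
            {"A": 1.0, "B": 3.0},
            standardize=False,
        )
        assert raw.x[0] == pytest.approx(2.0)
        assert raw.scales[0] == pytest.approx(np.sqrt(2.0))

    def test_identical_tip_values_give_zero_contrasts(self):
        tree = simulate_tree(SimulationConfig(seed=1, n_species=8))
        vals = {leaf.taxon.label: 7.0 for leaf in tree.leaf_node_iter()}
        cs = compute_contrasts(tree, vals, vals)
        assert np.allclose(cs.x, 0.0) and np.allclose(cs.y, 0.0)

    @pytest.mark.parametrize("method", ["algebraic_mean", "felsenstein_weighted"])
    def test_count_is_tips_minus_one(self, method):
        for n in (3, 7, 24, 39):
            tree = simulate_tree(SimulationConfig(seed=n, n_species=n))
            vals = {
                leaf.taxon.label: float(i)
                for i, leaf in enumerate(tree.leaf_node_iter())
            }
            cs = compute_contrasts(tree, vals, vals, method=method)
            assert len(cs) == n - 1

    @pytest.mark.parametrize("method", ["algebraic_mean", "felsenstein_weighted"])
    def test_matches_recursive_oracle_small_tree(self, method):
        tree = read_newick("(((A:1,B:2):1.5,(C:0.5,D:1):2):1,E:4);")
        x = {"A": 1.0, "B": 4.0, "C": -2.0, "D": 0.5, "E": 3.0}
        y = {"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0, "E": 4.0}
        cs = compute_contrasts(tree, x, y, method=method)
        oracle = pic_oracle(tree, x, method)
        for c in cs:
            ref = oracle[frozenset(c.tips)]
            assert c.contrast_x == pytest.approx(ref["standardized"], rel=1e-12)
            assert c.scale == pytest.approx(ref["scale"], rel=1e-12)

    def test_daughter_order_flip_flips_both_signs(self):
        a = read_newick("((A:1,B:1):1,C:2);")
        b = read_newick("((B:1,A:1):1,C:2);")
        x = {"A": 1.0, "B": 5.0, "C": 2.0}
        y = {"A": 2.0, "B": 1.0, "C": 0.0}
        ca = compute_contrasts(a, x, y)
        cb = compute_contrasts(b, x, y)
        key = frozenset({"A", "B"})
        rec_a = next(c for c in ca if frozenset(c.tips) == key)
        rec_b = next(c for c in cb if frozenset(c.tips) == key)
        assert rec_b.contrast_x == pytest.approx(-rec_a.contrast_x)
        assert rec_b.contrast_y == pytest.approx(-rec_a.contrast_y)


class TestStandardizationCheck:
    def test_correct_bm_standardization_mostly_passes(self):
        passed = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=seed, n_species=30, branch_lengths="exponential",
                ssd_sad_coupling=0.0,
            )
            tree = simulate_tree(cfg)
            table, _ = simulate_traits(tree, cfg)
            x = {r.species: float(np.log10(r.female_size)) for r in table}
            cs = compute_contrasts(tree, x, x, method="felsenstein_weighted")
            if standardization_check(cs).passed:
                passed += 1
        assert passed >= 0.9 * n_rep

    def test_unstandardized_contrasts_on_spread_branches_fail(self):
        # tips under a 100-fold branch-length spread: raw contrasts from the
        # long branches are systematically larger, so the check must fail
        rng = np.random.default_rng(0)
        tips: dict[str, float] = {}
        text = None
        for i in range(20):  # ladder of cherries, alternating length scales
            bl = 0.05 if i % 2 == 0 else 5.0
            tips[f"t{i}a"], tips[f"t{i}b"] = rng.normal(0.0, np.sqrt(bl), 2)
            cherry = f"(t{i}a:{bl},t{i}b:{bl})"
            text = cherry if text is None else f"({text}:1,{cherry}:1)"
        tree = read_newick(text + ";")
        cs_raw = compute_contrasts(tree, tips, tips, standardize=False)
        # masquerade raw contrasts as standardized to run the diagnostic
        cs_raw.standardized = True
        assert not standardization_check(cs_raw).passed

    def test_too_few_contrasts(self):
        cs = compute_contrasts(read_newick("(A:1,B:1);"), {"A": 1.0, "B": 0.0}, {"A": 1.0, "B": 0.0})
        with pytest.raises(InsufficientDataError):
            standardization_check(cs)

    def test_bm_contrasts_are_normal(self):
        """Standardized BM contrasts pass a KS normality screen at a high rate."""
        from renschrule import ks_normality

        passing = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=seed + 1000, n_species=25, branch_lengths="exponential",
                residual_sigma=0.0, ssd_sad_coupling=0.0,
            )
            tree = simulate_tree(cfg)
            table, _ = simulate_traits(tree, cfg)
            x = {r.species: float(np.log10(r.female_size)) for r in table}
            cs = compute_contrasts(tree, x, x, method="felsenstein_weighted")
            if ks_normality(cs.x).p_value > 0.01:
                passing += 1
        assert passing >= 0.95 * n_rep


class TestPruneAndAlign:
    def _table(self, names):
        return TraitTable(
            records=[SpeciesRecord(n, 50.0 + i, 45.0 + i) for i, n in enumerate(names)]
        )

    def test_extra_tip_pruned(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        t2, tbl2 = prune_and_align(tree, self._table(["A", "B"]))
        assert sorted(l.taxon.label for l in t2.leaf_node_iter()) == ["A", "B"]
        assert tbl2.species == [l.taxon.label for l in t2.leaf_node_iter()]

    def test_exact_match_identity(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        t2, tbl2 = prune_and_align(tree, self._table(["A", "B", "C"]))
        assert len(tbl2) == 3
        assert sorted(l.taxon.label for l in t2.leaf_node_iter()) == ["A", "B", "C"]

    def test_pruned_subset_contrast_count(self):
        cfg = SimulationConfig(seed=2, n_species=39)
        tree = simulate_tree(cfg)
        names = [l.taxon.label for l in tree.leaf_node_iter()][:36]
        t2, tbl2 = prune_and_align(tree, self._table(names))
        assert len(tbl2) == 36
        x = {r.species: float(r.female_size) for r in tbl2}
        assert len(compute_contrasts(t2, x, x)) == 35

    def test_empty_intersection_fatal(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(MismatchError):
            prune_and_align(tree, self._table(["X", "Y"]))

    def test_suppressed_node_branch_lengths_summed(self):
        tree = read_newick("((A:1,B:1):2,C:3);")
        t2, _ = prune_and_align(tree, self._table(["A", "C"]))
        lengths = {l.taxon.label: l.edge.length for l in t2.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(3.0)  # 1 (tip) + 2 (suppressed)
        assert lengths["C"] == pytest.approx(3.0)
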