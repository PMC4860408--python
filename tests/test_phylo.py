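import dendropy
import numpy as np
import pytest
import scipy.optimize

from ecomorph import (
    ancestral_states,
    independent_contrasts,
    phylo_signal_test,
    read_tree,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestAncestralStates:
    def test_constant_tips_everywhere(self):
        tree = _tree("((A:1,B:2):0.5,(C:1.5,D:1):0.8);")
        v = np.array([2.5, -1.0])
        states, length = ancestral_states(tree, {t: v for t in "ABCD"})
        for node_value in states.values():
            np.testing.assert_allclose(node_value, v)
        assert length == pytest.approx(0.0, abs=1e-20)

    def test_star_tree_root_is_mean(self):
        tree = read_tree(_tree("(A:1,B:1,C:1,D:1);"))
        tips = {t: np.array([x]) for t, x in zip("ABCD", [1.0, 2.0, 3.0, 6.0])}
        states, _ = ancestral_states(tree, tips)
        root = states[tree.seed_node]
        assert root[0] == pytest.approx(3.0, abs=1e-4)

    def test_matches_numeric_minimization(self):
        """4-tip tree: exact solution vs a generic optimizer."""
        newick = "((A:1,B:2):0.5,(C:1.5,D:1):0.8);"
        tree = _tree(newick)
        tips = {"A": 1.0, "B": 4.0, "C": -2.0, "D": 0.5}
        states, length = ancestral_states(
            tree, {k: np.array([v]) for k, v in tips.items()}
        )
        # free values: root, node (A,B), node (C,D)
        bl = {"A": 1.0, "B": 2.0, "C": 1.5, "D": 1.0, "nAB": 0.5, "nCD": 0.8}

        def objective(z):
            root, nab, ncd = z
            return (
                (tips["A"] - nab) ** 2 / bl["A"]
                + (tips["B"] - nab) ** 2 / bl["B"]
                + (tips["C"] - ncd) ** 2 / bl["C"]
                + (tips["D"] - ncd) ** 2 / bl["D"]
                + (nab - root) ** 2 / bl["nAB"]
                + (ncd - root) ** 2 / bl["nCD"]
            )

        opt = scipy.optimize.minimize(objective, np.zeros(3), method="BFGS")
        assert length == pytest.approx(opt.fun, rel=1e-8)
        root_node = tree.seed_node
        assert states[root_node][0] == pytest.approx(opt.x[0], abs=1e-6)

    def test_mismatched_tips_rejected(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            ancestral_states(tree, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestPhyloSignal:
    TREE = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"

    def test_tree_length_invariant_to_tip_order_and_quadratic_scaling(self, rng):
        tree = _tree(self.TREE)
        tips = {t: rng.normal(0, 1, 3) for t in "ABCDEFGH"}
        r1 = phylo_signal_test(tree, tips, n_perm=19, seed=0)
        scaled = {t: 2.0 * v for t, v in tips.items()}
        r2 = phylo_signal_test(_tree(self.TREE), scaled, n_perm=19, seed=0)
        assert r2.tree_length == pytest.approx(4.0 * r1.tree_length, rel=1e-9)

    def test_clustered_tips_give_signal(self):
        """Values tracking the two clades yield a small p."""
        tree = _tree(self.TREE)
        tips = {t: np.array([0.0 if t in "ABCD" else 5.0]) for t in "ABCDEFGH"}
        res = phylo_signal_test(tree, tips, n_perm=499, seed=1)
        assert res.permutation_p < 0.05  # ties: only 70 distinct 4/4 splits

    def test_brownian_tips_detected(self, rng):
        """Power against a Brownian alternative at 16 tips."""
        tips16 = "(" * 1  # built below
        # balanced 16-tip tree
        def balanced(labels, bl=1.0):
            if len(labels) == 1:
                return f"{labels[0]}:{bl}"
            half = len(labels) // 2
            return f"({balanced(labels[:half])},{balanced(labels[half:])}):{bl}"

        labels = [f"t{i}" for i in range(16)]
        newick = balanced(labels) + ";"
        hits = 0
        for rep in range(20):
            tree = _tree(newick)
            node_val = {}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    node_val[node] = 0.0
                else:
                    node_val[node] = node_val[node.parent_node] + rng.normal(
                        0, np.sqrt(node.edge.length or 1.0)
                    )
            tips = {
                leaf.taxon.label: np.array([node_val[leaf]])
                for leaf in tree.leaf_node_iter()
            }
            res = phylo_signal_test(tree, tips, n_perm=199, seed=rep)
            hits += res.permutation_p < 0.05
        assert hits / 20 > 0.5

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            phylo_signal_test(_tree("(A:1,B:1,C:1);"), {"A": 1.0, "B": 2.0, "C": 3.0})


class TestIndependentContrasts:
    def test_two_tip_definition(self):
        tree = _tree("(A:2,B:3);")
        c = independent_contrasts(tree, {"A": np.array([5.0]), "B": np.array([1.0])})
        assert c[0, 0] == pytest.approx((5.0 - 1.0) / np.sqrt(5.0))

    def test_constant_tips_zero_contrasts(self):
        tree = _tree("((A:1,B:2):0.5,(C:1.5,D:1):0.8);")
        c = independent_contrasts(tree, {t: np.array([7.0]) for t in "ABCD"})
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_matches_dendropy_pic(self):
        """Cross-check against dendropy's own contrasts implementation."""
        from dendropy.model import continuous

        newick = "((A:1.0,B:2.0):0.5,(C:1.5,D:1.0):0.8);"
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)
        values = {"A": 1.0, "B": 4.0, "C": -2.0, "D": 0.5}
        chars = dendropy.ContinuousCharacterMatrix.from_dict(
            {k: [v] for k, v in values.items()}, taxon_namespace=taxa
        )
        pic = continuous.PhylogeneticIndependentContrasts(tree=tree, char_matrix=chars)
        ctree = pic.contrasts_tree(character_index=0)
        ref = sorted(
            abs(nd.pic[0]["pic_contrast_standardized"])
            for nd in ctree.preorder_internal_node_iter()
        )
        mine = sorted(
            np.abs(
                independent_contrasts(
                    _tree(newick), {k: np.array([v]) for k, v in values.items()}
                )[:, 0]
            )
        )
        np.testing.assert_allclose(mine, ref, rtol=1e-8)

    def test_brownian_slope_recovered(self, rng):
        """Contrast regression recovers the evolutionary slope."""
        def balanced(labels, bl=1.0):
            if len(labels) == 1:
                return f"{labels[0]}:{bl}"
            half = len(labels) // 2
            return f"({balanced(labels[:half])},{balanced(labels[half:])}):{bl}"

        labels = [f"t{i}" for i in range(64)]
        newick = balanced(labels) + ";"
        slopes = []
        for rep in range(50):
            tree = _tree(newick)
            xval, yval = {}, {}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    xval[node], yval[node] = 0.0, 0.0
                else:
                    bl = node.edge.length or 1.0
                    dx = rng.normal(0, np.sqrt(bl))
                    xval[node] = xval[node.parent_node] + dx
                    yval[node] = (
                        yval[node.parent_node] + 0.8 * dx + rng.normal(0, 0.3 * np.sqrt(bl))
                    )
            tips_x = {l.taxon.label: np.array([xval[l]]) for l in tree.leaf_node_iter()}
            tips_y = {l.taxon.label: np.array([yval[l]]) for l in tree.leaf_node_iter()}
            cx = independent_contrasts(tree, tips_x)[:, 0]
            cy = independent_contrasts(tree, tips_y)[:, 0]
            slopes.append((cx @ cy) / (cx @ cx))  # through the origin
        assert np.mean(slopes) == pytest.approx(0.8, abs=0.04)  # bias < 5%


class TestReadTree:
    def test_polytomy_resolution_warns(self):
        with pytest.warns(UserWarning, match="polytom"):
            tree = read_tree(_tree("(A:1,B:1,C:1,D:1);"))
        for node in tree.preorder_internal_node_iter():
            assert len(node.child_nodes()) <= 2

    def test_shipped_synthetic_tree_loads(self):
        from importlib import resources

        ref = resources.files("ecomorph.data").joinpath("canid_tree_synthetic.nwk")
        with resources.as_file(ref) as p:
            tree = read_tree(p)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert "Cerdocyon thous" in labels
        assert len(labels) == 8
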