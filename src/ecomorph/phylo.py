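"""Phylogenetic comparative tools: squared-change parsimony ancestral
states, a tip-permutation test for phylogenetic signal, and Felsenstein's
independent contrasts.

Ancestral values minimize the branch-length-weighted sum of squared
changes, Σ‖Δ‖²/l, solved exactly by the standard two-pass linear
algorithm.  The "tree length" statistic is that minimized criterion (an
unweighted sum-of-squared-changes option is available); signal is assessed
by permuting tip values and recomputing, small observed lengths meaning
less change than random, i.e. signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

MIN_BRANCH = 1e-8


def read_tree(source, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree; polytomies are resolved with epsilon branches."""
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        tree = dendropy.Tree.get(path=str(source), schema=schema)
    polytomy = any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter())
    if polytomy:
        warnings.warn(
            "polytomies resolved arbitrarily with epsilon-length branches",
            stacklevel=2,
        )
        tree.resolve_polytomies()
    floored = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < MIN_BRANCH:
            edge.length = MIN_BRANCH
            floored = True
    if floored:
        warnings.warn(f"branch lengths floored at {MIN_BRANCH}", stacklevel=2)
    return tree


def _tip_order(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def ancestral_states(tree: dendropy.Tree, tip_values: dict[str, np.ndarray]):
    """Weighted squared-change-parsimony ancestral reconstruction.

    ``tip_values`` maps taxon label → value vector (scalars allowed).
    Returns (node_values, tree_length): a dict from dendropy node to the
    reconstructed vector, and the minimized Σ‖Δ‖²/branch-length.
    """
    labels = _tip_order(tree)
    if set(labels) != set(tip_values):
        raise ValueError("tip labels and tip_values keys must match exactly")
    dim = np.atleast_1d(np.asarray(tip_values[labels[0]], float)).size
    # downpass: prune toward the root accumulating (value, effective length)
    down_val: dict = {}
    down_len: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down_val[node] = np.atleast_1d(np.asarray(tip_values[node.taxon.label], float))
            down_len[node] = max(node.edge.length or 0.0, MIN_BRANCH)
        else:
            children = node.child_nodes()
            w = np.array([1.0 / down_len[c] for c in children])
            vals = np.stack([down_val[c] for c in children])
            down_val[node] = (w[:, None] * vals).sum(axis=0) / w.sum()
            extra = 1.0 / w.sum()
            base = node.edge.length if node is not tree.seed_node else 0.0
            down_len[node] = max(base or 0.0, 0.0) + extra

    # uppass: finalize internal values combining children and parent
    final: dict = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            final[node] = down_val[node]
            continue
        if node is tree.seed_node:
            final[node] = down_val[node]
            continue
        parent_val = final[node.parent_node]
        # parent contribution travels down this node's own branch; its
        # effective resistance excludes this subtree's downpass info
        children = node.child_nodes()
        w_children = np.array([1.0 / down_len[c] for c in children])
        vals = np.stack([down_val[c] for c in children])
        bl = max(node.edge.length or 0.0, MIN_BRANCH)
        w_parent = 1.0 / bl
        num = (w_children[:, None] * vals).sum(axis=0) + w_parent * parent_val
        final[node] = num / (w_children.sum() + w_parent)

    length = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = max(node.edge.length or 0.0, MIN_BRANCH)
        delta = final[node] - final[node.parent_node]
        length += float(delta @ delta) / bl
    return final, length


def _tree_quadratic_form(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Matrix Q with tree_length(x) = xᵀ Q x for scalar tip values.

    The reconstruction is linear in the tips, so the minimized criterion is
    a quadratic form; computing Q once makes mass permutation testing
    cheap.  Built by evaluating the reconstruction on unit tip vectors.
    """
    labels = _tip_order(tree)
    t = len(labels)
    basis_lengths = np.empty((t, t))
    # tree_length(e_i + e_j) etc. — derive Q from bilinearity:
    # q_ii = TL(e_i); q_ij = (TL(e_i + e_j) − TL(e_i) − TL(e_j))/2
    tl_single = np.empty(t)
    for i in range(t):
        tips = {lab: np.array([1.0 if j == i else 0.0]) for j, lab in enumerate(labels)}
        _, tl_single[i] = ancestral_states(tree, tips)
    q = np.empty((t, t))
    for i in range(t):
        q[i, i] = tl_single[i]
    for i in range(t):
        for j in range(i + 1, t):
            tips = {
                lab: np.array([1.0 if m in (i, j) else 0.0])
                for m, lab in enumerate(labels)
            }
            _, tl = ancestral_states(tree, tips)
            q[i, j] = q[j, i] = (tl - tl_single[i] - tl_single[j]) / 2.0
    return q, labels


@dataclass
class PhyloSignalResult:
    tree_length: float
    permutation_p: float
    n_permutations: int


def phylo_signal_test(
    tree: dendropy.Tree,
    tip_values: dict[str, np.ndarray],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Tip-permutation test for phylogenetic signal.

    The observed tree length is compared with lengths obtained after
    randomly permuting tip values across the tips;
    p = (#{permuted ≤ observed} + 1)/(n_perm + 1).  Small p means related
    species resemble each other more than chance allows.
    """
    labels = _tip_order(tree)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips")
    x = np.stack(
        [np.atleast_1d(np.asarray(tip_values[lab], float)) for lab in labels]
    )  # (t, d)
    q, _ = _tree_quadratic_form(tree)
    observed = float(np.einsum("id,ij,jd->", x, q, x))
    rng = np.random.default_rng(seed)
    t = len(labels)
    count = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(t)]
        tl = float(np.einsum("id,ij,jd->", xp, q, xp))
        if tl <= observed + 1e-12:
            count += 1
    return PhyloSignalResult(
        tree_length=observed,
        permutation_p=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
    )


def independent_contrasts(
    tree: dendropy.Tree, tip_values: dict[str, np.ndarray]
) -> np.ndarray:
    """Felsenstein's standardized independent contrasts, ((t−1), d).

    Each internal node contributes the difference of its two daughters'
    values divided by the square root of their summed effective branch
    lengths; under Brownian motion the contrasts are i.i.d.  Downstream
    regressions on contrasts must run through the origin.
    """
    labels = _tip_order(tree)
    if set(labels) != set(tip_values):
        raise ValueError("tip labels and tip_values keys must match exactly")
    vals: dict = {}
    lens: dict = {}
    contrasts = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vals[node] = np.atleast_1d(np.asarray(tip_values[node.taxon.label], float))
            lens[node] = max(node.edge.length or 0.0, MIN_BRANCH)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be strictly bifurcating (resolve first)")
        c1, c2 = children
        v1, v2 = vals[c1], vals[c2]
        l1, l2 = lens[c1], lens[c2]
        contrasts.append((v1 - v2) / np.sqrt(l1 + l2))
        vals[node] = (v1 / l1 + v2 / l2) / (1.0 / l1 + 1.0 / l2)
        extra = (l1 * l2) / (l1 + l2)
        base = node.edge.length if node is not tree.seed_node else 0.0
        lens[node] = max(base or 0.0, 0.0) + extra
    return np.stack(contrasts)
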