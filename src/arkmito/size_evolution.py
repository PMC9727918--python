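"""Brownian-motion ancestral reconstruction of mitogenome size on a tree.

Under Brownian motion (BM) a continuous trait accumulates variance
linearly with branch length; the maximum-likelihood state at an internal
node equals the generalized-least-squares estimate obtained by re-rooting
the tree at that node, (1'C^-1 x)/(1'C^-1 1), with C the BM covariance of
the tips (shared root-to-tip path lengths).  The implementation computes
all node estimates in two tree traversals by Gaussian message passing
(each neighbour contributes an inverse-variance-weighted mean), which is
algebraically identical to per-node GLS but linear-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; thin wrapper over dendropy."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_labels(self) -> list[str]:
        """Stable labels for internal nodes (preorder 'node0', 'node1', ...)."""
        labels = []
        i = 0
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf():
                if nd.label is None:
                    nd.label = f"node{i}"
                labels.append(nd.label)
                i += 1
        return labels


@dataclass
class AncestralEstimates:
    node_states: dict[str, float]
    node_variances: dict[str, float]
    sigma2_hat: float
    root_state: float
    root_label: str = ""


def read_newick(path_or_string, is_string: bool = False) -> PhyloTree:
    """Parse a rooted Newick tree; every edge needs a branch length."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if is_string:
        tree = dendropy.Tree.get(data=path_or_string, **kwargs)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), **kwargs)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"edge above {edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'} "
                "has no branch length (required for BM)"
            )
        if edge.length < 0:
            raise ValueError("negative branch length")
    return PhyloTree(tree)


def write_newick(pt: PhyloTree, path) -> None:
    pt.tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# message passing


def _combine(messages: list[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance-weighted combination of Gaussian messages."""
    exact = [m for m, v in messages if v == 0.0]
    if exact:
        if len({round(m, 12) for m in exact}) > 1:
            raise ValueError(
                "zero-length branches force conflicting exact values (singular BM "
                "covariance); prune zero-length cherries"
            )
        return exact[0], 0.0
    prec = sum(1.0 / v for _, v in messages)
    mean = sum(m / v for m, v in messages) / prec
    return mean, 1.0 / prec


def bm_covariance(pt: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Explicit n x n BM tip covariance (shared path length to the root)."""
    tips = list(pt.tree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    depth: dict = {pt.tree.seed_node: 0.0}
    for nd in pt.tree.preorder_node_iter():
        if nd is pt.tree.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + nd.edge.length
    n = len(tips)
    C = np.zeros((n, n))
    pdm = {}
    for i, a in enumerate(tips):
        anc_a = set()
        nd = a
        while nd is not None:
            anc_a.add(nd)
            nd = nd.parent_node
        pdm[i] = anc_a
    for i in range(n):
        for j in range(i, n):
            nd = tips[j]
            while nd not in pdm[i]:
                nd = nd.parent_node
            C[i, j] = C[j, i] = depth[nd]
    return C, labels


def bm_ancestral(pt: PhyloTree, tip_values: dict[str, float]) -> AncestralEstimates:
    """ML (GLS) ancestral states for a BM trait at every internal node.

    ``sigma2_hat`` is the ML rate at the root, (x-a)'C^-1(x-a)/n.
    """
    tree = pt.tree
    tips = list(tree.leaf_node_iter())
    missing = [t.taxon.label for t in tips if t.taxon.label not in tip_values]
    if missing:
        raise ValueError(f"tips without trait values: {missing}")
    pt.node_labels()  # ensure internal labels exist

    up: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            up[nd] = (float(tip_values[nd.taxon.label]), 0.0)
        else:
            msgs = [(up[c][0], up[c][1] + c.edge.length) for c in nd.child_nodes()]
            up[nd] = _combine(msgs)

    down: dict = {tree.seed_node: None}
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            msgs = [(up[s][0], up[s][1] + s.edge.length)
                    for s in nd.child_nodes() if s is not child]
            if down[nd] is not None:
                msgs.append(down[nd])
            if not msgs:  # root with a single child: no outside information
                down[child] = None
                continue
            m, v = _combine(msgs)
            down[child] = (m, v + child.edge.length)

    node_states: dict[str, float] = {}
    node_varfac: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        msgs = [(up[c][0], up[c][1] + c.edge.length) for c in nd.child_nodes()]
        if down[nd] is not None:
            msgs.append(down[nd])
        m, v = _combine(msgs)
        node_states[nd.label] = m
        node_varfac[nd.label] = v

    root_label = tree.seed_node.label
    root_state = node_states[root_label]

    C, labels = bm_covariance(pt)
    x = np.array([tip_values[l] for l in labels])
    resid = x - root_state
    sigma2 = float(resid @ np.linalg.solve(C, resid) / len(x))
    node_variances = {k: sigma2 * v for k, v in node_varfac.items()}
    return AncestralEstimates(node_states, node_variances, sigma2, root_state, root_label)


def simulate_bm(
    pt: PhyloTree, sigma2: float, root_state: float, seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate BM tip values; returns (tip_values, true_node_states)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    pt.node_labels()
    states: dict = {pt.tree.seed_node: float(root_state)}
    tip_values: dict[str, float] = {}
    node_states: dict[str, float] = {}
    for nd in pt.tree.preorder_node_iter():
        if nd is not pt.tree.seed_node:
            t = nd.edge.length
            if t < 0:
                raise ValueError("negative branch length")
            states[nd] = states[nd.parent_node] + (
                rng.normal(0.0, np.sqrt(sigma2 * t)) if t > 0 else 0.0
            )
        if nd.is_leaf():
            tip_values[nd.taxon.label] = states[nd]
        else:
            node_states[nd.label] = states[nd]
    return tip_values, node_states


def size_trait_table(recs) -> dict[str, float]:
    """Tip -> mitogenome size in kb (1 decimal); one tip per genome record."""
    if not recs:
        raise ValueError("no genome records")
    return {rec.id: round(rec.length_nt / 1000.0, 1) for rec in recs}


def write_node_states(est: AncestralEstimates, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tstate\tvariance\n")
        for k in est.node_states:
            fh.write(f"{k}\t{est.node_states[k]:.6g}\t{est.node_variances[k]:.6g}\n")
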