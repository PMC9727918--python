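"""Newick handling and BM ancestral reconstruction against explicit GLS."""

import numpy as np
import pytest

from arkmito.size_evolution import (
    bm_ancestral,
    bm_covariance,
    read_newick,
    simulate_bm,
    size_trait_table,
    write_newick,
)
from arkmito.synthetic_data import gen_balanced_tree

from .oracles import bm_gls_states


class TestNewick:
    def test_parse_lengths(self):
        t = read_newick("(A:1,B:1):0;", is_string=True)
        assert sorted(t.tip_labels) == ["A", "B"]

    def test_roundtrip(self, tmp_path):
        t = read_newick("((A:1,B:2):0.5,C:3);", is_string=True)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert sorted(t2.tip_labels) == ["A", "B", "C"]

    def test_missing_length_errors(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B):1,C:1);", is_string=True)

    def test_malformed_errors(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:1;", is_string=True)


class TestBmAncestral:
    def test_star_tree_root_is_mean(self):
        t = read_newick("(A:1,B:1,C:1);", is_string=True)
        est = bm_ancestral(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert est.root_state == pytest.approx(2.0)

    def test_two_tip_inverse_branch_weighting(self):
        # branches (1, 3): root = (0/1 + 4/3) / (1 + 1/3) = 1.0
        t = read_newick("(A:1,B:3);", is_string=True)
        est = bm_ancestral(t, {"A": 0.0, "B": 4.0})
        assert est.root_state == pytest.approx(1.0)

    def test_estimates_within_tip_range(self):
        rng = np.random.default_rng(0)
        t = read_newick(gen_balanced_tree(16), is_string=True)
        vals = {l: float(rng.uniform(10, 50)) for l in t.tip_labels}
        est = bm_ancestral(t, vals)
        for v in est.node_states.values():
            assert min(vals.values()) <= v <= max(vals.values())

    def test_translation_and_scale_equivariance(self):
        t = read_newick("((A:1,B:2):0.5,(C:1.5,D:0.7):1);", is_string=True)
        vals = {"A": 1.0, "B": 5.0, "C": 2.0, "D": 9.0}
        base = bm_ancestral(t, vals)
        shifted = bm_ancestral(t, {k: v + 11.0 for k, v in vals.items()})
        scaled = bm_ancestral(t, {k: 3.0 * v for k, v in vals.items()})
        for k in base.node_states:
            assert shifted.node_states[k] == pytest.approx(base.node_states[k] + 11.0)
            assert scaled.node_states[k] == pytest.approx(3.0 * base.node_states[k])

    def test_missing_tip_value_errors(self):
        t = read_newick("(A:1,B:1);", is_string=True)
        with pytest.raises(ValueError):
            bm_ancestral(t, {"A": 1.0})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_rerooted_gls_oracle(self, seed):
        """Message-passing estimates equal explicit re-rooting + n x n GLS."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 33))
        newick = _random_tree_newick(rng, n)
        t = read_newick(newick, is_string=True)
        vals = {l: float(rng.normal(30, 5)) for l in t.tip_labels}
        est = bm_ancestral(t, vals)
        oracle = bm_gls_states(newick, vals)
        for label, state in oracle.items():
            assert est.node_states[label] == pytest.approx(state, abs=1e-8)

    def test_polytomy_supported(self):
        t = read_newick("(A:1,B:1,C:1,(D:1,E:1):1);", is_string=True)
        vals = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}
        est = bm_ancestral(t, {k: float(v) for k, v in vals.items()})
        assert len(est.node_states) == 2

    def test_conflicting_zero_length_cherry_errors(self):
        t = read_newick("((A:0,B:0):1,C:1);", is_string=True)
        with pytest.raises(ValueError):
            bm_ancestral(t, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestSimulation:
    def test_zero_length_branch_copies_parent(self):
        t = read_newick("((A:0,B:1):1,C:1);", is_string=True)
        tips, nodes = simulate_bm(t, sigma2=1.0, root_state=0.0, seed=1)
        # A sits at zero distance below the cherry's parent (node1)
        assert tips["A"] == nodes["node1"]

    def test_determinism(self):
        t1 = read_newick(gen_balanced_tree(8), is_string=True)
        t2 = read_newick(gen_balanced_tree(8), is_string=True)
        assert simulate_bm(t1, 1.0, 30.0, seed=9) == simulate_bm(t2, 1.0, 30.0, seed=9)

    def test_tip_variance_scales_with_depth(self):
        newick = gen_balanced_tree(4, branch_length=2.0)
        vals = []
        for s in range(300):
            t = read_newick(newick, is_string=True)
            tips, _ = simulate_bm(t, sigma2=1.5, root_state=0.0, seed=s)
            vals.append(tips["t0"])
        depth = 2.0 * 2  # two edges of length 2 root->tip
        assert np.var(vals) == pytest.approx(1.5 * depth, rel=0.25)

    def test_root_recovery_unbiased(self):
        """Mean root estimate over replicates is within 2 SE of the truth."""
        newick = gen_balanced_tree(32)
        estimates = []
        for s in range(200):
            t = read_newick(newick, is_string=True)
            tips, _ = simulate_bm(t, sigma2=1.0, root_state=30.0, seed=1000 + s)
            estimates.append(bm_ancestral(t, tips).root_state)
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 30.0) < 2 * se + 1e-9


def _random_tree_newick(rng, n_tips):
    """Random binary tree by sequential attachment, lengths U(0.2, 2)."""
    nodes = [f"t{i}:{rng.uniform(0.2, 2):.3f}" for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(0.2, 2):.3f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def test_size_trait_table(small_genome):
    rec, _ = small_genome
    table = size_trait_table([rec])
    assert table[rec.id] == round(rec.length_nt / 1000, 1)
    with pytest.raises(ValueError):
        size_trait_table([])
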