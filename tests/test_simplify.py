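"""Graph recruitment (BFS) and depth-based simplification rules."""

import random

import numpy as np
import pytest

from conftest import make_graph, random_assembly_graph
from mitograph.core import HEAD, TAIL, GraphError, MitographError
from mitograph.simplify import (
    DepthModel,
    PruneParams,
    classify_by_depth,
    estimate_nuclear_depth,
    extend_seeds_bfs,
    prune_weak_links,
    remove_nuclear_like,
    remove_tips,
    reserved_mtpt_contigs,
    resolve_plastid_contigs,
    simplify_graph,
)


class TestNuclearDepth:
    def test_identity_case(self):
        assert estimate_nuclear_depth(1e9, 1e9) == 1.0

    def test_arabidopsis_scale_coverage(self):
        # 22.9 Gb of reads over a 119.7 Mb genome is ~191.3x coverage
        assert estimate_nuclear_depth(119.7e6, 22.9e9) == pytest.approx(191.31, abs=0.02)

    def test_zero_genomesize_is_an_error(self):
        with pytest.raises(MitographError):
            estimate_nuclear_depth(0, 1e9)


def chain_graph():
    return make_graph(
        [("A", 10, 20.0), ("B", 10, 20.0), ("C", 10, 20.0), ("D", 10, 20.0), ("E", 10, 20.0)],
        [("A", TAIL, "B", HEAD, 5), ("B", TAIL, "C", HEAD, 5), ("D", TAIL, "E", HEAD, 5)],
    )


class TestBfs:
    def test_reachability_from_one_seed(self):
        g = chain_graph()
        sub = extend_seeds_bfs(g, {"A"})
        assert set(sub.contigs) == {"A", "B", "C"}
        assert sub.n_links == 2

    def test_two_seeds_cover_both_components(self):
        assert set(extend_seeds_bfs(chain_graph(), {"A", "D"}).contigs) == set("ABCDE")

    def test_unknown_seed_error_names_the_seed(self):
        with pytest.raises(GraphError, match="zz"):
            extend_seeds_bfs(chain_graph(), {"zz"})

    def test_matches_transitive_closure_oracle_on_random_graphs(self):
        rng = random.Random(100)
        for _ in range(100):
            g = random_assembly_graph(rng, max_contigs=20, with_seq=False)
            ids = sorted(g.contigs)
            seeds = set(rng.sample(ids, rng.randint(1, min(3, len(ids)))))
            got = set(extend_seeds_bfs(g, seeds).contigs)
            # oracle: boolean adjacency-matrix closure
            idx = {cid: i for i, cid in enumerate(ids)}
            n = len(ids)
            adj = np.eye(n, dtype=bool)
            for l in g.links:
                adj[idx[l.a], idx[l.b]] = adj[idx[l.b], idx[l.a]] = True
            reach = adj.copy()
            for _ in range(n):
                reach = reach @ adj | reach
            want = {
                ids[j]
                for s in seeds
                for j in range(n)
                if reach[idx[s], j]
            }
            assert got == want


class TestDepthGates:
    def test_nuclear_gate_arithmetic(self):
        g = make_graph([("a", 10, 8.0), ("b", 10, 15.0), ("c", 10, 300.0)])
        dm = DepthModel(nuclear_depth=10.0, mito_median=100.0)
        out = remove_nuclear_like(g, dm)
        assert set(out.contigs) == {"c"}

    def test_seed_contigs_survive_the_gate(self):
        g = make_graph([("s", 10, 12.0), ("x", 10, 12.0)])
        dm = DepthModel(10.0, 100.0)
        out = remove_nuclear_like(g, dm, protected={"s"})
        assert set(out.contigs) == {"s"}

    def test_no_contig_below_gate_leaves_graph_unchanged(self):
        g = make_graph([("a", 10, 50.0), ("b", 10, 60.0)])
        out = remove_nuclear_like(g, DepthModel(10.0, 50.0))
        assert out == g

    def test_plastid_full_path_removed_bridge_reserved(self):
        # p1 (pure plastid) sits between two plastid-class contigs; m (MTPT-like)
        # touches a mito-class contig and must be reserved
        g = make_graph(
            [("p1", 10, 100.0), ("m", 10, 120.0), ("a", 10, 20.0)],
            [("p1", TAIL, "m", HEAD, 50), ("m", TAIL, "a", HEAD, 20),
             ("p1", HEAD, "m", TAIL, 50)],
        )
        dm = DepthModel(1.0, 20.0)  # plastid gate = 60
        out = resolve_plastid_contigs(g, dm)
        assert set(out.contigs) == {"m", "a"}
        assert reserved_mtpt_contigs(g, dm) == {"m"}

    def test_no_plastid_class_leaves_graph_unchanged(self):
        g = make_graph([("a", 10, 20.0), ("b", 10, 30.0)])
        assert resolve_plastid_contigs(g, DepthModel(1.0, 20.0)) == g


class TestWeakLinks:
    def test_one_fifth_rule(self):
        g = make_graph(
            [("a", 10, 20.0), ("b", 10, 25.0)],
            [("a", TAIL, "b", HEAD, 3)],
        )
        assert prune_weak_links(g, PruneParams()).n_links == 0  # 3 < 20/5

    def test_sufficient_support_kept(self):
        g = make_graph(
            [("a", 10, 20.0), ("b", 10, 25.0)],
            [("a", TAIL, "b", HEAD, 5)],
        )
        assert prune_weak_links(g, PruneParams()).n_links == 1  # 5 >= 20/5

    def test_absolute_min_link_floor(self):
        g = make_graph(
            [("a", 10, 10.0), ("b", 10, 10.0)],
            [("a", TAIL, "b", HEAD, 5)],
        )
        assert prune_weak_links(g, PruneParams(min_link=6)).n_links == 0
        assert prune_weak_links(g, PruneParams(min_link=5)).n_links == 1


class TestTips:
    def test_isolated_linear_contig_removed(self):
        g = make_graph([("a", 10, 20.0)])
        assert remove_tips(g).n_contigs == 0

    def test_isolated_self_circular_contig_kept(self):
        g = make_graph([("a", 10, 20.0)], [("a", HEAD, "a", TAIL, 5)])
        assert remove_tips(g).n_contigs == 1

    def test_one_end_attached_contig_kept_by_literal_definition(self):
        g = make_graph(
            [("a", 10, 20.0), ("b", 10, 20.0)],
            [("a", TAIL, "b", HEAD, 5)],
        )
        assert remove_tips(g).n_contigs == 2

    def test_optional_dead_end_trimming(self):
        g = make_graph(
            [("a", 10, 20.0), ("b", 10, 20.0), ("c", 10, 20.0)],
            [("a", TAIL, "b", HEAD, 5), ("b", TAIL, "c", HEAD, 5),
             ("c", TAIL, "b", HEAD, 5)],  # b-c in a loop, a dangles
        )
        assert remove_tips(g).n_contigs == 3
        trimmed = remove_tips(g, trim_dead_ends=True)
        assert "a" not in trimmed.contigs


class TestClassification:
    def test_planted_depth_mixture_recovered(self):
        g = make_graph([("n", 10, 1.0), ("m", 10, 20.0), ("p", 10, 100.0)])
        dm = DepthModel(nuclear_depth=1.0, mito_median=20.0)
        assert classify_by_depth(g, dm) == {"n": "nuclear", "m": "mito", "p": "plastid"}

    def test_boundary_exactly_at_nuclear_gate_is_nuclear(self):
        g = make_graph([("x", 10, 2.0)])
        assert classify_by_depth(g, DepthModel(1.0, 20.0))["x"] == "nuclear"

    def test_single_contig_graph(self):
        g = make_graph([("x", 10, 30.0)])
        assert classify_by_depth(g, DepthModel(1.0, 20.0))["x"] == "mito"


class TestPipelineProperties:
    def test_every_op_is_monotone_on_contigs_and_links(self):
        rng = random.Random(200)
        dm = DepthModel(5.0, 40.0)
        for _ in range(30):
            g = random_assembly_graph(rng, max_contigs=10, with_seq=False)
            for op in (
                lambda x: remove_nuclear_like(x, dm),
                lambda x: resolve_plastid_contigs(x, dm),
                lambda x: prune_weak_links(x, PruneParams()),
                remove_tips,
            ):
                out = op(g)
                assert set(out.contigs) <= set(g.contigs)
                assert out.links <= g.links
                out.validate()

    def test_full_simplification_pass_is_idempotent(self):
        rng = random.Random(300)
        dm = DepthModel(5.0, 40.0)
        for _ in range(20):
            g = random_assembly_graph(rng, max_contigs=12, with_seq=False)
            once, _, _ = simplify_graph(g, dm)
            twice, _, _ = simplify_graph(once, dm)
            assert twice == once
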