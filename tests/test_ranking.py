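"""Ranking engine: fixed points, seeds, spam mass, and the orchestrator.

The independent oracle for both propagation runs is the direct dense
linear solve of (I - d·Prᵀ)x = (1 - d)·v followed by normalization, which
characterizes the unique stationary vector for 0 <= d < 1.
"""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from targo.network import assemble_network, build_transition_operator
from targo.ranking import (NoGoodSeedsError, RankingConfig, SeedVector,
                           compute_spammass, rank_term, run_trustrank,
                           run_tspr, select_good_seeds)
from targo.signatures import SignatureSet, build_weight_vector
from tests.conftest import random_directed_network


def linear_solve_oracle(op, teleport, d):
    """Stationary vector by dense linear algebra (independent of iteration)."""
    pr = op.dense()
    x = np.linalg.solve(np.eye(op.n) - d * pr.T, (1 - d) * teleport)
    return x / x.sum()


def make_seed(net, genes):
    gd = np.zeros(net.n)
    idx = [net.node_index[g] for g in genes]
    gd[idx] = 1.0 / len(idx)
    return SeedVector(term_id="T", good_seeds=frozenset(genes), gd=gd)


class TestPowerIteration:
    def test_zero_damping_returns_teleport(self, star_with_dangling):
        net, op = star_with_dangling
        pa = build_weight_vector(SignatureSet("T", "", frozenset("AX")), net)
        scores, _, converged = run_tspr(op, pa, RankingConfig(d=0.0))
        assert converged
        np.testing.assert_allclose(scores, pa.pa, atol=1e-15)

    def test_symmetric_cycle_uniform_fixed_point(self, cycle3):
        net, op = cycle3
        pa = build_weight_vector(SignatureSet("T", "", frozenset("ABC")), net)
        scores, _, _ = run_tspr(op, pa, RankingConfig())
        np.testing.assert_allclose(scores, 1 / 3, atol=1e-9)

    def test_unnormalized_teleport_rejected(self, cycle3):
        net, op = cycle3
        pa = build_weight_vector(SignatureSet("T", "", frozenset("AB")), net)
        bad = type(pa)(term_id="T", pa=pa.pa * 2, support_size=2)
        with pytest.raises(ValueError, match="sum to 1"):
            run_tspr(op, bad, RankingConfig())

    def test_matches_linear_solve_on_random_graph(self):
        rng = np.random.default_rng(42)
        net = random_directed_network(rng, 12)
        op = build_transition_operator(net)
        genes = frozenset(rng.choice(net.nodes, size=4, replace=False))
        pa = build_weight_vector(SignatureSet("T", "", genes), net)
        cfg = RankingConfig()
        scores, _, converged = run_tspr(op, pa, cfg)
        assert converged
        expected = linear_solve_oracle(op, pa.pa, cfg.d)
        assert np.max(np.abs(scores - expected)) < 1e-8

    def test_matches_networkx_personalized_pagerank(self):
        """Independent cross-check against networkx's PageRank solver."""
        rng = np.random.default_rng(7)
        net = random_directed_network(rng, 15)
        op = build_transition_operator(net)
        genes = frozenset(rng.choice(net.nodes, size=5, replace=False))
        pa = build_weight_vector(SignatureSet("T", "", genes), net)
        scores, _, _ = run_tspr(op, pa, RankingConfig())
        G = nx.DiGraph()
        G.add_nodes_from(net.nodes)
        G.add_edges_from(net.directed_edges)
        pers = {g: pa.pa[net.node_index[g]] for g in net.nodes}
        uniform = {g: 1.0 / net.n for g in net.nodes}
        ref = nx.pagerank(G, alpha=0.85, personalization=pers,
                          dangling=uniform, tol=1e-12, max_iter=500)
        np.testing.assert_allclose(
            scores, [ref[g] for g in net.nodes], atol=1e-8)

    def test_teleport_term_shrinks_as_damping_grows(self, cycle3):
        net, op = cycle3
        pa = build_weight_vector(SignatureSet("T", "", frozenset("A")), net)
        steps = {}
        for d in (0.2, 0.5, 0.8):
            steps[d] = d * op.propagate(pa.pa) + (1 - d) * pa.pa
        # teleport contribution (1-d)*pa strictly decreases with d
        a = net.node_index["A"]
        assert (1 - 0.2) * pa.pa[a] > (1 - 0.5) * pa.pa[a] > (1 - 0.8) * pa.pa[a]
        for d, step in steps.items():
            assert step.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_convergence_flagged_not_raised(self, cycle3, caplog):
        net, op = cycle3
        pa = build_weight_vector(SignatureSet("T", "", frozenset("A")), net)
        scores, iters, converged = run_tspr(
            op, pa, RankingConfig(max_iter=2, tol=1e-16))
        assert not converged and iters == 2
        assert scores.sum() == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 20), st.integers(0, 2**31 - 1))
    def test_stationary_vector_is_distribution(self, n, seed):
        rng = np.random.default_rng(seed)
        net = random_directed_network(rng, n)
        op = build_transition_operator(net)
        k = int(rng.integers(1, n + 1))
        genes = frozenset(rng.choice(net.nodes, size=k, replace=False))
        pa = build_weight_vector(SignatureSet("T", "", genes), net)
        scores, _, _ = run_tspr(op, pa, RankingConfig())
        assert np.all(scores >= 0)
        assert scores.sum() == pytest.approx(1.0, abs=1e-8)


class TestGoodSeeds:
    def test_worked_toy_example_two_seeds_get_half(self, edge_writer):
        # A and D are signature genes ranked in the top 3 TSPR scores
        pairs = [("B", "A"), ("C", "A"), ("E", "D"), ("F", "D"), ("A", "D"),
                 ("D", "A"), ("B", "C"), ("E", "F")]
        net = assemble_network([(edge_writer("toy.tsv", pairs), "pathway")])
        op = build_transition_operator(net)
        sig = SignatureSet("MP:toy", "", frozenset("AD"))
        cfg = RankingConfig(seed_k=3)
        tspr, _, _ = run_tspr(op, build_weight_vector(sig, net), cfg)
        top3 = set(np.argsort(-tspr)[:3])
        assert {net.node_index["A"], net.node_index["D"]} <= top3
        seeds = select_good_seeds(tspr, sig, net, cfg)
        assert seeds.good_seeds == {"A", "D"}
        assert seeds.gd[net.node_index["A"]] == 0.5
        assert seeds.gd[net.node_index["D"]] == 0.5

    def test_all_top_genes_signature_gives_uniform_pool(self, cycle3):
        net, op = cycle3
        sig = SignatureSet("T", "", frozenset("ABC"))
        cfg = RankingConfig(seed_k=3)
        tspr, _, _ = run_tspr(op, build_weight_vector(sig, net), cfg)
        seeds = select_good_seeds(tspr, sig, net, cfg)
        assert seeds.good_seeds == {"A", "B", "C"}
        np.testing.assert_allclose(seeds.gd, 1 / 3)

    def test_no_signature_gene_in_pool_raises(self, edge_writer):
        # hub genes dominate the top-1 pool; signature gene Z ranks below
        pairs = [("A", "B"), ("B", "A"), ("A", "Z")]
        net = assemble_network([(edge_writer("p.tsv", pairs), "pathway")])
        op = build_transition_operator(net)
        sig = SignatureSet("T", "", frozenset("Z"))
        tspr, _, _ = run_tspr(op, build_weight_vector(
            SignatureSet("T", "", frozenset("AB")), net), RankingConfig())
        with pytest.raises(NoGoodSeedsError):
            select_good_seeds(tspr, sig, net, RankingConfig(seed_k=1))

    def test_boundary_tie_broken_by_gene_id(self, cycle3):
        net, op = cycle3
        tspr = np.array([0.4, 0.3, 0.3])  # B and C tie at the k=2 boundary
        sig = SignatureSet("T", "", frozenset("BC"))
        seeds = select_good_seeds(tspr, sig, net, RankingConfig(seed_k=2))
        assert seeds.good_seeds == {"B"}


class TestTrustRank:
    def test_zero_damping_returns_seed_vector(self, star_with_dangling):
        net, op = star_with_dangling
        gd = make_seed(net, ["A", "X"])
        scores, _, _ = run_trustrank(op, gd, RankingConfig(d=0.0))
        np.testing.assert_allclose(scores, gd.gd, atol=1e-15)

    def test_equal_teleports_give_equal_fixed_points(self):
        rng = np.random.default_rng(3)
        net = random_directed_network(rng, 10)
        op = build_transition_operator(net)
        genes = frozenset(rng.choice(net.nodes, size=3, replace=False))
        pa = build_weight_vector(SignatureSet("T", "", genes), net)
        tspr, _, _ = run_tspr(op, pa, RankingConfig())
        trust, _, _ = run_trustrank(op, make_seed(net, sorted(genes)),
                                    RankingConfig())
        np.testing.assert_allclose(trust, tspr, atol=1e-10)

    def test_matches_linear_solve(self):
        rng = np.random.default_rng(11)
        net = random_directed_network(rng, 12)
        op = build_transition_operator(net)
        gd = make_seed(net, sorted(rng.choice(net.nodes, 2, replace=False)))
        cfg = RankingConfig()
        trust, _, _ = run_trustrank(op, gd, cfg)
        expected = linear_solve_oracle(op, gd.gd, cfg.d)
        assert np.max(np.abs(trust - expected)) < 1e-8

    def test_empty_seed_rejected(self, cycle3):
        net, op = cycle3
        empty = SeedVector("T", frozenset(), np.zeros(net.n))
        with pytest.raises(NoGoodSeedsError):
            run_trustrank(op, empty, RankingConfig())


class TestSpammass:
    def test_identical_vectors_give_zero(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(compute_spammass(v, v), 0.0)

    def test_sign_tracks_trust_vs_tspr(self):
        tspr = np.array([0.5, 0.5])
        trust = np.array([0.7, 0.3])
        sm = compute_spammass(tspr, trust)
        assert sm[0] < 0          # elevated by good seeds
        assert sm[1] > 0          # elevated by unrelated genes

    def test_zero_tspr_flagged_undefined(self):
        sm = compute_spammass(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        assert np.isnan(sm[0]) and sm[1] == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_spammass(np.ones(3) / 3, np.ones(2) / 2)


class TestRankTerm:
    @pytest.fixture
    def module_net(self, edge_writer):
        """Signature genes m1..m4 form a dense module; others a sparse chain."""
        module = ["m1", "m2", "m3", "m4"]
        pairs = [(a, b) for i, a in enumerate(module) for b in module[i + 1:]]
        chain = [("u1", "u2"), ("u2", "u3"), ("u3", "u4"), ("u4", "u5"),
                 ("u5", "m1")]
        net = assemble_network(
            [(edge_writer("m.tsv", pairs + chain), "ppi")])
        return net, build_transition_operator(net)

    def test_signature_module_tops_the_ranking(self, module_net):
        net, op = module_net
        sig = SignatureSet("T", "", frozenset(["m1", "m2", "m3", "m4"]))
        res = rank_term(net, op, sig, RankingConfig(seed_k=5))
        top4 = list(res.table.index[:4])
        assert set(top4) == set(sig.genes)
        assert res.table["is_signature"].iloc[:4].all()

    def test_ranks_are_permutations(self, module_net):
        net, op = module_net
        sig = SignatureSet("T", "", frozenset(["m1", "m2"]))
        res = rank_term(net, op, sig, RankingConfig(seed_k=5))
        for col in ("tspr_rank", "trust_rank"):
            assert sorted(res.table[col]) == list(range(1, net.n + 1))

    def test_filter_noop_when_no_positive_spammass(self, module_net):
        net, op = module_net
        sig = SignatureSet("T", "", frozenset(["m1", "m2", "m3", "m4"]))
        cfg = RankingConfig(seed_k=net.n)     # gd == pa -> spammass == 0
        off = rank_term(net, op, sig, cfg, filter_spammass=False)
        on = rank_term(net, op, sig, cfg, filter_spammass=True)
        assert (off.table["spammass"] <= 0).all()
        assert list(off.table.index) == list(on.table.index)

    def test_positive_spammass_demoted_below_retained(self, module_net):
        net, op = module_net
        sig = SignatureSet("T", "", frozenset(["m1", "m2", "m3", "m4"]))
        cfg = RankingConfig(seed_k=2)         # seeds a strict signature subset
        res = rank_term(net, op, sig, cfg, filter_spammass=True)
        sm = res.table["spammass"].to_numpy()
        demoted = sm > cfg.spammass_cutoff
        assert demoted.any()
        # all demoted genes sit after every retained gene
        assert demoted[np.flatnonzero(demoted)[0]:].all()

    def test_bitwise_deterministic_across_runs(self, module_net):
        net, op = module_net
        sig = SignatureSet("T", "", frozenset(["m1", "m3"]))
        r1 = rank_term(net, op, sig, RankingConfig(seed_k=4))
        r2 = rank_term(net, op, sig, RankingConfig(seed_k=4))
        assert list(r1.table.index) == list(r2.table.index)
        assert (r1.table["trust_score"].to_numpy()
                == r2.table["trust_score"].to_numpy()).all()

    def test_equal_trust_scores_tie_break_lexicographic(self, cycle3):
        net, op = cycle3
        sig = SignatureSet("T", "", frozenset("ABC"))
        res = rank_term(net, op, sig, RankingConfig(seed_k=3))
        # perfect symmetry: all scores equal, order must be A, B, C
        assert list(res.table.index) == ["A", "B", "C"]
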