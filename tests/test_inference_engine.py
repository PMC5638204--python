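import itertools
import time

import networkx as nx
import numpy as np
import pytest

from conflux.inference_engine import (BeliefPropagation, InferenceConfig,
                                      counting_factor_messages,
                                      counting_factor_messages_naive,
                                      damped_update, exact_marginals_bruteforce,
                                      exponential_count_messages,
                                      rank_patient_aberrations, run_inference)
from conflux.model_core import ModelConfig
from conflux.network_prior import PriorConfig
from tests.conftest import make_graph

TIGHT = InferenceConfig(convergence_tol=1e-10, outer_max_iterations=3000)

# forest-structured fixtures: BP must agree with enumeration to numerical precision
TREE_FIXTURES = [
    # (counts, variant genes, phenotypes)
    ([[1, 0], [0, 2]], ["A", "B"], [1, 0]),
    ([[1, 0], [1, 0], [0, 1]], ["A", "B", "A"], [1, 1]),
    ([[1, 0], [2, 0], [0, 1], [1, 0]], ["A", "A", "A", "B"], [1, 0]),
    ([[2]], ["A"], [1]),
    ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], ["A", "B", "C"], [1, 1, 0]),
]

# loopy but weakly coupled, as in rare-variant cohorts (low carrier overlap)
LOOPY_FIXTURES = [
    ([[1, 0, 0, 1, 0], [0, 1, 0, 0, 0], [0, 1, 0, 0, 0],
      [0, 0, 1, 0, 0], [0, 0, 0, 0, 1]],
     ["A", "A", "B", "C", "C"], [1, 1, 1, 0, 0]),
    ([[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1]],
     ["A", "B", "C", "B", "C"], [1, 1, 0]),
    ([[1, 1], [1, 0], [0, 1]], ["A", "A", "B"], [1, 0]),
]


def marginal_diffs(table_a, table_b):
    return {
        "h": float(np.abs(table_a.gene_posterior - table_b.gene_posterior).max()),
        "g": float(np.abs(table_a.g_posterior[["p0", "p1", "p2"]].values
                          - table_b.g_posterior[["p0", "p1", "p2"]].values).max()),
        "x": float(np.abs(table_a.x_posterior - table_b.x_posterior).max()),
    }


class TestDampedUpdate:
    def test_alpha_zero_returns_new(self):
        old, new = np.array([1.0, 0.0]), np.array([0.3, 0.7])
        assert np.allclose(damped_update(old, new, 0.0), new)

    def test_midpoint(self):
        out = damped_update(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.5)
        assert np.allclose(out, [0.5, 0.5])

    def test_idempotent_at_fixed_point(self):
        m = np.array([0.2, 0.8])
        assert np.allclose(damped_update(m, m, 0.5), m)

    def test_support_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            damped_update(np.array([1.0, 0.0]), np.array([0.3, 0.3, 0.4]), 0.5)


class TestCountingFactorMessages:
    def test_single_child_identity_potential(self):
        out, belief = counting_factor_messages([[0.5, 0.5]], [0.25, 0.75])
        assert np.allclose(out, [[0.25, 0.75]])
        assert np.allclose(belief, [0.25, 0.75])

    def test_neutral_potential_uniform(self):
        msgs = [[0.5, 0.5]] * 4
        out, _ = counting_factor_messages(msgs, lambda c: 1.0)
        assert np.allclose(out, 0.5)

    def test_all_off_mass_at_zero(self):
        _, belief = counting_factor_messages_naive([[1, 0], [1, 0]],
                                                   lambda c: 1.0)
        assert np.allclose(belief, [1, 0, 0])

    def test_all_on_mass_at_n(self):
        _, belief = counting_factor_messages_naive([[0, 1], [0, 1]],
                                                   lambda c: 1.0)
        assert np.allclose(belief, [0, 0, 1])

    def test_naive_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        n = 5
        m1 = rng.random(n)
        msgs = np.stack([1 - m1, m1], axis=1)
        f = rng.random(n + 1) + 0.01
        expected = np.zeros((n, 2))
        for cfg in itertools.product([0, 1], repeat=n):
            w = np.prod([msgs[i, cfg[i]] for i in range(n)]) * f[sum(cfg)]
            for i in range(n):
                expected[i, cfg[i]] += w / msgs[i, cfg[i]]
        expected /= expected.sum(axis=1, keepdims=True)
        out, _ = counting_factor_messages_naive(msgs, f)
        assert np.allclose(out, expected, atol=1e-12)

    def test_tree_matches_naive_over_100_seeded_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            m1 = rng.random(n)
            msgs = np.stack([1 - m1, m1], axis=1)
            f = rng.random(n + 1) + 1e-3
            tree_out, tree_belief = counting_factor_messages(msgs, f)
            naive_out, naive_belief = counting_factor_messages_naive(msgs, f)
            assert np.abs(tree_out - naive_out).max() < 1e-9
            assert np.abs(tree_belief - naive_belief).max() < 1e-9

    def test_naive_refuses_large_n(self):
        with pytest.raises(ValueError, match="refused"):
            counting_factor_messages_naive([[0.5, 0.5]] * 21, lambda c: 1.0)

    def test_closed_form_matches_naive_for_model_potentials(self):
        rng = np.random.default_rng(7)
        n = 12
        m1 = rng.random(n)
        msgs = np.stack([1 - m1, m1], axis=1)
        # noisy-OR case side: f(c) = 1 - 0.99 * 0.3**c
        f = [1 - 0.99 * 0.3 ** c for c in range(n + 1)]
        closed = exponential_count_messages(msgs, 1.0, -0.99, 0.3)
        naive, _ = counting_factor_messages_naive(msgs, f)
        assert np.abs(closed - naive).max() < 1e-12
        # geometric sparsity: f(c) = 0.9**c
        closed = exponential_count_messages(msgs, 0.0, 1.0, 0.9)
        naive, _ = counting_factor_messages_naive(msgs, [0.9 ** c
                                                         for c in range(n + 1)])
        assert np.abs(closed - naive).max() < 1e-12

    def test_subquadratic_scaling(self):
        # time ratio between n=4096 and n=64 must be far below the
        # quadratic ratio (4096/64)**2 = 4096
        rng = np.random.default_rng(0)

        def run_at(n):
            m1 = rng.random(n)
            msgs = np.stack([1 - m1, m1], axis=1)
            f = np.exp(-np.arange(n + 1) * 0.01)
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                counting_factor_messages(msgs, f)
                best = min(best, time.perf_counter() - t0)
            return best

        small, large = run_at(64), run_at(4096)
        assert large / small < 1000


class TestRunInference:
    def test_prior_only_gene_marginal_is_tau(self):
        # a gene present only through a network prior on an empty cohort,
        # with its sole neighbour clamped OFF, keeps exactly its prior odds
        pc = PriorConfig(neighbourhood_order=1)
        g = make_graph([[1]], ["A"], [1], network=nx.Graph([("A", "Z")]),
                       model_config=ModelConfig(gamma=1.0), prior_config=pc)
        table = run_inference(g, TIGHT, clamp_h={"A": 0})
        assert table.gene_posterior["Z"] == pytest.approx(pc.tau, abs=1e-9)

    @pytest.mark.parametrize("counts,genes,phen", TREE_FIXTURES)
    def test_exact_on_trees(self, counts, genes, phen):
        g = make_graph(counts, genes, phen)
        diffs = marginal_diffs(run_inference(g, TIGHT),
                               exact_marginals_bruteforce(g))
        assert max(diffs.values()) < 1e-6

    @pytest.mark.parametrize("counts,genes,phen", LOOPY_FIXTURES)
    def test_gene_marginals_close_on_weak_loops(self, counts, genes, phen):
        g = make_graph(counts, genes, phen)
        diffs = marginal_diffs(run_inference(g, TIGHT),
                               exact_marginals_bruteforce(g))
        # gene-level marginals (the output contract) stay within 0.02;
        # variant-level marginals in shared-carrier loops drift further
        # (documented limitation) but must stay bounded
        assert diffs["h"] < 0.02
        assert diffs["x"] < 0.1
        assert diffs["g"] < 0.2

    def test_network_alone_cannot_exceed_ceiling(self):
        # every neighbour clamped active, focal gene has no variants
        pc = PriorConfig(neighbourhood_order=1)
        net = nx.star_graph(4)  # focal 0, neighbours 1..4
        net = nx.relabel_nodes(net, {k: f"N{k}" for k in net.nodes})
        g = make_graph([[1]], ["N1"], [1], network=net,
                       model_config=ModelConfig(gamma=1.0), prior_config=pc)
        table = run_inference(g, TIGHT,
                              clamp_h={f"N{k}": 1 for k in range(1, 5)})
        assert table.gene_posterior["N0"] <= pc.ceiling + 1e-9

    def test_determinism_bit_identical(self):
        counts, genes, phen = LOOPY_FIXTURES[0]
        net = nx.Graph([("A", "B"), ("B", "C")])
        g1 = make_graph(counts, genes, phen, network=net)
        g2 = make_graph(counts, genes, phen, network=net)
        t1, t2 = run_inference(g1), run_inference(g2)
        assert (t1.gene_posterior.values == t2.gene_posterior.values).all()
        assert (t1.x_posterior.values == t2.x_posterior.values).all()
        assert t1.n_iterations == t2.n_iterations

    def test_emitted_distributions_normalized(self):
        counts, genes, phen = LOOPY_FIXTURES[0]
        g = make_graph(counts, genes, phen)
        bp = BeliefPropagation(g, InferenceConfig())
        bp.run()
        for msg in (bp.msg_phi2_to_q, bp.msg_phi3_to_q, bp.msg_phi3_to_g,
                    bp.msg_phi2_to_y, bp.msg_phi4_to_g):
            assert np.abs(msg.sum(axis=1) - 1.0).max() < 1e-12
        table = bp.marginals()
        assert np.abs(table.g_posterior[["p0", "p1", "p2"]].sum(axis=1)
                      - 1.0).max() < 1e-12


class TestTwoTierSchedule:
    def test_inner_loop_stops_early_when_converged(self):
        g = make_graph([[1, 0]], ["A"], [1, 0])
        bp = BeliefPropagation(g, InferenceConfig())
        bp.run()
        bp.two_tier_sweep()  # at the fixed point
        assert bp.last_inner_sweeps == 1

    def test_inner_loop_capped(self):
        counts, genes, phen = LOOPY_FIXTURES[0]
        g = make_graph(counts, genes, phen)
        cfg = InferenceConfig(inner_loop_max=10, inner_tol=1e-300)
        bp = BeliefPropagation(g, cfg)
        bp.two_tier_sweep()
        assert bp.last_inner_sweeps == 10

    def test_convergence_flag_and_iterations_reported(self):
        g = make_graph([[1, 0]], ["A"], [1, 0])
        table = run_inference(g, InferenceConfig())
        assert table.converged
        assert table.n_iterations >= 1


class TestBruteForce:
    def test_refuses_large_state_space(self):
        counts = np.ones((25, 2), dtype=int)
        g = make_graph(counts, [f"g{k}" for k in range(25)], [1, 0])
        with pytest.raises(ValueError, match="state space"):
            exact_marginals_bruteforce(g)

    def test_single_gene_single_case_hand_enumeration(self):
        # 1 gene, 1 het variant, 1 case: enumerate X in {0,1}, H in {0,1},
        # Q in {0,1,2} by hand
        mc, pc = ModelConfig(), PriorConfig()
        g = make_graph([[1]], ["A"], [1], model_config=mc, prior_config=pc)
        from conflux.model_core import phi2_cpt, phi4_potential
        cpt = phi2_cpt(mc)
        z = 0.0
        h_sum = 0.0
        for x in (0, 1):
            for h in (0, 1):
                for q in (0, 1, 2):
                    w = (0.5 * cpt[x, q]  # S = x * dose(1)
                         * (pc.tau if h else 1 - pc.tau)
                         * mc.gamma ** h
                         * phi4_potential(1, int(h * q >= 1), mc))
                    z += w
                    h_sum += w * h
        expected = h_sum / z
        out = exact_marginals_bruteforce(g)
        assert out.gene_posterior["A"] == pytest.approx(expected, abs=1e-12)

    def test_gamma_one_no_network_genes_factorize(self):
        mc = ModelConfig(gamma=1.0)
        joint = make_graph([[1, 0], [0, 1]], ["A", "B"], [1, 0],
                           model_config=mc)
        single_a = make_graph([[1, 0]], ["A"], [1, 0], model_config=mc)
        bf_joint = exact_marginals_bruteforce(joint)
        bf_a = exact_marginals_bruteforce(single_a)
        assert bf_joint.gene_posterior["A"] == pytest.approx(
            bf_a.gene_posterior["A"], abs=1e-12)


class TestRankPatientAberrations:
    def _table(self):
        g = make_graph([[1, 0], [0, 1], [1, 0]], ["A", "B", "C"], [1, 0])
        return run_inference(g, TIGHT)

    def test_no_carried_variants_unknown(self):
        table = self._table()
        with pytest.raises(KeyError):
            rank_patient_aberrations(table, "i99")

    def test_high_marginal_gene_variant_ranks_first(self):
        # i1 (case) carries v1 in A and v3 in C; A also carried by a second
        # case -> v1 should outrank v3 after inference on a fixture where A
        # accumulates more evidence
        g = make_graph([[1, 0, 1], [0, 1, 0], [1, 0, 0]],
                       ["A", "B", "A"], [1, 0, 1])
        table = run_inference(g, TIGHT)
        bf = exact_marginals_bruteforce(g)
        ranked = rank_patient_aberrations(table, "i1")
        sub = bf.y_posterior[bf.y_posterior["individual"] == "i1"]
        expected = list(sub.sort_values(["p_active", "variant"],
                                        ascending=[False, True])["variant"])
        assert ranked == expected

    def test_tie_broken_lexicographically(self):
        g = make_graph([[1], [1]], ["A", "A"], [1])
        table = run_inference(g, TIGHT)
        assert rank_patient_aberrations(table, "i1") == ["v1", "v2"]
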