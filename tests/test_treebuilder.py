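import numpy as np
import pytest

from grmt import (
    FREE,
    MISSING,
    Attachment,
    BuildParams,
    ErrorModel,
    MutationMatrix,
    MutationTree,
    PosteriorCache,
    attach_cells,
    build_mutation_tree,
    enumerate_candidates,
    score_candidate,
    validate_tree,
)
from grmt.core import genotype_of_node
from grmt.likelihood import cell_loglik
from grmt.metrics import caset_distance, aggregate_linear_chains
from grmt.simulator import SimConfig, simulate
from conftest import make_params


def brute_candidate_score(D, tree, p, c, model, lam):
    """From-scratch recomputation of the expected-flow score, no caching."""
    data = np.where(D.missing_mask, MISSING, D.data)

    def posteriors(tr):
        nodes = [v for v in range(tr.n_nodes) if tr.parent[v] != FREE]
        L = np.array([[cell_loglik(data[i], genotype_of_node(tr, v), model)
                       for v in nodes] for i in range(D.n_cells)])
        W = np.exp(L - np.log(np.exp(L).sum(axis=1))[:, None])
        return dict(zip(nodes, W.T))

    P_t = posteriors(tree)
    t2 = tree.copy()
    t2.parent[c] = p
    P_pc = posteriors(t2)
    pi_bar = P_t[p].sum() - P_pc[p].sum()
    pi_tilde = P_pc[c].sum() - pi_bar
    return pi_bar, pi_tilde, lam * pi_bar + (1 - lam) * pi_tilde


class TestEnumerateCandidates:
    def test_root_only_all_gains(self):
        tree = MutationTree(5, 0)
        assert enumerate_candidates(tree) == [(0, c) for c in range(1, 6)]

    def test_no_free_nodes_empty(self, chain_tree):
        assert enumerate_candidates(chain_tree) == []

    def test_loss_offered_only_where_mutation_present(self):
        tree = MutationTree(2, 1)
        tree.parent[1] = 0  # gain of mutation 0 under root
        cands = enumerate_candidates(tree)
        loss0 = tree.loss_node(0, 0)
        assert (1, loss0) in cands          # below its own gain
        assert (0, loss0) not in cands      # not under the root
        # mutation 1 not gained -> its loss never offered
        assert all(c != tree.loss_node(1, 0) for _, c in cands)

    def test_loss_copies_deduplicated(self):
        tree = MutationTree(1, 3)
        tree.parent[1] = 0
        cands = [c for _, c in enumerate_candidates(tree)]
        assert cands.count(tree.loss_node(0, 0)) == 1
        assert tree.loss_node(0, 1) not in cands

    def test_count_bounded_by_neighborhood_formula(self):
        # bound: t * (M*k + M + 1 - t) at tree size t
        out = simulate(SimConfig(N=30, M=6, k=1, loss_prob=0.8, seed=5))
        params = make_params(alpha=0.01, beta=0.1, k=1, kappa=0.0)
        res = build_mutation_tree(out.D, params)
        tree = MutationTree(6, 1)
        for rec in res.trace:
            t = len([v for v in tree.parent if v != FREE])
            M, k = tree.M, tree.k
            assert len(enumerate_candidates(tree)) <= t * (M * k + M + 1 - t)
            tree.parent[rec.c] = rec.p


class TestScoreCandidate:
    def test_matches_bruteforce_equations(self, small_matrix, error_model):
        tree = MutationTree(small_matrix.n_mutations, 1)
        tree.parent[1] = 0
        tree.parent[2] = 1
        cache = PosteriorCache(small_matrix, tree, error_model)
        for (p, c) in enumerate_candidates(tree):
            sc = score_candidate(cache, p, c, lam=0.7)
            bb, bt, bs = brute_candidate_score(small_matrix, tree, p, c,
                                               error_model, 0.7)
            assert sc.pi_bar == pytest.approx(bb, abs=1e-9)
            assert sc.pi_tilde == pytest.approx(bt, abs=1e-9)
            assert sc.s == pytest.approx(bs, abs=1e-9)

    def test_flow_conservation_and_nonnegativity(self, small_matrix, error_model):
        tree = MutationTree(small_matrix.n_mutations, 0)
        tree.parent[2] = 0
        cache = PosteriorCache(small_matrix, tree, error_model)
        for (p, c) in enumerate_candidates(tree):
            sc = score_candidate(cache, p, c, lam=0.3)
            assert sc.pi_bar >= 0 and sc.pi_tilde >= 0
            # pi_bar + pi_tilde equals the expected occupancy of c after the move
            bb, bt, _ = brute_candidate_score(small_matrix, tree, p, c,
                                              error_model, 0.3)
            assert sc.pi_bar + sc.pi_tilde == pytest.approx(bb + bt, abs=1e-9)

    def test_lam_one_reduces_to_direct_flow(self, small_matrix, error_model):
        tree = MutationTree(small_matrix.n_mutations, 0)
        tree.parent[1] = 0
        cache = PosteriorCache(small_matrix, tree, error_model)
        sc = score_candidate(cache, 0, 2, lam=1.0 - 1e-12)
        assert sc.s == pytest.approx(sc.pi_bar, rel=1e-9)

    def test_illegal_candidate_rejected(self, small_matrix, error_model):
        tree = MutationTree(small_matrix.n_mutations, 1)
        tree.parent[1] = 0
        cache = PosteriorCache(small_matrix, tree, error_model)
        with pytest.raises(ValueError):
            score_candidate(cache, 0, tree.loss_node(0, 0), lam=0.7)  # 0 not at root
        with pytest.raises(ValueError):
            score_candidate(cache, 2, 3, lam=0.7)  # split point not attached


def all_trees(M):
    """Every valid k=0 tree over M mutations (all subsets, all parents)."""
    from itertools import combinations, product
    for r in range(M + 1):
        for sub in combinations(range(1, M + 1), r):
            for parents in product(*[list(sub) + [0] for _ in sub]):
                tree = MutationTree(M, 0)
                for v, p in zip(sub, parents):
                    tree.parent[v] = p
                if not validate_tree(tree):
                    yield tree


class TestBuildMutationTree:
    def test_kappa_above_n_returns_root_only(self, small_matrix):
        params = make_params(kappa=small_matrix.n_cells + 1)
        res = build_mutation_tree(small_matrix, params)
        assert res.stop_reason == "kappa"
        assert np.sum(res.best_tree.parent != FREE) == 1
        root = MutationTree(small_matrix.n_mutations, 0)
        model = ErrorModel(params.alpha, params.beta)
        assert res.best_loglik == pytest.approx(
            attach_cells(small_matrix, root, model).loglik)

    def test_recovers_noiseless_chain(self):
        out = simulate(SimConfig(N=60, M=5, alpha=0.001, beta=0.001, eta=0.0,
                                 rho=0.0, gamma=0.0, seed=2))
        params = make_params(alpha=0.001, beta=0.001)
        res = build_mutation_tree(out.D, params)
        a_pred = aggregate_linear_chains(res.best_tree, res.attachment)
        a_true = aggregate_linear_chains(out.tree,
                                         Attachment(xi=out.attachments, loglik=0.0))
        assert caset_distance(a_pred, a_true) == pytest.approx(0.0, abs=1e-12)

    def test_greedy_bounded_by_exhaustive_optimum(self):
        # M=3: enumerate every valid tree; greedy cannot beat the global best,
        # and matches it on noiseless data
        out = simulate(SimConfig(N=12, M=3, alpha=0.001, beta=0.001, eta=0.0,
                                 rho=0.0, seed=9))
        model = ErrorModel(0.001, 0.001)
        params = make_params(alpha=0.001, beta=0.001, kappa=0.5)
        res = build_mutation_tree(out.D, params)
        best = max(attach_cells(out.D, t, model).loglik for t in all_trees(3))
        assert res.best_loglik <= best + 1e-9
        assert res.best_loglik == pytest.approx(best, abs=1e-6)

    def test_greedy_bounded_by_exhaustive_optimum_noisy(self, rng):
        data = rng.integers(0, 2, (6, 3))
        D = MutationMatrix(data=data, missing_mask=None)
        model = ErrorModel(0.05, 0.2)
        params = make_params(alpha=0.05, beta=0.2, kappa=0.0)
        res = build_mutation_tree(D, params)
        best = max(attach_cells(D, t, model).loglik for t in all_trees(3))
        assert res.best_loglik <= best + 1e-9

    def test_best_loglik_consistent_with_attachment(self, small_matrix):
        params = make_params()
        res = build_mutation_tree(small_matrix, params)
        model = ErrorModel(params.alpha, params.beta)
        assert res.best_loglik == pytest.approx(
            attach_cells(small_matrix, res.best_tree, model).loglik)

    def test_trace_logliks_never_exceed_best(self, small_matrix):
        res = build_mutation_tree(small_matrix, make_params(kappa=0.0))
        assert all(r.loglik <= res.best_loglik + 1e-9 for r in res.trace)

    def test_deterministic(self, small_matrix):
        params = make_params()
        r1 = build_mutation_tree(small_matrix, params)
        r2 = build_mutation_tree(small_matrix, params)
        assert np.array_equal(r1.best_tree.parent, r2.best_tree.parent)
        assert r1.best_loglik == r2.best_loglik
        assert r1.trace == r2.trace

    def test_built_trees_are_valid_fuzz(self):
        for seed in range(6):
            out = simulate(SimConfig(N=25, M=8, k=1, loss_prob=0.5,
                                     alpha=0.02, beta=0.15, eta=0.1,
                                     rho=0.1, seed=seed))
            res = build_mutation_tree(out.D, make_params(alpha=0.02, beta=0.15, k=1))
            assert validate_tree(res.best_tree) == []

    def test_batch_scores_match_percandidate_scorer(self, small_matrix, error_model):
        # replay a build; at each recorded step the chosen edge's score must
        # equal the standalone scorer's value on the same precursor tree
        params = make_params(alpha=error_model.alpha, beta=error_model.beta,
                             kappa=0.0)
        res = build_mutation_tree(small_matrix, params)
        tree = MutationTree(small_matrix.n_mutations, params.k)
        for rec in res.trace:
            cache = PosteriorCache(small_matrix, tree, error_model)
            sc = score_candidate(cache, rec.p, rec.c, params.lam)
            assert sc.s == pytest.approx(rec.score, abs=1e-9)
            # and no legal candidate scores strictly higher
            smax = max(score_candidate(cache, p, c, params.lam).s
                       for p, c in enumerate_candidates(tree))
            assert rec.score == pytest.approx(smax, abs=1e-9)
            tree.parent[rec.c] = rec.p

    def test_dimension_mismatch_rejected(self, small_matrix):
        params = make_params()
        model = ErrorModel(params.alpha, params.beta, mode="ternary")
        with pytest.raises(ValueError):
            build_mutation_tree(small_matrix, params, model)
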