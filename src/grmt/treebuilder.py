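"""Generative construction of the mutation tree.

Starting from the root-only tree, the builder repeatedly attaches the best
free event node: every legal (split point ``p``, free node ``c``) pair is
scored by the expected "cell flow" the new edge would capture,

    s(T_pc) = lam * pi_bar + (1 - lam) * pi_tilde,

where ``pi_bar`` is the expected number of cells moving from ``p`` directly
to ``c`` and ``pi_tilde`` the expected number arriving at ``c`` from other
nodes, both under the posterior attachment distribution with a uniform node
prior.  Growth stops when free nodes run out or the best score drops below
``kappa``; the tree with the highest data log-likelihood seen along the way
is returned.

Scoring one candidate touches only the new node's per-cell likelihood: with
``W[i,p]`` the current posterior and ``R[i] = p(D_i|S_c)/p(D_i|S_p)`` the
single-site likelihood ratio of the new event,

    u = W[i,p] * R[i]
    pi_c   = sum_i u/(1+u)          (expected cells at c after the edge)
    pi_bar = sum_i W[i,p] * u/(1+u) (cells leaving p for c)

which the batch kernel evaluates for all candidates at once.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .core import (
    FREE,
    BuildParams,
    MutationMatrix,
    MutationTree,
    attached_nodes,
    genotype_of_node,
)
from .likelihood import Attachment, ErrorModel, attach_cells, loglik_columns


class CandidateScore(NamedTuple):
    """Score of attaching free node ``c`` under split point ``p``."""

    p: int
    c: int
    pi_bar: float
    pi_tilde: float
    s: float


class TraceRecord(NamedTuple):
    t: int
    p: int
    c: int
    score: float
    loglik: float


@dataclass
class BuildResult:
    """Outcome of a tree-building run: globally best tree and bookkeeping."""

    best_tree: MutationTree
    best_loglik: float
    attachment: Attachment
    trace: list = field(default_factory=list)
    stop_reason: str = "complete"
    params: BuildParams | None = None


class PosteriorCache:
    """Per-cell attachment posteriors of the current tree, ready for scoring.

    Holds, for every attached node, each cell's log-likelihood column and the
    posterior weight ``W``; candidate evaluation derives the tentative new
    node's likelihood from its parent's column via one emission-ratio factor.
    """

    def __init__(self, D: MutationMatrix, tree: MutationTree, model: ErrorModel):
        self.tree = tree
        self.N = D.n_cells
        self.M = D.n_mutations
        l0, l1 = loglik_columns(D, model)
        self.d_gain = l1 - l0                    # log ratio of a gain event
        self.ratio_gain = np.exp(self.d_gain)    # p(D|S with j)/p(D|S without j)
        self.L = np.empty((self.N, tree.n_nodes))
        self.profiles = np.zeros((tree.n_nodes, self.M), dtype=np.int8)
        self.nodes: list[int] = attached_nodes(tree)
        for v in sorted(self.nodes, key=lambda u: _depth(tree, u)):
            if v == 0:
                self.L[:, 0] = l0.sum(axis=1)
                continue
            p = int(tree.parent[v])
            j = tree.node_mutation(v)
            sign = 1.0 if tree.is_gain(v) else -1.0
            self.L[:, v] = self.L[:, p] + sign * self.d_gain[:, j]
            self.profiles[v] = self.profiles[p]
            self.profiles[v, j] = 1 if tree.is_gain(v) else 0
        self.refresh()

    def refresh(self) -> None:
        """Recompute posteriors W and expected node occupancies pi."""
        cols = self.L[:, self.nodes]
        self.logZ = logsumexp(cols, axis=1)
        self.W = np.exp(cols - self.logZ[:, None])
        self.pi = self.W.sum(axis=0)
        self.max_ll = cols.max(axis=1)

    def node_index(self, v: int) -> int:
        return self.nodes.index(v)

    def attach(self, p: int, c: int) -> None:
        """Permanently add edge p→c and refresh the posterior state."""
        tree = self.tree
        j = tree.node_mutation(c)
        sign = 1.0 if tree.is_gain(c) else -1.0
        tree.parent[c] = p
        self.L[:, c] = self.L[:, p] + sign * self.d_gain[:, j]
        self.profiles[c] = self.profiles[p]
        self.profiles[c, j] = 1 if tree.is_gain(c) else 0
        insort(self.nodes, c)
        self.refresh()


def _depth(tree: MutationTree, v: int) -> int:
    d = 0
    while v != 0:
        v = int(tree.parent[v])
        d += 1
    return d


def enumerate_candidates(tree: MutationTree,
                         free_nodes: set[int] | None = None) -> list[tuple[int, int]]:
    """All legal (split point, free node) pairs, lexicographically ordered.

    Gain nodes may attach under any internal node.  A loss node of mutation
    ``a`` may attach only under nodes whose genotype carries ``a``; the ``k``
    interchangeable loss copies of a mutation are deduplicated — only the
    lowest-id free copy is offered.
    """
    nodes = attached_nodes(tree)
    if free_nodes is None:
        free_nodes = {v for v in range(tree.n_nodes) if tree.parent[v] == FREE}
    free_gains = sorted(v for v in free_nodes if tree.is_gain(v))
    # canonical (lowest-id) free loss copy per mutation with an attached gain
    canon: dict[int, int] = {}
    for j in range(tree.M):
        if tree.parent[tree.gain_node(j)] == FREE or tree.k == 0:
            continue
        for q in range(tree.k):
            v = tree.loss_node(j, q)
            if v in free_nodes:
                canon[j] = v
                break
    out: list[tuple[int, int]] = []
    for p in nodes:
        prof = genotype_of_node(tree, p)
        cands = list(free_gains)
        cands.extend(v for j, v in canon.items() if prof[j] == 1)
        out.extend((p, c) for c in sorted(cands))
    return out


def score_candidate(cache: PosteriorCache, p: int, c: int, lam: float) -> CandidateScore:
    """Score one candidate edge from the posterior cache (no tree mutation)."""
    tree = cache.tree
    if tree.parent[p] == FREE or tree.parent[c] != FREE:
        raise ValueError(f"illegal candidate ({p}, {c})")
    j = tree.node_mutation(c)
    if tree.is_loss(c):
        if cache.profiles[p, j] != 1:
            raise ValueError(
                f"loss of mutation {j} cannot attach under node {p}"
            )
        R = 1.0 / cache.ratio_gain[:, j]
    else:
        R = cache.ratio_gain[:, j]
    Wp = cache.W[:, cache.node_index(p)]
    u = Wp * R
    b = u / (1.0 + u)
    pi_c = float(b.sum())
    pi_bar = float((Wp * b).sum())
    pi_tilde = pi_c - pi_bar
    pi_bar = max(pi_bar, 0.0)
    pi_tilde = max(pi_tilde, 0.0)
    s = lam * pi_bar + (1.0 - lam) * pi_tilde
    return CandidateScore(p=p, c=c, pi_bar=pi_bar, pi_tilde=pi_tilde, s=s)


@njit(cache=True)
def _pair_flows(Wt, Rt):  # pragma: no cover - exercised via build_mutation_tree
    """pi_c and pi_bar for every (attached node, candidate event) pair.

    Wt: (t, N) posterior weights, one row per attached node.
    Rt: (f, N) per-cell likelihood ratios, one row per candidate event.
    """
    t, N = Wt.shape
    f = Rt.shape[0]
    pic = np.empty((t, f))
    pbar = np.empty((t, f))
    for p in range(t):
        for a in range(f):
            s1 = 0.0
            s2 = 0.0
            for i in range(N):
                u = Wt[p, i] * Rt[a, i]
                b = u / (1.0 + u)
                s1 += b
                s2 += Wt[p, i] * b
            pic[p, a] = s1
            pbar[p, a] = s2
    return pic, pbar


def build_mutation_tree(D: MutationMatrix, params: BuildParams,
                        model: ErrorModel | None = None) -> BuildResult:
    """Grow the mutation tree greedily and return the globally best one.

    At each step every legal candidate edge is scored; the argmax is taken
    (ties resolved by larger resulting data log-likelihood, then smallest
    (p, c) pair).  If the winning score falls below ``kappa`` the loop stops
    immediately; otherwise the edge is attached and the globally best tree
    is updated whenever the data log-likelihood strictly improves.
    """
    if model is None:
        model = ErrorModel(params.alpha, params.beta)
    if D.mode != model.mode:
        raise ValueError("matrix mode and error-model mode disagree")
    tree = MutationTree(D.n_mutations, params.k)
    cache = PosteriorCache(D, tree, model)
    lam = params.lam
    M, k = tree.M, tree.k

    free_gain_muts = list(range(M))          # mutations whose gain is free
    gain_free = np.ones(M, dtype=bool)
    loss_used = np.zeros(M, dtype=np.int64)  # attached loss copies per mutation

    best_parent = tree.parent.copy()
    best_ll = float(cache.max_ll.sum())
    trace: list[TraceRecord] = []
    stop_reason = "complete"

    for t_iter in range(2, tree.n_nodes + 1):
        nodes = cache.nodes
        t = len(nodes)
        Wt = np.ascontiguousarray(cache.W.T)

        # --- gain candidates: any free gain under any attached node
        fg = len(free_gain_muts)
        if fg:
            Rg = np.ascontiguousarray(cache.ratio_gain[:, free_gain_muts].T)
            pic_g, pbar_g = _pair_flows(Wt, Rg)
            s_g = lam * pbar_g + (1.0 - lam) * (pic_g - pbar_g)
        else:
            s_g = np.empty((t, 0))

        # --- loss candidates: canonical free copy, only where the mutation
        #     is present in the split point's genotype
        if k > 0:
            loss_muts = [int(j) for j in
                         np.flatnonzero(~gain_free & (loss_used < k))]
        else:
            loss_muts = []
        fl = len(loss_muts)
        if fl:
            Rl = np.ascontiguousarray(1.0 / cache.ratio_gain[:, loss_muts].T)
            pic_l, pbar_l = _pair_flows(Wt, Rl)
            s_l = lam * pbar_l + (1.0 - lam) * (pic_l - pbar_l)
            legal = cache.profiles[np.asarray(nodes)][:, loss_muts] == 1
            s_l = np.where(legal, s_l, -np.inf)
        else:
            s_l = np.empty((t, 0))

        smax_g = s_g.max() if s_g.size else -np.inf
        smax_l = s_l.max() if s_l.size else -np.inf
        s_best = max(smax_g, smax_l)
        if not np.isfinite(s_best):
            stop_reason = "no_candidates"
            break

        # tied candidates at the exact maximum, as (p_node, c_node) pairs
        tied: list[tuple[int, int]] = []
        if s_g.size and smax_g == s_best:
            for pi_, ai_ in zip(*np.nonzero(s_g == s_best)):
                tied.append((int(nodes[int(pi_)]), free_gain_muts[int(ai_)] + 1))
        if s_l.size and smax_l == s_best:
            for pi_, ai_ in zip(*np.nonzero(s_l == s_best)):
                j = loss_muts[int(ai_)]
                tied.append((int(nodes[int(pi_)]),
                             tree.loss_node(j, int(loss_used[j]))))
        if len(tied) > 1:
            tied.sort()
            lls = []
            for p, c in tied:
                j = tree.node_mutation(c)
                sign = 1.0 if tree.is_gain(c) else -1.0
                Lc = cache.L[:, p] + sign * cache.d_gain[:, j]
                lls.append(float(np.maximum(cache.max_ll, Lc).sum()))
            p_win, c_win = tied[int(np.argmax(lls))]
        else:
            p_win, c_win = tied[0]

        if s_best < params.kappa:
            stop_reason = "kappa"
            break

        cache.attach(p_win, c_win)
        if tree.is_gain(c_win):
            free_gain_muts.remove(tree.node_mutation(c_win))
            gain_free[tree.node_mutation(c_win)] = False
        else:
            loss_used[tree.node_mutation(c_win)] += 1
        ll_t = float(cache.max_ll.sum())
        trace.append(TraceRecord(t=t_iter, p=p_win, c=c_win,
                                 score=float(s_best), loglik=ll_t))
        if ll_t > best_ll:
            best_ll = ll_t
            best_parent = tree.parent.copy()

    best_tree = MutationTree(M, k, best_parent)
    attachment = attach_cells(D, best_tree, model)
    return BuildResult(best_tree=best_tree, best_loglik=attachment.loglik,
                       trace=trace, attachment=attachment,
                       stop_reason=stop_reason, params=params)
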