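"""Genotype error model and maximum-likelihood cell attachment.

The hidden genotype ``E`` is binary (mutation absent/present).  Observations
are corrupted by a false-positive rate ``alpha`` (absent called present) and
a false-negative rate ``beta`` (present called absent).  In ternary mode the
observation alphabet is {0,1,2} where 2 records a heterozygous mutation
mis-called homozygous through allele dropout; the hidden state stays binary
and the emission table becomes 2×3:

    p(D|E=0) = (1 - alpha - alpha*beta/2,  alpha,    alpha*beta/2)
    p(D|E=1) = (beta/2,                    1 - beta, beta/2)

Missing observations contribute a neutral factor of 1 to every likelihood,
so an all-missing cell is equally compatible with every tree node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import MISSING, MutationMatrix, MutationTree, attached_nodes, genotype_of_node


@dataclass
class ErrorModel:
    alpha: float
    beta: float
    mode: str = "binary"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie strictly in (0,1)")
        if self.mode not in ("binary", "ternary"):
            raise ValueError("mode must be 'binary' or 'ternary'")

    def emission_matrix(self) -> np.ndarray:
        """Rows = hidden state (0,1); columns = observed value."""
        a, b = self.alpha, self.beta
        if self.mode == "binary":
            return np.array([[1.0 - a, a], [b, 1.0 - b]])
        return np.array(
            [[1.0 - a - a * b / 2.0, a, a * b / 2.0], [b / 2.0, 1.0 - b, b / 2.0]]
        )


def emission_prob(observed: int, true_state: int, model: ErrorModel) -> float:
    """p(observed | true_state); a MISSING observation returns 1."""
    if observed == MISSING:
        return 1.0
    if true_state not in (0, 1):
        raise ValueError("true_state must be 0 or 1")
    em = model.emission_matrix()
    if not 0 <= observed < em.shape[1]:
        raise ValueError(f"observed value {observed} illegal for {model.mode} mode")
    return float(em[true_state, observed])


def loglik_columns(D: MutationMatrix, model: ErrorModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry log emission probabilities under each hidden state.

    Returns ``(l0, l1)``, both N×M: ``l0[i,j] = log p(D_ij | E_ij = 0)`` and
    likewise for state 1, with missing entries set to 0 (a factor of 1).
    """
    em = model.emission_matrix()
    if D.mode != model.mode:
        raise ValueError("matrix mode and error-model mode disagree")
    logem = np.log(em)
    data = np.where(D.missing_mask, 0, D.data)
    l0 = logem[0][data].astype(np.float64)
    l1 = logem[1][data].astype(np.float64)
    l0[D.missing_mask] = 0.0
    l1[D.missing_mask] = 0.0
    return l0, l1


def cell_loglik(cell_row: np.ndarray, profile: np.ndarray, model: ErrorModel,
                missing_mask: np.ndarray | None = None) -> float:
    """log p(D_i | S_n) — sum of log emissions over non-missing sites."""
    cell_row = np.asarray(cell_row)
    profile = np.asarray(profile)
    if cell_row.shape != profile.shape:
        raise ValueError("cell row and genotype profile lengths differ")
    if missing_mask is None:
        missing_mask = cell_row == MISSING
    logem = np.log(model.emission_matrix())
    obs = np.where(missing_mask, 0, cell_row)
    vals = logem[profile.astype(np.intp), obs.astype(np.intp)]
    return float(np.sum(np.where(missing_mask, 0.0, vals)))


def node_loglik_table(D: MutationMatrix, tree: MutationTree, model: ErrorModel,
                      nodes: list[int] | None = None) -> tuple[list[int], np.ndarray]:
    """Log-likelihood of every cell at every attached node (N × |V|).

    Columns follow the increasing-id order of ``attached_nodes``.  Computed
    incrementally down the tree: a child's column differs from its parent's
    by the single emission factor of the child's event.
    """
    if nodes is None:
        nodes = attached_nodes(tree)
    l0, l1 = loglik_columns(D, model)
    d_gain = l1 - l0
    L = np.empty((D.n_cells, len(nodes)))
    col = {v: i for i, v in enumerate(nodes)}
    # parents precede children in any root-first topological order; increasing
    # id order is not necessarily topological, so process by depth
    order = sorted(nodes, key=lambda v: _depth(tree, v))
    for v in order:
        i = col[v]
        if v == 0:
            L[:, i] = l0.sum(axis=1)
            continue
        p = int(tree.parent[v])
        j = tree.node_mutation(v)
        sign = 1.0 if tree.is_gain(v) else -1.0
        L[:, i] = L[:, col[p]] + sign * d_gain[:, j]
    return nodes, L


def _depth(tree: MutationTree, v: int) -> int:
    d = 0
    while v != 0:
        v = int(tree.parent[v])
        d += 1
    return d


@dataclass
class Attachment:
    """Maximum-likelihood cell placements ``xi`` and the total log-likelihood."""

    xi: np.ndarray
    loglik: float


def attach_cells(D: MutationMatrix, tree: MutationTree, model: ErrorModel) -> Attachment:
    """Attach each cell to its maximum-likelihood node (ties → smallest id)."""
    nodes, L = node_loglik_table(D, tree, model)
    best = np.argmax(L, axis=1)  # first occurrence wins = smallest node id
    xi = np.asarray(nodes, dtype=np.int32)[best]
    loglik = float(L[np.arange(D.n_cells), best].sum())
    return Attachment(xi=xi, loglik=loglik)


def attachment_posterior(D: MutationMatrix, tree: MutationTree,
                         model: ErrorModel) -> tuple[list[int], np.ndarray]:
    """Posterior attachment probabilities under a uniform node prior.

    Returns ``(nodes, P)`` where ``P[i, v]`` is the probability that cell
    ``i`` derives from attached node ``nodes[v]``; rows sum to 1.  Computed
    stably from log-likelihoods via log-sum-exp.
    """
    nodes, L = node_loglik_table(D, tree, model)
    logZ = logsumexp(L, axis=1, keepdims=True)
    return nodes, np.exp(L - logZ)
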