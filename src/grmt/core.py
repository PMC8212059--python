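"""Shared data model: mutation matrices, event-node trees, genotype derivation.

A mutation tree over ``M`` mutations under the k-Dollo parsimony model has
``zeta = (k+1)*M + 1`` labelled event nodes:

* node ``0`` — the root (no mutations);
* nodes ``1 .. M`` — gain events, one per mutation;
* nodes ``M+1 .. (k+1)*M`` — loss events, ``k`` interchangeable copies per
  mutation (copy ``q`` of mutation ``j`` sits at ``1 + M + q*M + j`` for
  0-based ``j``).

The tree structure is a parent vector: ``parent[v]`` is the parent node id,
``FREE`` (−1) marks a node not yet attached, and the root carries the
``ROOT_PARENT`` sentinel.  A loss event of mutation ``a`` may only hang below
a node whose genotype still carries ``a`` (gained and not yet lost on that
path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel in a parent vector for an unattached node
FREE = -1
#: sentinel for the root's parent slot (the root has no parent but is attached)
ROOT_PARENT = -2
#: integer code for a missing observation in matrix files
MISSING_CODE = 3
#: sentinel accepted by emission functions for a missing observation
MISSING = -9

VALID_MODES = ("binary", "ternary")


@dataclass
class MutationMatrix:
    """Observed single-cell mutation matrix D (cells in rows).

    ``data`` holds integer calls (0/1 in binary mode, 0/1/2 in ternary mode);
    entries under ``missing_mask`` are unobserved and their stored value is
    ignored.
    """

    data: np.ndarray
    missing_mask: np.ndarray
    mode: str = "binary"
    cell_ids: list[str] = field(default_factory=list)
    mutation_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a non-empty 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.data.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.data.shape:
            raise ValueError("missing_mask shape differs from data shape")
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}")
        hi = 1 if self.mode == "binary" else 2
        observed = self.data[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > hi):
            raise ValueError(
                f"matrix contains values outside 0..{hi} for {self.mode} mode"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.n_cells)]
        if not self.mutation_ids:
            self.mutation_ids = [f"mut{j}" for j in range(self.n_mutations)]
        if len(self.cell_ids) != self.n_cells or len(self.mutation_ids) != self.n_mutations:
            raise ValueError("id lists do not match matrix dimensions")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.data.shape[1]


class MutationTree:
    """Parent-vector mutation tree over (k+1)M+1 event nodes."""

    def __init__(self, n_mutations: int, k: int = 0, parent: np.ndarray | None = None):
        if n_mutations < 1:
            raise ValueError("need at least one mutation")
        if k < 0:
            raise ValueError("k must be non-negative")
        self.M = int(n_mutations)
        self.k = int(k)
        if parent is None:
            parent = np.full(self.n_nodes, FREE, dtype=np.int32)
            parent[0] = ROOT_PARENT
        parent = np.asarray(parent, dtype=np.int32)
        if parent.shape != (self.n_nodes,):
            raise ValueError(
                f"parent vector must have length zeta=(k+1)M+1={self.n_nodes}"
            )
        self.parent = parent

    @property
    def n_nodes(self) -> int:
        """zeta = M(k+1)+1."""
        return self.M * (self.k + 1) + 1

    # -- node label helpers -------------------------------------------------
    def gain_node(self, j: int) -> int:
        """Node id of the gain event of 0-based mutation ``j``."""
        return j + 1

    def loss_node(self, j: int, copy: int = 0) -> int:
        """Node id of loss copy ``copy`` of 0-based mutation ``j``."""
        if not 0 <= copy < self.k:
            raise ValueError("loss copy out of range")
        return 1 + self.M + copy * self.M + j

    def is_gain(self, v: int) -> bool:
        return 1 <= v <= self.M

    def is_loss(self, v: int) -> bool:
        return v > self.M

    def node_mutation(self, v: int) -> int:
        """0-based mutation index of event node ``v`` (root has none)."""
        if v == 0:
            raise ValueError("root carries no mutation")
        return (v - 1) % self.M

    def node_label(self, v: int, mutation_ids: list[str] | None = None) -> str:
        if v == 0:
            return "root"
        name = mutation_ids[self.node_mutation(v)] if mutation_ids else f"mut{self.node_mutation(v)}"
        return name if self.is_gain(v) else f"-{name}"

    def is_attached(self, v: int) -> bool:
        return self.parent[v] != FREE

    def copy(self) -> "MutationTree":
        return MutationTree(self.M, self.k, self.parent.copy())

    def children(self, v: int) -> list[int]:
        return [int(c) for c in np.flatnonzero(self.parent == v)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MutationTree)
            and self.M == other.M
            and self.k == other.k
            and np.array_equal(self.parent, other.parent)
        )

    def __repr__(self) -> str:
        t = int(np.sum(self.parent != FREE))
        return f"MutationTree(M={self.M}, k={self.k}, attached={t}/{self.n_nodes})"


@dataclass
class BuildParams:
    """Hyper-parameters of the generative tree search.

    alpha/beta are the false-positive / false-negative genotype error rates,
    ``lam`` weighs direct vs indirect expected cell flow in the candidate
    score, and ``kappa`` is the early-stopping threshold on the best score.
    """

    alpha: float
    beta: float
    k: int = 0
    lam: float = 0.7
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie strictly in (0,1)")
        if self.alpha + self.beta >= 1.0:
            raise ValueError("alpha + beta must be < 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must lie in (0,1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


class TreeStructureError(ValueError):
    """Raised when an operation receives a malformed mutation tree."""


def attached_nodes(tree: MutationTree) -> list[int]:
    """All attached node ids, root first, in increasing id order."""
    violations = validate_tree(tree)
    if violations:
        raise TreeStructureError("; ".join(violations))
    return [int(v) for v in np.flatnonzero(tree.parent != FREE)]


def genotype_of_node(tree: MutationTree, node: int) -> np.ndarray:
    """Length-M binary genotype implied by the root→node event path.

    A mutation is present iff its gain lies on the path and no loss of the
    same mutation occurs below that gain on the path.
    """
    node = int(node)
    if not 0 <= node < tree.n_nodes:
        raise ValueError(f"node {node} out of range")
    if tree.parent[node] == FREE:
        raise ValueError(f"node {node} is not attached")
    path = []
    v = node
    while v != 0:
        path.append(v)
        v = int(tree.parent[v])
        if len(path) > tree.n_nodes:
            raise TreeStructureError("cycle detected while walking to root")
    states = np.zeros(tree.M, dtype=np.int8)
    for v in reversed(path):  # root-to-node order
        j = tree.node_mutation(v)
        states[j] = 1 if tree.is_gain(v) else 0
    return states


def validate_tree(tree: MutationTree) -> list[str]:
    """Return human-readable descriptions of every structural violation.

    An empty list certifies: root attached with the ROOT_PARENT sentinel,
    every attached non-root node's parent attached and reachable from the
    root without cycles, and every attached loss node placed below a point
    where its mutation is currently present (the k-Dollo placement rule).
    """
    out: list[str] = []
    parent = tree.parent
    if parent[0] != ROOT_PARENT:
        out.append("node 0 (root) must carry the ROOT_PARENT sentinel")
        return out
    attached = np.flatnonzero(parent != FREE)
    for v in attached:
        v = int(v)
        if v == 0:
            continue
        p = int(parent[v])
        if not 0 <= p < tree.n_nodes:
            out.append(f"node {v} has out-of-range parent {p}")
        elif parent[p] == FREE:
            out.append(f"node {v} is attached to unattached node {p}")
    if out:
        return out
    # cycle check: walk each attached node to the root
    for v in attached:
        seen = set()
        u = int(v)
        while u != 0:
            if u in seen:
                out.append(f"cycle involving node {u}")
                return out
            seen.add(u)
            u = int(parent[u])
    # k-Dollo placement: a loss of mutation a hangs below a node carrying a
    for v in attached:
        v = int(v)
        if v == 0 or not tree.is_loss(v):
            continue
        j = tree.node_mutation(v)
        p = int(parent[v])
        if _genotype_unchecked(tree, p)[j] != 1:
            out.append(
                f"loss node {v} (mutation {j}) attached where the mutation "
                "is not present"
            )
    return out


def _genotype_unchecked(tree: MutationTree, node: int) -> np.ndarray:
    """genotype_of_node without validation (for use inside validate_tree)."""
    states = np.zeros(tree.M, dtype=np.int8)
    path = []
    v = int(node)
    while v != 0:
        path.append(v)
        v = int(tree.parent[v])
    for v in reversed(path):
        j = tree.node_mutation(v)
        states[j] = 1 if tree.is_gain(v) else 0
    return states


def genotype_matrix(tree: MutationTree, nodes: list[int] | np.ndarray) -> np.ndarray:
    """Stack genotype profiles for several attached nodes (len(nodes) × M)."""
    return np.array([genotype_of_node(tree, int(v)) for v in nodes], dtype=np.int8)
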