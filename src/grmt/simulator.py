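"""Synthetic single-cell mutation data under the k-Dollo model.

The generator mirrors the conditions used to benchmark the tree builder:
a random ground-truth mutation tree, uniform cell attachments, and noise
layered as doublet merging, genotype errors (false positives/negatives),
then missing entries.

Tree shape is controlled by ``gamma``: each new gain node picks its parent
uniformly from all attached nodes with probability ``gamma`` (yielding a
random recursive tree) and extends the most recently added node otherwise,
so ``gamma = 0`` produces a linear chain and ``gamma = 1`` a bushy tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FREE, MutationMatrix, MutationTree, validate_tree


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the benchmark defaults: 200 cells × 200 mutations,
    FPR 1%, FNR 20%, 10% missing entries, 10% doublets, no losses.
    """

    N: int = 200
    M: int = 200
    alpha: float = 0.01
    beta: float = 0.2
    eta: float = 0.1
    rho: float = 0.1
    k: int = 0
    gamma: float = 1.0
    loss_prob: float = 0.5
    mode: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be positive")
        for name in ("alpha", "beta", "eta", "rho", "gamma", "loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.alpha >= 1 or self.beta >= 1 or self.eta >= 1 or self.rho >= 1:
            raise ValueError("rates must be < 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class SimOutput:
    tree: MutationTree
    E: np.ndarray
    D: MutationMatrix
    attachments: np.ndarray
    doublet_mask: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> MutationTree:
    """Grow a random ground-truth mutation tree.

    Gain nodes are attached in a random mutation order; with probability
    ``gamma`` the parent is uniform over all attached nodes, otherwise the
    most recently attached node is extended.  When ``k > 0`` each mutation
    then receives one loss event with probability ``loss_prob``, placed
    uniformly among attached nodes whose genotype still carries it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = MutationTree(config.M, config.k)
    profiles = np.zeros((tree.n_nodes, config.M), dtype=np.int8)
    attached = [0]
    last = 0
    for j in rng.permutation(config.M):
        gain = tree.gain_node(int(j))
        if rng.random() < config.gamma:
            parent = int(attached[rng.integers(len(attached))])
        else:
            parent = last
        tree.parent[gain] = parent
        profiles[gain] = profiles[parent]
        profiles[gain, j] = 1
        attached.append(gain)
        last = gain
    if config.k > 0:
        for j in range(config.M):
            if rng.random() >= config.loss_prob:
                continue
            eligible = [v for v in attached if profiles[v, j] == 1]
            parent = int(eligible[rng.integers(len(eligible))])
            loss = tree.loss_node(j, 0)
            tree.parent[loss] = parent
            profiles[loss] = profiles[parent]
            profiles[loss, j] = 0
            attached.append(loss)
    assert not validate_tree(tree)
    return tree


def simulate_cells(tree: MutationTree, config: SimConfig,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Attach cells uniformly to the tree's nodes and read off genotypes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nodes = np.flatnonzero(tree.parent != FREE)
    profiles = _profiles_of(tree, nodes)
    idx = rng.integers(len(nodes), size=config.N)
    attachments = nodes[idx].astype(np.int32)
    E = profiles[idx].copy()
    return E, attachments


def add_noise(E: np.ndarray, attachments: np.ndarray, tree: MutationTree,
              config: SimConfig,
              rng: np.random.Generator | None = None) -> tuple[MutationMatrix, np.ndarray]:
    """Layer doublets, genotype errors, then missing entries onto E.

    Doublets: with probability ``rho`` a cell's profile is OR-merged with the
    profile of another uniformly drawn node.  Errors: in binary mode 1→0
    flips occur at rate ``beta`` and 0→1 at rate ``alpha``; in ternary mode
    observations are drawn from the 2×3 dropout-aware emission table.
    Missing: every entry is masked independently at rate ``eta``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, M = E.shape
    nodes = np.flatnonzero(tree.parent != FREE)
    profiles = _profiles_of(tree, nodes)

    doublet_mask = rng.random(N) < config.rho
    signal = E.copy()
    for i in np.flatnonzero(doublet_mask):
        partner = profiles[rng.integers(len(nodes))]
        signal[i] = signal[i] | partner

    r = rng.random((N, M))
    if config.mode == "binary":
        data = signal.copy()
        data[(signal == 1) & (r < config.beta)] = 0
        data[(signal == 0) & (r < config.alpha)] = 1
    else:
        a, b = config.alpha, config.beta
        # cumulative thresholds of the emission rows for states 0 and 1
        data = np.zeros((N, M), dtype=np.int8)
        p0 = np.where(signal == 1, b / 2.0, 1.0 - a - a * b / 2.0)
        p1 = np.where(signal == 1, 1.0 - b, a)
        data[r >= p0] = 1
        data[r >= p0 + p1] = 2

    missing = rng.random((N, M)) < config.eta
    D = MutationMatrix(data=data, missing_mask=missing, mode=config.mode)
    return D, doublet_mask


def simulate(config: SimConfig) -> SimOutput:
    """Full pipeline: tree → cells → noise, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    E, attachments = simulate_cells(tree, config, rng)
    D, doublet_mask = add_noise(E, attachments, tree, config, rng)
    return SimOutput(tree=tree, E=E, D=D, attachments=attachments,
                     doublet_mask=doublet_mask, config=config)


def _profiles_of(tree: MutationTree, nodes: np.ndarray) -> np.ndarray:
    """Genotype profiles for the given attached nodes (parent-first fill)."""
    prof = np.zeros((tree.n_nodes, tree.M), dtype=np.int8)
    order = sorted(nodes, key=lambda v: _depth(tree, int(v)))
    for v in order:
        v = int(v)
        if v == 0:
            continue
        p = int(tree.parent[v])
        j = tree.node_mutation(v)
        prof[v] = prof[p]
        prof[v, j] = 1 if tree.is_gain(v) else 0
    return prof[np.asarray(nodes, dtype=np.intp)]


def _depth(tree: MutationTree, v: int) -> int:
    d = 0
    while v != 0:
        v = int(tree.parent[v])
        d += 1
    return d
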