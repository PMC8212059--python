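"""Evaluation metrics: genotype recovery and CASet/DISC tree distances.

Genotype metrics compare the predicted genotype matrix (each cell's profile
at its maximum-likelihood node) with the ground truth, excluding doublet
cells.  Tree distances follow the common-ancestor-set (CASet) and
distinctly-inherited-set (DISC) measures: after aggregating linear chains
whose internal order is unidentifiable, each mutation's ancestor set is the
set of mutations on the root path to (and including) its node, and the
distance averages Jaccard distances between the two trees' ancestor-set
intersections (unordered pairs, CASet) or set differences (ordered pairs,
DISC).  The intersection variants restrict the mutation universe to
mutations present in both trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MutationTree, attached_nodes, genotype_matrix
from .likelihood import Attachment


def predicted_genotypes(tree: MutationTree, attachment: Attachment) -> np.ndarray:
    """Predicted genotype matrix: row i = profile of cell i's ML node."""
    xi = np.asarray(attachment.xi)
    uniq, inv = np.unique(xi, return_inverse=True)
    return genotype_matrix(tree, uniq)[inv]


def imputation_accuracy(D, E_pred: np.ndarray, E_true: np.ndarray,
                        doublet_mask: np.ndarray | None = None) -> float:
    """Percentage of missing entries (non-doublet rows) imputed correctly."""
    if doublet_mask is None:
        doublet_mask = np.zeros(D.n_cells, dtype=bool)
    keep = ~np.asarray(doublet_mask, dtype=bool)
    sel = D.missing_mask & keep[:, None]
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no missing entries in non-doublet rows to impute")
    correct = int((E_pred[sel] == E_true[sel]).sum())
    return 100.0 * correct / n


def gtm_error_rate(E_pred: np.ndarray, E_true: np.ndarray,
                   doublet_mask: np.ndarray | None = None) -> float:
    """Fraction of genotype entries (non-doublet rows) predicted wrongly."""
    E_pred = np.asarray(E_pred)
    E_true = np.asarray(E_true)
    if E_pred.shape != E_true.shape:
        raise ValueError("genotype matrices differ in shape")
    if doublet_mask is None:
        doublet_mask = np.zeros(E_pred.shape[0], dtype=bool)
    keep = ~np.asarray(doublet_mask, dtype=bool)
    if not keep.any():
        raise ValueError("all cells are doublets; nothing to evaluate")
    return float((E_pred[keep] != E_true[keep]).mean())


@dataclass
class AggregatedTree:
    """Mutation tree with unidentifiable linear chains collapsed.

    Each node carries a (possibly empty) set of mutation labels; labels are
    disjoint across nodes and their union is the tree's gained mutations.
    """

    parent: dict[int, int]
    labels: dict[int, set[int]]
    root: int = 0
    cells: dict[int, int] = field(default_factory=dict)

    def label_union(self) -> set[int]:
        out: set[int] = set()
        for s in self.labels.values():
            out |= s
        return out

    def children(self, v: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == v and c != self.root]


def aggregate_linear_chains(tree: MutationTree, attachment: Attachment) -> AggregatedTree:
    """Collapse chains whose chronological order no cells pin down.

    While some node has exactly one child and no attached cells, the node
    and its child merge into one (label sets united); repeated to fixpoint.
    The mutation universe is gain events; loss nodes carry no labels but
    take part in merging.
    """
    nodes = attached_nodes(tree)
    parent = {v: int(tree.parent[v]) for v in nodes if v != 0}
    parent[0] = -1
    labels = {v: ({tree.node_mutation(v)} if v != 0 and tree.is_gain(v) else set())
              for v in nodes}
    cells = {v: 0 for v in nodes}
    for x in np.asarray(attachment.xi):
        cells[int(x)] += 1

    children: dict[int, set[int]] = {v: set() for v in nodes}
    for v in nodes:
        if v != 0:
            children[parent[v]].add(v)

    changed = True
    while changed:
        changed = False
        for p in list(children):
            if p not in children:
                continue
            if cells[p] == 0 and len(children[p]) == 1:
                c = next(iter(children[p]))
                labels[p] |= labels.pop(c)
                cells[p] += cells.pop(c)
                children[p] = children.pop(c)
                for g in children[p]:
                    parent[g] = p
                parent.pop(c, None)
                changed = True
    return AggregatedTree(parent=parent, labels=labels, root=0, cells=cells)


def _ancestor_matrix(agg: AggregatedTree, universe: list[int]) -> np.ndarray:
    """Bool matrix A[i, l]: label universe[l] is an ancestor of (or co-located
    with) mutation universe[i], restricted to the universe."""
    pos = {m: i for i, m in enumerate(universe)}
    node_of = {}
    for v, labs in agg.labels.items():
        for m in labs:
            node_of[m] = v
    # ancestor label set per node, walking up to the root
    anc_cache: dict[int, set[int]] = {}

    def anc(v: int) -> set[int]:
        if v in anc_cache:
            return anc_cache[v]
        if v == agg.root:
            s = set(agg.labels.get(v, set()))
        else:
            s = anc(agg.parent[v]) | agg.labels[v]
        anc_cache[v] = s
        return s

    A = np.zeros((len(universe), len(universe)), dtype=bool)
    for i, m in enumerate(universe):
        for lab in anc(node_of[m]):
            if lab in pos:
                A[i, pos[lab]] = True
    return A


def _common_universe(T1: AggregatedTree, T2: AggregatedTree, intersect: bool) -> list[int]:
    u1, u2 = T1.label_union(), T2.label_union()
    universe = sorted(u1 & u2 if intersect else u1 | u2)
    if not universe:
        raise ValueError("the trees share no mutations")
    return universe


def caset_distance(T1: AggregatedTree, T2: AggregatedTree, intersect: bool = True) -> float:
    """Mean Jaccard distance of common-ancestor sets over unordered pairs."""
    universe = _common_universe(T1, T2, intersect)
    m = len(universe)
    if m < 2:
        return 0.0
    A1 = _ancestor_matrix(T1, universe).astype(np.float64)
    A2 = _ancestor_matrix(T2, universe).astype(np.float64)
    U = A1 * A2
    inter = U @ U.T                       # |C1(i,j) ∩ C2(i,j)|
    c1 = A1 @ A1.T
    c2 = A2 @ A2.T
    union = c1 + c2 - inter
    with np.errstate(invalid="ignore"):
        jd = np.where(union > 0, 1.0 - inter / np.where(union > 0, union, 1.0), 0.0)
    iu = np.triu_indices(m, k=1)
    return float(jd[iu].mean())


def disc_distance(T1: AggregatedTree, T2: AggregatedTree, intersect: bool = True) -> float:
    """Mean Jaccard distance of distinctly-inherited sets over ordered pairs."""
    universe = _common_universe(T1, T2, intersect)
    m = len(universe)
    if m < 2:
        return 0.0
    A1 = _ancestor_matrix(T1, universe).astype(np.float64)
    A2 = _ancestor_matrix(T2, universe).astype(np.float64)
    U = A1 * A2                           # label in both A1(i) and A2(i)
    V = (1.0 - A1) * (1.0 - A2)           # label in neither A1(j) nor A2(j)
    inter = U @ V.T                       # |D1(i,j) ∩ D2(i,j)|
    d1 = A1 @ (1.0 - A1).T
    d2 = A2 @ (1.0 - A2).T
    union = d1 + d2 - inter
    jd = np.where(union > 0, 1.0 - inter / np.where(union > 0, union, 1.0), 0.0)
    off = ~np.eye(m, dtype=bool)
    return float(jd[off].mean())


@dataclass
class EvalReport:
    """Bundle of the four benchmark metrics for one replicate."""

    imputed_mb_pct: float | None
    gtm_error_rate: float
    caset: float
    disc: float

    def as_dict(self) -> dict:
        return {
            "imputed_mb_pct": self.imputed_mb_pct,
            "gtm_error_rate": self.gtm_error_rate,
            "caset": self.caset,
            "disc": self.disc,
        }


def evaluate_run(D, pred_tree: MutationTree, pred_attach: Attachment,
                 true_tree: MutationTree, true_attach: Attachment,
                 E_true: np.ndarray,
                 doublet_mask: np.ndarray | None = None) -> EvalReport:
    """All four metrics between a reconstruction and the ground truth."""
    E_pred = predicted_genotypes(pred_tree, pred_attach)
    try:
        imput = imputation_accuracy(D, E_pred, E_true, doublet_mask)
    except ValueError:
        imput = None
    err = gtm_error_rate(E_pred, E_true, doublet_mask)
    a_pred = aggregate_linear_chains(pred_tree, pred_attach)
    a_true = aggregate_linear_chains(true_tree, true_attach)
    return EvalReport(
        imputed_mb_pct=imput,
        gtm_error_rate=err,
        caset=caset_distance(a_pred, a_true),
        disc=disc_distance(a_pred, a_true),
    )
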