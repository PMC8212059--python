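"""Model/Results front end for mutation-tree reconstruction.

``MutationTreeModel`` wraps an observed single-cell mutation matrix together
with the k-Dollo and search hyper-parameters; ``fit`` runs the generative
tree search (optionally estimating the error rates first) and returns a
``MutationTreeResults`` carrying the tree, cell attachments, log-likelihood
and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FREE, BuildParams, MutationMatrix, MutationTree
from .error_inference import BOConfig, infer_error_rates
from .likelihood import Attachment, ErrorModel
from .metrics import predicted_genotypes
from .treebuilder import BuildResult, build_mutation_tree


class MutationTreeModel:
    """Generative mutation-tree model for noisy single-cell genotype calls.

    Parameters
    ----------
    data : MutationMatrix or array-like
        N×M observed mutation calls, cells in rows.  Arrays may contain the
        missing code (3 by default).
    alpha, beta : float, optional
        False-positive / false-negative rates.  Leave unset to estimate them
        during ``fit(infer_errors=True)``.
    k : int
        Maximum number of losses per mutation (0 = infinite-sites model).
    lam : float
        Weight of direct vs indirect expected cell flow in candidate scores.
    kappa : float
        Early-stopping threshold on the best candidate score.
    """

    def __init__(self, data, alpha: float | None = None, beta: float | None = None,
                 k: int = 0, lam: float = 0.7, kappa: float = 1.0,
                 mode: str = "binary", missing_code: int = 3):
        if isinstance(data, MutationMatrix):
            self.data = data
        else:
            arr = np.asarray(data)
            mask = arr == missing_code
            self.data = MutationMatrix(data=np.where(mask, 0, arr),
                                       missing_mask=mask, mode=mode)
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.lam = lam
        self.kappa = kappa

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MutationTreeModel":
        """Build from a DataFrame (index = cell ids, columns = mutation ids)."""
        model = cls(df.to_numpy(), **kwargs)
        model.data.cell_ids = [str(i) for i in df.index]
        model.data.mutation_ids = [str(c) for c in df.columns]
        return model

    def fit(self, infer_errors: bool = False,
            bo_config: BOConfig | None = None) -> "MutationTreeResults":
        """Run the tree search; optionally estimate (alpha, beta) first."""
        if infer_errors:
            est = infer_error_rates(self.data, k=self.k, lam=self.lam,
                                    kappa=self.kappa, config=bo_config)
            return MutationTreeResults(self, est.result, est.alpha, est.beta,
                                       estimated=True, bo_history=(est.evaluated, est.values))
        if self.alpha is None or self.beta is None:
            raise ValueError("alpha and beta must be given unless infer_errors=True")
        params = BuildParams(alpha=self.alpha, beta=self.beta, k=self.k,
                             lam=self.lam, kappa=self.kappa)
        model = ErrorModel(self.alpha, self.beta, mode=self.data.mode)
        res = build_mutation_tree(self.data, params, model)
        return MutationTreeResults(self, res, self.alpha, self.beta)


class MutationTreeResults:
    """Fitted mutation tree with attachments, likelihood and diagnostics."""

    def __init__(self, model: MutationTreeModel, build: BuildResult,
                 alpha: float, beta: float, estimated: bool = False,
                 bo_history=None):
        self.model = model
        self.build = build
        self.tree: MutationTree = build.best_tree
        self.attachment: Attachment = build.attachment
        self.loglik: float = build.best_loglik
        self.alpha = alpha
        self.beta = beta
        self.estimated = estimated
        self.bo_history = bo_history
        self.trace = build.trace

    @property
    def n_attached(self) -> int:
        return int(np.sum(self.tree.parent != FREE))

    def predicted_genotypes(self) -> np.ndarray:
        """Denoised genotype matrix implied by the ML cell attachments."""
        return predicted_genotypes(self.tree, self.attachment)

    def imputed_frame(self) -> pd.DataFrame:
        """Predicted genotypes as a labelled DataFrame."""
        return pd.DataFrame(self.predicted_genotypes(),
                            index=self.model.data.cell_ids,
                            columns=self.model.data.mutation_ids)

    def n_losses(self) -> int:
        """Number of attached mutation-loss events."""
        return sum(1 for v in range(self.tree.M + 1, self.tree.n_nodes)
                   if self.tree.parent[v] != FREE)

    def summary(self) -> str:
        d = self.model.data
        rows = [
            ("cells (N)", d.n_cells),
            ("mutations (M)", d.n_mutations),
            ("mode", d.mode),
            ("k (max losses)", self.tree.k),
            ("lambda", self.model.lam),
            ("kappa", self.model.kappa),
            ("alpha (FPR)", f"{self.alpha:.4g}" + (" [estimated]" if self.estimated else "")),
            ("beta (FNR)", f"{self.beta:.4g}" + (" [estimated]" if self.estimated else "")),
            ("attached nodes", self.n_attached),
            ("mutation losses", self.n_losses()),
            ("log-likelihood", f"{self.loglik:.2f}"),
            ("stop reason", self.build.stop_reason),
        ]
        width = max(len(name) for name, _ in rows)
        lines = ["Mutation tree reconstruction", "=" * 40]
        lines += [f"{name:<{width}}  {val}" for name, val in rows]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MutationTreeResults loglik={self.loglik:.2f} "
                f"nodes={self.n_attached} k={self.tree.k}>")
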