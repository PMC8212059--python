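"""Error-rate estimation by Bayesian optimization.

The objective f(alpha, beta) is the data log-likelihood of the best tree the
builder finds at those error rates.  A Gaussian-process surrogate (Matérn
5/2, per-dimension lengthscales) is fitted to the points evaluated so far —
on the search box linearly rescaled to the unit square — and the next point
to evaluate maximizes the expected improvement over the incumbent.  After an
initial Latin-hypercube design of ``n_init`` points and ``n_iter``
acquisition steps, the best *evaluated* point is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .core import BuildParams, MutationMatrix
from .likelihood import ErrorModel
from .treebuilder import BuildResult, build_mutation_tree

DEFAULT_BOUNDS = ((1e-4, 0.1), (1e-4, 0.5))  # (alpha, beta) search box


@dataclass
class BOConfig:
    n_init: int = 50
    n_iter: int = 15
    bounds: tuple = DEFAULT_BOUNDS
    seed: int = 0
    n_candidates: int = 2048
    refit_every: int = 5
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_init < 2:
            raise ValueError("need at least two initial design points")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        for lo, hi in self.bounds:
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("bounds must lie strictly inside (0,1)")


@dataclass
class SurrogateState:
    """Evaluated points, their objective values, and the fitted GP."""

    X: np.ndarray                 # (t, 2) in unit-cube coordinates
    y: np.ndarray                 # (t,) standardized objective values
    gp: GaussianProcessRegressor = field(repr=False, default=None)

    @property
    def incumbent(self) -> float:
        return float(np.max(self.y))


def objective(D: MutationMatrix, x: tuple[float, float], k: int = 0,
              lam: float = 0.7, kappa: float = 1.0) -> float:
    """Best-tree log-likelihood at error rates x = (alpha, beta)."""
    alpha, beta = float(x[0]), float(x[1])
    params = BuildParams(alpha=alpha, beta=beta, k=k, lam=lam, kappa=kappa)
    model = ErrorModel(alpha, beta, mode=D.mode)
    return build_mutation_tree(D, params, model).best_loglik


def fit_surrogate(X: np.ndarray, y: np.ndarray, seed: int = 0,
                  jitter: float = 1e-8, optimize: bool = True,
                  kernel=None) -> SurrogateState:
    """Fit the GP surrogate, escalating jitter on factorization failure."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if kernel is None:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.full(X.shape[1], 0.3),
            length_scale_bounds=(1e-2, 1e2), nu=2.5)
    for attempt in range(8):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=jitter * 10 ** attempt,
            normalize_y=True, optimizer="fmin_l_bfgs_b" if optimize else None,
            n_restarts_optimizer=2 if optimize else 0,
            random_state=seed)
        try:
            import warnings

            from sklearn.exceptions import ConvergenceWarning

            with warnings.catch_warnings():
                # short L-BFGS runs on a 2-d kernel routinely stop early;
                # the fit is still usable as an acquisition surrogate
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
            return SurrogateState(X=X, y=y, gp=gp)
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError("GP fit failed even with escalated jitter")


def gp_posterior(state: SurrogateState, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of the surrogate at point(s) x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu, sd = state.gp.predict(x, return_std=True)
    return mu, sd ** 2


def expected_improvement(mu, sigma, incumbent: float):
    """Closed-form EI of a Gaussian belief over a maximization objective.

    EI = (mu - f*) Phi(z) + sigma phi(z) with z = (mu - f*)/sigma; at
    sigma = 0 it degenerates to max(mu - f*, 0).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    imp = mu - incumbent
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(sigma > 0,
                      imp * norm.cdf(z) + sigma * norm.pdf(z),
                      np.maximum(imp, 0.0))
    return ei if ei.ndim else float(ei)


@dataclass
class ErrorEstimate:
    alpha: float
    beta: float
    result: BuildResult
    evaluated: np.ndarray        # (t, 2) evaluated (alpha, beta) points
    values: np.ndarray           # (t,) objective values

    def __iter__(self):
        return iter((self.alpha, self.beta, self.result))


def infer_error_rates(D: MutationMatrix, k: int = 0, lam: float = 0.7,
                      kappa: float = 1.0,
                      config: BOConfig | None = None) -> ErrorEstimate:
    """Maximum-likelihood (alpha, beta) by GP-based Bayesian optimization."""
    if config is None:
        config = BOConfig()
    rng = np.random.default_rng(config.seed)
    blo = np.array([b[0] for b in config.bounds])
    bhi = np.array([b[1] for b in config.bounds])

    # the GP works on the rate box linearly rescaled to the unit square; a
    # logit rescaling devotes most of the square to vanishing rates and
    # steers the acquisition into that empty region
    def to_rates(u: np.ndarray) -> np.ndarray:
        return blo + np.clip(np.asarray(u), 0.0, 1.0) * (bhi - blo)

    def to_unit(x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - blo) / (bhi - blo)

    sampler = qmc.LatinHypercube(d=2, seed=rng)
    X0 = blo + sampler.random(config.n_init) * (bhi - blo)
    U = [to_unit(x) for x in X0]
    y = [objective(D, x, k=k, lam=lam, kappa=kappa) for x in X0]

    state = None
    for step in range(config.n_iter):
        t = len(y)
        refit = state is None or (t % config.refit_every) == 0
        kern = None if refit else state.gp.kernel_
        state = fit_surrogate(np.array(U), np.array(y), seed=config.seed,
                              jitter=config.jitter, optimize=refit,
                              kernel=kern)
        inc = state.incumbent
        # dense uniform candidates plus a local cloud around the incumbent,
        # then local refinement from the best one
        u_best = U[int(np.argmax(y))]
        local = np.clip(u_best + 0.05 * rng.standard_normal((256, 2)), 0.0, 1.0)
        cand = np.vstack([rng.random((config.n_candidates, 2)), local])
        mu, var = gp_posterior(state, cand)
        ei = expected_improvement(mu, np.sqrt(var), inc)
        u0 = cand[int(np.argmax(ei))]

        def neg_ei(u):
            m, v = gp_posterior(state, u)
            return -float(np.asarray(expected_improvement(m, np.sqrt(v), inc)).ravel()[0])

        res = minimize(neg_ei, u0, method="L-BFGS-B",
                       bounds=[(0.0, 1.0), (0.0, 1.0)])
        u_next = res.x if res.success and -res.fun >= -neg_ei(u0) else u0
        U.append(np.asarray(u_next))
        y.append(objective(D, to_rates(u_next), k=k, lam=lam, kappa=kappa))

    y_arr = np.asarray(y)
    X_rates = np.array([to_rates(u) for u in U])
    best = int(np.argmax(y_arr))
    alpha, beta = float(X_rates[best, 0]), float(X_rates[best, 1])
    params = BuildParams(alpha=alpha, beta=beta, k=k, lam=lam, kappa=kappa)
    model = ErrorModel(alpha, beta, mode=D.mode)
    result = build_mutation_tree(D, params, model)
    return ErrorEstimate(alpha=alpha, beta=beta, result=result,
                         evaluated=X_rates, values=y_arr)
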