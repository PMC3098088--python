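"""emBayesB: EM estimation of SNP effects under a Dirac + Laplace mixture prior.

The model is ``y = B g + e`` with standardized genotype columns.  An EM
algorithm treats each SNP's slab/atom membership as missing data: the
E-step computes ``gamma_j``, the posterior probability that SNP ``j`` is in
LD with QTL, from the two component marginal likelihoods of its conditional
maximum-likelihood estimate ``G_j``; the M-step updates the effect by a
``gamma_j``-scaled soft threshold (the MAP rule) and the hyperparameters
``gamma``, ``lambda``, ``sigma_e^2`` by their ML estimators.  Sweeps over
SNP are Gauss-Seidel: either with the precomputed cross-product matrix
(``gs``) or with an incrementally updated residual vector (``gsru``), which
never forms the m x m matrix and scales to large panels.  Both produce
identical iterates for the same update order.

Fitting modes
-------------
embayesb        full EM with hyperparameter re-estimation (and a safeguard
                bound on lambda)
embayesb_fixed  same updates with all hyperparameters frozen
lasso           gamma fixed at 1 with frozen lambda, sigma_e^2: the MAP rule
                reduces to plain soft-thresholding (the LASSO)
ice             iterated conditional expectation: each SNP set to its exact
                conditional posterior mean, hyperparameters frozen
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _kernels
from .prior import ConditionalContext, HyperParams, posterior_prob

__all__ = [
    "FitConfig",
    "EMState",
    "FitResult",
    "initialize",
    "cml_estimate",
    "map_update",
    "update_hyperparams",
    "convergence",
    "sweep_gs",
    "sweep_gsru",
    "fit",
    "EMBayesB",
]

_MODES = ("embayesb", "lasso", "ice", "embayesb_fixed")
_SOLVERS = ("auto", "gs", "gsru")

# beyond this panel size the solver="auto" choice avoids materializing B'B
_DIRECT_M = 2000


@dataclass
class FitConfig:
    """Configuration of one EM run.

    ``h2_init`` is the guessed heritability used by the Step-1 formulas
    ``sigma_e2 = (1 - h2) var(y)`` and ``lambda = sqrt(2 m gamma / (h2 var(y)))``
    (the DE slab variance is ``2/lambda^2``, so ``m gamma`` slab SNP give
    genetic variance ``h2 var(y)``).  ``lambda_init``/``sigma_e2_init``
    override the formulas when given (ICE runs usually supply them).
    """

    mode: str = "embayesb"
    solver: str = "auto"
    h2_init: float = 0.5
    gamma_init: float = 0.01
    lambda_init: float | None = None
    sigma_e2_init: float | None = None
    tol: float = 1e-8
    max_iter: int = 5000
    lambda_bound_policy: str = "lasso_bound"
    residual_refresh_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.solver not in _SOLVERS:
            raise ValueError(f"solver must be one of {_SOLVERS}, got {self.solver!r}")
        if self.mode == "lasso":
            if self.gamma_init not in (None, 1.0, 0.01):
                raise ValueError("lasso mode fixes gamma at 1; do not set gamma_init")
            self.gamma_init = 1.0
        if not 0.0 < self.h2_init < 1.0:
            raise ValueError("h2_init must be in (0, 1)")
        if not 0.0 < self.gamma_init <= 1.0:
            raise ValueError("gamma_init must be in (0, 1]")
        if not self.tol > 0.0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1 or self.residual_refresh_every < 1:
            raise ValueError("max_iter and residual_refresh_every must be >= 1")
        if self.lambda_bound_policy not in ("lasso_bound", "none"):
            raise ValueError("lambda_bound_policy must be 'lasso_bound' or 'none'")

    @property
    def updates_hyperparams(self) -> bool:
        return self.mode == "embayesb"


@dataclass
class EMState:
    """Mutable state of the EM iteration."""

    g_hat: np.ndarray
    gamma_post: np.ndarray
    e: np.ndarray
    hp: HyperParams
    iter: int = 0
    crit: float = np.inf


@dataclass
class FitResult:
    g_hat: np.ndarray
    gamma_post: np.ndarray
    hp_final: HyperParams
    converged: bool
    n_iter: int
    trace: list[dict] = field(default_factory=list)
    lambda_bound: float | None = None
    lambda_resets: int = 0

    @property
    def crit(self) -> float:
        return self.trace[-1]["crit"] if self.trace else np.inf


def lasso_initial_lambda(m: int, h2: float, var_y: float) -> float:
    """Step-1 lambda at gamma = 1: the LASSO initial value (and the
    safeguard bound for the EM lambda update)."""
    return float(np.sqrt(2.0 * m / (h2 * var_y)))


def initialize(y: np.ndarray, m: int, cfg: FitConfig) -> tuple[np.ndarray, HyperParams]:
    """Step 1: zero effects and moment-matched hyperparameters.

    ``var(y)`` uses divisor n.  Raises for a constant phenotype vector.
    """
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y))
    if var_y <= 0.0:
        raise ValueError("phenotype variance is zero; cannot initialize")
    gamma0 = cfg.gamma_init
    sigma_e2 = (
        cfg.sigma_e2_init
        if cfg.sigma_e2_init is not None
        else (1.0 - cfg.h2_init) * var_y
    )
    lam0 = (
        cfg.lambda_init
        if cfg.lambda_init is not None
        else float(np.sqrt(2.0 * m * gamma0 / (cfg.h2_init * var_y)))
    )
    return np.zeros(m), HyperParams(gamma=gamma0, lam=lam0, sigma_e2=sigma_e2)


def cml_estimate(j: int, state: EMState, B: np.ndarray, y: np.ndarray) -> float:
    """Conditional ML estimate of SNP j's effect given current estimates:
    ``G_j = (b_j'y - sum_{l != j} b_j'b_l g_l) / n``."""
    n = B.shape[0]
    bj = B[:, j]
    return float(
        (bj @ y - bj @ (B @ state.g_hat) + (bj @ bj) * state.g_hat[j]) / n
    )


def map_update(G: float, gamma_j: float, hp: HyperParams, n: int) -> float:
    """MAP effect update: ``gamma_j``-scaled soft threshold of ``G`` at
    ``lambda * sigma_e2 / n``."""
    return float(_kernels._map_update(G, gamma_j, hp.lam, hp.sigma_e2 / n))


def update_hyperparams(
    state: EMState,
    cfg: FitConfig,
    lambda_bound: float | None = None,
    lambda_reset_value: float | None = None,
) -> tuple[HyperParams, bool]:
    """M-step ML updates of (gamma, lambda, sigma_e2) after a full sweep.

    ``gamma = mean(gamma_j)``; ``lambda = sum(gamma_j)/sum(gamma_j |g_j|)``;
    ``sigma_e2 = ||y - B g||^2 / n``.  When the ``lasso_bound`` policy is
    active and the lambda update exceeds the bound (the gamma=1 Step-1
    lambda), lambda is reset to the run's own Step-1 value.  Returns the new
    hyperparameters and whether the reset fired.  Fixed-mode configs return
    the state's hyperparameters unchanged.
    """
    if not cfg.updates_hyperparams:
        return state.hp, False
    gp = state.gamma_post
    m = gp.size
    n = state.e.size
    gamma_hat = float(gp.sum() / m)
    denom = float(gp @ np.abs(state.g_hat))
    reset = False
    if denom > 0.0:
        lam_hat = float(gp.sum() / denom)
    else:
        lam_hat = lambda_bound if lambda_bound is not None else state.hp.lam
        reset = True
    if (
        cfg.lambda_bound_policy == "lasso_bound"
        and lambda_bound is not None
        and lam_hat > lambda_bound
    ):
        lam_hat = lambda_reset_value if lambda_reset_value is not None else lambda_bound
        reset = True
    sigma_e2 = float(state.e @ state.e / n)
    gamma_hat = min(max(gamma_hat, 1e-12), 1.0)
    sigma_e2 = max(sigma_e2, 1e-300)
    return HyperParams(gamma=gamma_hat, lam=lam_hat, sigma_e2=sigma_e2), reset


def convergence(g_new: np.ndarray, g_old: np.ndarray) -> float:
    """Relative-change criterion ``(dg'dg) / (g_new'g_new)``.

    Returns +inf (with a warning) for an all-zero ``g_new`` so a degenerate
    start keeps iterating rather than claiming convergence.
    """
    g_new = np.asarray(g_new, dtype=float)
    g_old = np.asarray(g_old, dtype=float)
    if g_new.shape != g_old.shape:
        raise ValueError("effect vectors differ in length")
    denom = float(g_new @ g_new)
    if denom == 0.0:
        warnings.warn("all-zero effect vector; convergence criterion undefined")
        return np.inf
    dg = g_new - g_old
    return float(dg @ dg / denom)


def _update_rule(mode: str) -> int:
    return 1 if mode == "ice" else 0


def sweep_gs(
    state: EMState,
    B: np.ndarray,
    y: np.ndarray,
    cfg: FitConfig | None = None,
    BtB: np.ndarray | None = None,
    Bty: np.ndarray | None = None,
) -> EMState:
    """One in-order Gauss-Seidel sweep using cross-products (small panels).

    For each SNP: cML estimate, E-step probability, effect update — with the
    updated effect used immediately by later SNP.  The residual vector is
    recomputed afterwards so the M-step sees ``e = y - B g``.
    """
    cfg = cfg or FitConfig()
    if BtB is None:
        BtB = B.T @ B
    if Bty is None:
        Bty = B.T @ y
    _kernels.gs_sweep_kernel(
        BtB,
        Bty,
        state.g_hat,
        state.gamma_post,
        state.hp.gamma,
        state.hp.lam,
        state.hp.sigma_e2,
        B.shape[0],
        _update_rule(cfg.mode),
    )
    state.e = y - B @ state.g_hat
    return state


def sweep_gsru(
    state: EMState, B: np.ndarray, y: np.ndarray, cfg: FitConfig | None = None
) -> EMState:
    """One Gauss-Seidel sweep with residual update (large panels).

    ``G_j = b_j'e/n + g_j`` and ``e`` is corrected immediately after every
    effect update; ``e`` is recomputed from scratch every
    ``residual_refresh_every`` sweeps to stop numerical drift.
    """
    cfg = cfg or FitConfig()
    _kernels.gsru_sweep_kernel(
        B,
        y,
        state.g_hat,
        state.gamma_post,
        state.e,
        state.hp.gamma,
        state.hp.lam,
        state.hp.sigma_e2,
        B.shape[0],
        _update_rule(cfg.mode),
    )
    if state.iter % cfg.residual_refresh_every == 0:
        state.e = y - B @ state.g_hat
    return state


def fit(B: np.ndarray, y: np.ndarray, cfg: FitConfig | None = None) -> FitResult:
    """Run the EM algorithm to convergence (criterion <= tol) or max_iter.

    ``B`` must be the standardized genotype matrix (column sums ~0, column
    sums of squares ~n).  Non-convergence is reported through
    ``FitResult.converged``, never raised.
    """
    cfg = cfg or FitConfig()
    B = np.asfortranarray(B, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, m = B.shape
    if y.shape != (n,):
        raise ValueError("y length does not match rows of B")

    g0, hp = initialize(y, m, cfg)
    var_y = float(np.var(y))
    bound = lasso_initial_lambda(m, cfg.h2_init, var_y)
    lam0 = hp.lam

    solver = cfg.solver
    if solver == "auto":
        solver = "gs" if m <= _DIRECT_M and m <= n else "gsru"
    BtB = Bty = None
    if solver == "gs":
        BtB = B.T @ B
        Bty = B.T @ y

    state = EMState(
        g_hat=g0,
        gamma_post=np.zeros(m),
        e=y - B @ g0,
        hp=hp,
    )
    trace: list[dict] = []
    resets = 0
    converged = False
    for k in range(1, cfg.max_iter + 1):
        state.iter = k
        g_old = state.g_hat.copy()
        if solver == "gs":
            sweep_gs(state, B, y, cfg, BtB=BtB, Bty=Bty)
        else:
            sweep_gsru(state, B, y, cfg)
        state.crit = convergence(state.g_hat, g_old)
        new_hp, reset = update_hyperparams(
            state, cfg, lambda_bound=bound, lambda_reset_value=lam0
        )
        state.hp = new_hp
        resets += int(reset)
        trace.append(
            {
                "crit": state.crit,
                "gamma": state.hp.gamma,
                "lambda": state.hp.lam,
                "sigma_e2": state.hp.sigma_e2,
            }
        )
        if state.crit <= cfg.tol:
            converged = True
            break

    return FitResult(
        g_hat=state.g_hat,
        gamma_post=state.gamma_post,
        hp_final=state.hp,
        converged=converged,
        n_iter=state.iter,
        trace=trace,
        lambda_bound=bound,
        lambda_resets=resets,
    )


class EMBayesB(RegressorMixin, BaseEstimator):
    """scikit-learn style estimator wrapping the emBayesB EM algorithm.

    Parameters mirror :class:`FitConfig`; ``X`` passed to :meth:`fit` and
    :meth:`predict` is the standardized genotype matrix (see
    :func:`embayesb.genotypes.standardize` and
    :func:`embayesb.genotypes.apply_training_scaling`).

    Attributes
    ----------
    coef_ : ndarray of shape (m,)
        MAP SNP effect estimates.
    gamma_post_ : ndarray of shape (m,)
        Posterior probability per SNP of being in LD with at least one QTL.
    hyperparams_ : HyperParams
        Final (gamma, lambda, sigma_e2).
    n_iter_ : int
    converged_ : bool
    trace_ : list of dict
        Per-iteration (crit, gamma, lambda, sigma_e2).
    """

    def __init__(
        self,
        mode: str = "embayesb",
        solver: str = "auto",
        h2_init: float = 0.5,
        gamma_init: float = 0.01,
        lambda_init: float | None = None,
        sigma_e2_init: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 5000,
        lambda_bound_policy: str = "lasso_bound",
        residual_refresh_every: int = 1,
    ):
        self.mode = mode
        self.solver = solver
        self.h2_init = h2_init
        self.gamma_init = gamma_init
        self.lambda_init = lambda_init
        self.sigma_e2_init = sigma_e2_init
        self.tol = tol
        self.max_iter = max_iter
        self.lambda_bound_policy = lambda_bound_policy
        self.residual_refresh_every = residual_refresh_every

    def _config(self) -> FitConfig:
        return FitConfig(
            mode=self.mode,
            solver=self.solver,
            h2_init=self.h2_init,
            gamma_init=self.gamma_init,
            lambda_init=self.lambda_init,
            sigma_e2_init=self.sigma_e2_init,
            tol=self.tol,
            max_iter=self.max_iter,
            lambda_bound_policy=self.lambda_bound_policy,
            residual_refresh_every=self.residual_refresh_every,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        result = fit(X, y, self._config())
        self.coef_ = result.g_hat
        self.gamma_post_ = result.gamma_post
        self.hyperparams_ = result.hp_final
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.trace_ = result.trace
        self.lambda_bound_ = result.lambda_bound
        self.lambda_resets_ = result.lambda_resets
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Genomic estimated breeding values ``GEBV = X @ coef_``."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_


def spike_surrogate_objective(
    B: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    hp: HyperParams,
    spike_lambda: float = 1000.0,
) -> float:
    """Marginal log posterior with the Dirac atom replaced by a DE spike.

    A continuous stand-in for the mixed-measure objective, usable as a
    convergence diagnostic.  Because the effect update is a posterior-
    probability-weighted mean of the two component modes rather than the
    exact maximizer of this surrogate's M-step, the surrogate is only
    guaranteed non-decreasing once the per-SNP probabilities have
    polarized; early sweeps can overshoot (the transient decays
    geometrically).
    """
    n = y.size
    slab = np.log(hp.gamma) + np.log(0.5 * hp.lam) - hp.lam * np.abs(g)
    spike = (
        np.log1p(-hp.gamma) + np.log(0.5 * spike_lambda) - spike_lambda * np.abs(g)
    )
    lp = float(np.logaddexp(slab, spike).sum())
    r = y - B @ g
    return lp - 0.5 * n * np.log(2 * np.pi * hp.sigma_e2) - float(r @ r) / (
        2 * hp.sigma_e2
    )


def estep_probabilities(G, hp: HyperParams, n: int) -> np.ndarray:
    """Vectorized E-step probabilities for a grid of cML estimates."""
    ctx = ConditionalContext.from_sigma_e2(np.asarray(G, dtype=float), n, hp.sigma_e2)
    return np.asarray(posterior_prob(ctx, hp))
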