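"""GS-BLUP: ridge-regression comparator for SNP effects.

All SNP effects are assumed normal with a common variance, which leads to
the ridge system ``(B'B + alpha I) g = B'y`` with shrinkage constant
``alpha = m (1 - h2) / h2`` (the residual-to-genetic variance ratio when
the m standardized SNP share the genetic variance equally).  ``m`` is the
post-MAF-filter panel size, i.e. the m of the fitted system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _kernels

__all__ = ["BlupConfig", "fit_gsblup", "GSBLUP", "ridge_alpha"]

_DIRECT_M = 2000


@dataclass
class BlupConfig:
    h2: float = 0.5
    solver: str = "auto"
    tol: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be strictly inside (0, 1)")
        if self.solver not in ("auto", "direct", "gsru"):
            raise ValueError("solver must be 'auto', 'direct' or 'gsru'")


def ridge_alpha(m: int, h2: float) -> float:
    """Shrinkage constant alpha = m (1 - h2) / h2."""
    return m * (1.0 - h2) / h2


def fit_gsblup(
    B: np.ndarray, y: np.ndarray, cfg: BlupConfig | None = None
) -> tuple[np.ndarray, bool]:
    """Solve ``(B'B + alpha I) g = B'y``; returns (g_hat, converged).

    ``direct`` factorizes the m x m system; ``gsru`` runs Gauss-Seidel
    coordinate updates with an incrementally maintained residual and stops
    when the normal-equations residual ``B'e - alpha g`` satisfies
    ``||r||_inf <= tol * max(1, ||B'y||_inf)``.  ``auto`` picks ``direct``
    for panels up to 2000 SNP.
    """
    cfg = cfg or BlupConfig()
    B = np.asfortranarray(B, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, m = B.shape
    alpha = ridge_alpha(m, cfg.h2)
    solver = cfg.solver
    if solver == "auto":
        solver = "direct" if m <= _DIRECT_M else "gsru"
    if solver == "direct":
        A = B.T @ B
        A[np.diag_indices_from(A)] += alpha
        g = np.linalg.solve(A, B.T @ y)
        return g, True
    g = np.zeros(m)
    e = y.copy()
    ref = max(1.0, float(np.max(np.abs(B.T @ y))))
    converged = False
    for _ in range(cfg.max_iter):
        _kernels.ridge_gsru_sweep_kernel(B, g, e, alpha, n)
        e = y - B @ g
        resid = float(np.max(np.abs(B.T @ e - alpha * g)))
        if resid <= cfg.tol * ref:
            converged = True
            break
    return g, converged


class GSBLUP(RegressorMixin, BaseEstimator):
    """Ridge ("equal variance") SNP-BLUP with heritability-derived shrinkage.

    Attributes: ``coef_`` (SNP effects), ``alpha_``, ``converged_``.
    """

    def __init__(
        self,
        h2: float = 0.5,
        solver: str = "auto",
        tol: float = 1e-10,
        max_iter: int = 10000,
    ):
        self.h2 = h2
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        cfg = BlupConfig(
            h2=self.h2, solver=self.solver, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_, self.converged_ = fit_gsblup(X, y, cfg)
        self.alpha_ = ridge_alpha(X.shape[1], self.h2)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_
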