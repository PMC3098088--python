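"""Per-SNP probabilistic machinery for the Dirac-delta + Laplace mixture prior.

The model assumes that a SNP effect ``g`` is drawn, with probability
``gamma``, from a double-exponential (Laplace, DE) slab with rate ``lam``,
and with probability ``1 - gamma`` from a point mass at zero (the Dirac
component, modelling SNP that are not in LD with any QTL).  Conditional on
all other SNP effects, the data contribute a normal likelihood centred at
the conditional maximum-likelihood estimate ``G`` with variance
``sigma_e2 / n``.  Everything the EM engine needs per SNP — the two
component marginal likelihoods, the E-step posterior probability of being
in the slab, and the conditional posterior mean (the ICE update) — lives
here in closed form, computed on the log scale so that regimes with
``lam * sigma >> 1`` or ``|G| / sigma >> 1`` never overflow.

For plotting and cross-checks the Dirac atom can be replaced by a second,
very concentrated DE "spike" with rate ``spike_lambda`` (e.g. 1000), which
turns the mixed measure into an ordinary density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, logsumexp

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class HyperParams:
    """Mixture-prior hyperparameters.

    Parameters
    ----------
    gamma : float
        Prior probability, in [0, 1], that a SNP is in LD with at least one
        QTL (i.e. that its effect comes from the DE slab).
    lam : float
        Rate of the DE slab, in inverse effect units; the slab variance is
        ``2 / lam**2``.
    sigma_e2 : float
        Residual variance of the trait, in squared trait units.
    """

    gamma: float
    lam: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not self.lam > 0.0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        if not self.sigma_e2 > 0.0:
            raise ValueError(f"sigma_e2 must be > 0, got {self.sigma_e2}")


@dataclass
class ConditionalContext:
    """Context of one SNP's conditional likelihood.

    ``G`` is the conditional maximum-likelihood (cML) estimate of the SNP
    effect given all other current estimates; the conditional likelihood of
    the effect is normal with mean ``G`` and variance ``sigma2 = sigma_e2/n``.
    """

    G: float
    n: int
    sigma2: float

    @classmethod
    def from_sigma_e2(cls, G: float, n: int, sigma_e2: float) -> "ConditionalContext":
        return cls(G=G, n=n, sigma2=sigma_e2 / n)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


def dirac_atom_weight(hp: HyperParams) -> float:
    """Prior mass of the point-mass (no-LD) component."""
    return 1.0 - hp.gamma


def prior_density(g, hp: HyperParams, spike_lambda: float | None = None):
    """Density of the mixture prior at effect ``g``.

    With ``spike_lambda`` given, the Dirac atom is replaced by a DE spike
    and the full (proper) mixture density
    ``gamma*(lam/2)e^(-lam|g|) + (1-gamma)*(lam_s/2)e^(-lam_s|g|)``
    is returned.  Without it, only the continuous slab part
    ``gamma*(lam/2)e^(-lam|g|)`` is returned; the weight of the atom at
    zero is available separately via :func:`dirac_atom_weight`.
    """
    g = np.asarray(g, dtype=float)
    slab = hp.gamma * 0.5 * hp.lam * np.exp(-hp.lam * np.abs(g))
    if spike_lambda is None:
        return slab
    if not spike_lambda > 0.0:
        raise ValueError("spike_lambda must be > 0")
    spike = (1.0 - hp.gamma) * 0.5 * spike_lambda * np.exp(-spike_lambda * np.abs(g))
    return slab + spike


def conditional_likelihood(g, ctx: ConditionalContext):
    """Normal conditional likelihood N(g; G, sigma2) of one SNP effect."""
    g = np.asarray(g, dtype=float)
    z = (g - ctx.G) / ctx.sigma
    return np.exp(-0.5 * z * z) / (ctx.sigma * np.sqrt(2.0 * np.pi))


def log_de_marginal(ctx: ConditionalContext, lam: float):
    """Log of the DE-slab marginal likelihood of one SNP.

    Integrates the normal conditional likelihood against a unit-mass DE
    prior with rate ``lam``::

        L_DE = int N(g; G, sigma2) * (lam/2) * exp(-lam*|g|) dg

    evaluated in closed form through the normal CDF, entirely on the log
    scale (``log_ndtr`` absorbs the ``exp(lam^2 sigma^2 / 2)`` factor that
    would otherwise overflow).
    """
    if not lam > 0.0:
        raise ValueError("lambda must be > 0")
    G = np.asarray(ctx.G, dtype=float)
    s = ctx.sigma
    s2 = ctx.sigma2
    half = np.log(0.5 * lam) + 0.5 * lam * lam * s2
    t_pos = half - lam * G + log_ndtr((G - lam * s2) / s)
    t_neg = half + lam * G + log_ndtr(-(G + lam * s2) / s)
    return np.logaddexp(t_pos, t_neg)


def de_marginal(ctx: ConditionalContext, lam: float):
    """DE-slab marginal likelihood (may underflow to 0.0 for extreme |G|;
    use :func:`log_de_marginal` in ratios)."""
    return np.exp(log_de_marginal(ctx, lam))


def log_dd_marginal(ctx: ConditionalContext):
    """Log marginal likelihood of the point-mass component: the conditional
    likelihood evaluated at g = 0."""
    G = np.asarray(ctx.G, dtype=float)
    return -0.5 * G * G / ctx.sigma2 - np.log(ctx.sigma) - _LOG_SQRT_2PI


def dd_marginal(ctx: ConditionalContext):
    return np.exp(log_dd_marginal(ctx))


def posterior_prob(
    ctx: ConditionalContext, hp: HyperParams, spike_lambda: float | None = None
):
    """E-step posterior probability that the SNP is in LD with QTL.

    ``gamma_j = gamma*L_DE / (gamma*L_DE + (1-gamma)*L_0)`` where ``L_0`` is
    the Dirac marginal (conditional likelihood at 0) or, in spike mode, the
    marginal under the concentrated DE spike.  Computed with log-sum-exp.
    """
    if hp.gamma == 0.0:
        return np.zeros_like(np.asarray(ctx.G, dtype=float)) + 0.0
    if hp.gamma == 1.0:
        return np.ones_like(np.asarray(ctx.G, dtype=float)) + 0.0
    l_slab = log_de_marginal(ctx, hp.lam)
    if spike_lambda is None:
        l_null = log_dd_marginal(ctx)
    else:
        l_null = log_de_marginal(ctx, spike_lambda)
    log_odds = np.log(hp.gamma) - np.log1p(-hp.gamma) + l_slab - l_null
    out = 1.0 / (1.0 + np.exp(-log_odds))
    return np.clip(out, 1e-300, 1.0)


def conditional_posterior_density(
    g, ctx: ConditionalContext, hp: HyperParams, spike_lambda: float = 1000.0
):
    """Density of one SNP effect given the data and all other effects.

    Uses the spike representation of the Dirac atom (default rate 1000) so
    the posterior is an ordinary density; normalized to integrate to 1.
    """
    g = np.asarray(g, dtype=float)
    num = prior_density(g, hp, spike_lambda) * conditional_likelihood(g, ctx)
    log_norm = logsumexp(
        [
            np.log(hp.gamma) + log_de_marginal(ctx, hp.lam),
            np.log1p(-hp.gamma) + log_de_marginal(ctx, spike_lambda),
        ]
    )
    return num * np.exp(-log_norm)


def _slab_posterior_mean(ctx: ConditionalContext, lam: float) -> float:
    """Mean of the effect under the DE-slab posterior (normalized slab part).

    The slab posterior is a two-piece truncated normal (centres
    ``G -/+ lam*s2`` on the positive/negative half-lines).  Writing the two
    branch log-masses ``t_pos``/``t_neg``, the truncation (Mills-ratio)
    corrections of the branches cancel exactly — both equal
    ``(lam/2) exp(-G^2/2s^2)`` — leaving

        E[g | slab, data] = G + lam*s2 * tanh((t_neg - t_pos) / 2)

    which avoids the catastrophic cancellation of summing the two branch
    means directly when ``lam * s >> |G|``.
    """
    G = float(ctx.G)
    s = ctx.sigma
    s2 = ctx.sigma2
    x_pos = (G - lam * s2) / s
    x_neg = -(G + lam * s2) / s
    t_pos = -lam * G + log_ndtr(x_pos)
    t_neg = lam * G + log_ndtr(x_neg)
    return G + lam * s2 * float(np.tanh(0.5 * (t_neg - t_pos)))


def conditional_posterior_mean(ctx: ConditionalContext, hp: HyperParams) -> float:
    """E(g | data, other effects) under the exact Dirac + DE mixture.

    The atom contributes zero, so the mean is the E-step probability times
    the slab-posterior mean.  This is the per-SNP update of the iterated
    conditional expectation (ICE) algorithm.
    """
    if hp.gamma == 0.0:
        return 0.0
    gj = float(posterior_prob(ctx, hp))
    return gj * _slab_posterior_mean(ctx, hp.lam)
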