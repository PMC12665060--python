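"""Zero-inflated negative binomial (ZINB) distribution.

The ZINB mixes a point mass at zero (dropout probability ``pi``) with a
negative binomial parameterized by mean ``mu`` and dispersion ``theta``:

    P(X = x) = pi * 1{x = 0} + (1 - pi) * NB(x; mu, theta)
    NB(x) = Gamma(x + theta) / (Gamma(theta) x!) *
            (theta / (theta + mu))^theta * (mu / (theta + mu))^x

The mean log-likelihood of this distribution over a count matrix is the
training loss of the autoencoder; the sampler is the generative counterpart
used by the synthetic-data module.

All computation is in log space via log-gamma; the zero mixture term uses
log-sum-exp. For numerical stability inside the loss, dispersion is clamped
to [1e-4, 1e4] and mean to [1e-5, 1e6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

MEAN_CLAMP = (1e-5, 1e6)
DISP_CLAMP = (1e-4, 1e4)

__all__ = ["ZINBParams", "zinb_logpmf", "zinb_negloglik", "zinb_sample"]


@dataclass
class ZINBParams:
    """Per-cell-per-gene ZINB parameters (all matrices cells x genes)."""

    mean: np.ndarray
    dispersion: np.ndarray
    dropout: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.dropout = np.asarray(self.dropout, dtype=float)
        if not (self.mean.shape == self.dispersion.shape == self.dropout.shape):
            raise ValueError("mean, dispersion and dropout must share one shape")
        if np.any(self.mean <= 0):
            raise ValueError("mean must be positive")
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be positive")
        if np.any((self.dropout < 0) | (self.dropout > 1)):
            raise ValueError("dropout must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mean.shape


def _nb_logpmf(x: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    log_theta_mu = np.log(theta + mu)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu)
    )


def zinb_logpmf(x, mean, dispersion, dropout) -> np.ndarray | float:
    """Log-probability of counts under the ZINB distribution.

    Broadcasts over array arguments. Finite whenever ``dropout < 1`` or
    ``x = 0``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mean, dtype=float)
    theta = np.asarray(dispersion, dtype=float)
    pi = np.asarray(dropout, dtype=float)
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("x must be a nonnegative integer")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mean and dispersion must be positive")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("dropout must lie in [0, 1]")

    x, mu, theta, pi = np.broadcast_arrays(x, mu, theta, pi)
    nb = _nb_logpmf(x, mu, theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    # x = 0: log(pi + (1-pi) * NB(0)) via log-sum-exp; x > 0: log(1-pi) + NB.
    zero_term = np.logaddexp(log_pi, log_1mpi + nb)
    out = np.where(x == 0, zero_term, log_1mpi + nb)
    return out if out.ndim else float(out)


def zinb_negloglik(counts, params: ZINBParams) -> float:
    """Mean negative log-likelihood of a count matrix under ZINB parameters.

    This is the autoencoder's training loss.
    """
    x = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if x.shape != params.shape:
        raise ValueError(f"counts shape {x.shape} != params shape {params.shape}")
    mu = np.clip(params.mean, *MEAN_CLAMP)
    theta = np.clip(params.dispersion, *DISP_CLAMP)
    ll = zinb_logpmf(x, mu, theta, params.dropout)
    return float(-np.mean(ll))


def zinb_sample(params: ZINBParams, seed: int) -> np.ndarray:
    """Draw one count matrix from the ZINB distribution.

    Entries are 0 with probability ``dropout``, otherwise a Gamma-Poisson
    draw with the given mean and dispersion. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=params.dispersion, scale=params.mean / params.dispersion)
    counts = rng.poisson(lam)
    dropped = rng.random(params.shape) < params.dropout
    counts[dropped] = 0
    return counts.astype(np.int64)
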