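"""ZINB autoencoder with a one-neuron bottleneck.

The network maps the normalized expression of the Q common-target genes of
each cell through a 64-neuron encoding layer, a single-neuron middle layer,
and a 64-neuron decoding layer; three output heads produce the per-entry
mean, dispersion and dropout of a zero-inflated negative binomial, and the
mean ZINB negative log-likelihood of the raw counts is the training loss.
After training, the middle-layer activation of a cell is its Multi-Target
Integration Score (MTIS): a one-dimensional integrated representation of
the cell's expression over the target gene set.

Normalization (``f_norm``) is size-factor division, log1p, then per-gene
z-scoring, with the statistics stored at fit time and reused at encode
time. Two head parameterizations are provided:

* ``dca`` (default): mean = s_c * exp(.), dispersion = exp(.),
  dropout = sigmoid(.) — the convention of deep count autoencoders.
* ``literal``: the printed equations verbatim, with the exponential dropout
  head read as odds, so dropout = sigmoid of the same logits, and
  mean = s_c * sigmoid(.).

Training is adaptive-moment (Adam) gradient descent on analytically
derived gradients, in mini-batches of 32 with a seeded 10% validation
split and early stopping (patience 15, best-validation weights restored),
from a data-dependent warm start (first principal axis of the normalized
matrix plus per-gene log-mean head biases). Fixed seeds give bit-identical
weights, loss history and scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, digamma
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CellGeneMatrix
from .zinb import DISP_CLAMP, MEAN_CLAMP, ZINBParams

__all__ = [
    "TrainConfig",
    "SizeFactors",
    "MTISEncoder",
    "normalize_counts",
    "forward",
    "decode_heads",
]

_BATCH_SIZE = 32  # the cited count-autoencoder's mini-batch convention
_MIN_CELLS_FOR_VALIDATION = 20


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the published protocol)."""

    epochs: int = 300
    learning_rate: float = 1e-3
    hidden: int = 64
    seed: int = 0
    head_mode: str = "dca"  # {"dca", "literal"}
    loss_threshold: float | None = None
    bottleneck_activation: str = "relu"  # {"relu", "linear"}
    use_bias: bool = True
    validation_fraction: float = 0.1
    patience: int = 15

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.head_mode not in ("dca", "literal"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if self.bottleneck_activation not in ("relu", "linear"):
            raise ValueError(
                f"unknown bottleneck_activation {self.bottleneck_activation!r}"
            )


@dataclass
class SizeFactors:
    """Per-cell library-size factors: total counts over the median total."""

    total: np.ndarray
    median_total: float
    factor: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        if self.median_total <= 0:
            raise ValueError("median_total must be positive")
        # Zero-total cells get the smallest meaningful factor, 1/median.
        self.factor = np.where(self.total > 0, self.total, 1.0) / self.median_total


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_counts(
    cg: CellGeneMatrix | np.ndarray,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    median_total: float | None = None,
):
    """Size-factor + log1p + per-gene z-score normalization.

    When ``center``/``scale``/``median_total`` are given (encode time), the
    stored statistics are applied; otherwise they are estimated and
    returned. Zero-variance genes get scale 1 with a warning.

    Returns ``(normalized, size_factors, norm_stats)`` with ``norm_stats``
    a dict holding ``center`` and ``scale``.
    """
    x = np.asarray(getattr(cg, "counts", cg), dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    total = x.sum(axis=1)
    if np.any(total == 0):
        warnings.warn(
            f"{int((total == 0).sum())} cell(s) with zero total count; "
            "size factor set to 1/median",
            stacklevel=2,
        )
    if median_total is None:
        median_total = float(np.median(total))
        if median_total <= 0:
            warnings.warn("median total count is zero; using 1", stacklevel=2)
            median_total = 1.0
    sf = SizeFactors(total, median_total)
    y = np.log1p(x / sf.factor[:, None])
    if center is None or scale is None:
        center = y.mean(axis=0)
        scale = y.std(axis=0, ddof=1) if y.shape[0] > 1 else np.zeros(y.shape[1])
        zero_var = ~(scale > 1e-12)  # tolerate float residue on constant genes
        if zero_var.any():
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance gene(s); scale set to 1",
                stacklevel=2,
            )
            scale = np.where(zero_var, 1.0, scale)
    normalized = (y - center) / scale
    return normalized, sf, {"center": np.asarray(center), "scale": np.asarray(scale)}


# ---------------------------------------------------------------------------
# Forward pass and output heads
# ---------------------------------------------------------------------------


def _forward_cache(norm: np.ndarray, w: dict[str, np.ndarray], config: TrainConfig):
    z1 = norm @ w["W1"] + w["b1"]
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ w["W2"] + w["b2"]
    m = np.maximum(z2, 0.0) if config.bottleneck_activation == "relu" else z2
    z3 = m @ w["W3"] + w["b3"]
    h2 = np.maximum(z3, 0.0)
    return {"z1": z1, "h1": h1, "z2": z2, "m": m, "z3": z3, "h2": h2}


def forward(norm: np.ndarray, weights: dict[str, np.ndarray], config: TrainConfig):
    """Run the encoder/decoder stack; returns ``(mtis, dc)``.

    ``mtis`` is the middle-layer activation (one value per cell) and ``dc``
    the 64-dimensional decoded representation feeding the output heads.
    """
    norm = np.asarray(norm, dtype=float)
    if norm.shape[1] != weights["W1"].shape[0]:
        raise ValueError(
            f"input has {norm.shape[1]} genes, weights expect {weights['W1'].shape[0]}"
        )
    cache = _forward_cache(norm, weights, config)
    return cache["m"][:, 0].copy(), cache["h2"]


def decode_heads(
    dc: np.ndarray,
    size_factors: SizeFactors | np.ndarray | float,
    weights: dict[str, np.ndarray],
    mode: str = "dca",
) -> ZINBParams:
    """Map the decoded representation to ZINB parameter matrices.

    ``dca``: mean = s_c * exp(W_k head), dispersion = exp(W_r head),
    dropout = sigmoid(W_p head). ``literal``: the printed head equations,
    with the exponential dropout head interpreted as odds
    (odds / (1 + odds) = sigmoid of the same logits) and
    mean = s_c * sigmoid(W_k head). Clamps as in the loss.
    """
    if mode not in ("dca", "literal"):
        raise ValueError(f"unknown head mode {mode!r}")
    s = size_factors.factor if isinstance(size_factors, SizeFactors) else size_factors
    s = np.atleast_1d(np.asarray(s, dtype=float))[:, None]
    zk = dc @ weights["Wk"] + weights["bk"]
    zr = dc @ weights["Wr"] + weights["br"]
    zp = dc @ weights["Wp"] + weights["bp"]
    if mode == "dca":
        mean = s * np.exp(np.clip(zk, np.log(MEAN_CLAMP[0]), np.log(MEAN_CLAMP[1])))
    else:
        mean = s * _sigmoid(zk)
    mean = np.clip(mean, *MEAN_CLAMP)
    dispersion = np.exp(np.clip(zr, np.log(DISP_CLAMP[0]), np.log(DISP_CLAMP[1])))
    dropout = _sigmoid(zp)
    return ZINBParams(mean, dispersion, dropout)


# ---------------------------------------------------------------------------
# Loss and analytic gradients
# ---------------------------------------------------------------------------


def _zinb_loss_and_head_grads(x, s, zk, zr, zp, mode):
    """Mean ZINB negative log-likelihood and its gradients w.r.t. the three
    head pre-activations. Derived by chaining d(-ll)/d{mu,theta,logit}
    through the head transforms; clamped regions get zero gradient."""
    log_mu_lo, log_mu_hi = np.log(MEAN_CLAMP[0]), np.log(MEAN_CLAMP[1])
    log_th_lo, log_th_hi = np.log(DISP_CLAMP[0]), np.log(DISP_CLAMP[1])

    if mode == "dca":
        zk_c = np.clip(zk, log_mu_lo, log_mu_hi)
        mu = s * np.exp(zk_c)
        dmu_dzk = np.where((zk > log_mu_lo) & (zk < log_mu_hi), mu, 0.0)
    else:  # literal: mean = s * sigmoid(zk)
        sig = _sigmoid(zk)
        mu = s * sig
        dmu_dzk = mu * (1.0 - sig)
    in_range = (mu > MEAN_CLAMP[0]) & (mu < MEAN_CLAMP[1])
    mu = np.clip(mu, *MEAN_CLAMP)
    dmu_dzk = np.where(in_range, dmu_dzk, 0.0)

    zr_c = np.clip(zr, log_th_lo, log_th_hi)
    theta = np.exp(zr_c)
    dth_dzr = np.where((zr > log_th_lo) & (zr < log_th_hi), theta, 0.0)

    w = theta + mu
    log_w = np.log(w)
    nb0 = theta * (np.log(theta) - log_w)
    is_zero = x == 0

    # log-likelihood
    nb = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + nb0
        + x * (np.log(mu) - log_w)
    )
    ll = np.where(is_zero, np.logaddexp(zp, nb0) - _softplus(zp), nb - _softplus(zp))

    # gradients of ll w.r.t. mu, theta, zp
    dnb0_dmu = -theta / w
    dnb0_dth = np.log(theta) + 1.0 - log_w - theta / w
    g0 = _sigmoid(nb0 - zp)  # posterior weight of the NB branch at x = 0
    dll_dmu = np.where(is_zero, g0 * dnb0_dmu, x / mu - (x + theta) / w)
    dll_dth = np.where(
        is_zero,
        g0 * dnb0_dth,
        digamma(x + theta) - digamma(theta) + np.log(theta) + 1.0 - log_w
        - (x + theta) / w,
    )
    dll_dzp = np.where(is_zero, _sigmoid(zp - nb0) - _sigmoid(zp), -_sigmoid(zp))

    coef = -1.0 / x.size  # loss = -mean(ll)
    gk = coef * dll_dmu * dmu_dzk
    gr = coef * dll_dth * dth_dzr
    gp = coef * dll_dzp
    return float(-ll.mean()), gk, gr, gp


def _loss_and_grads(x, norm, s, w, config: TrainConfig):
    cache = _forward_cache(norm, w, config)
    h1, m, h2 = cache["h1"], cache["m"], cache["h2"]
    zk = h2 @ w["Wk"] + w["bk"]
    zr = h2 @ w["Wr"] + w["br"]
    zp = h2 @ w["Wp"] + w["bp"]
    loss, gk, gr, gp = _zinb_loss_and_head_grads(
        x, s[:, None], zk, zr, zp, config.head_mode
    )

    grads = {
        "Wk": h2.T @ gk, "bk": gk.sum(axis=0),
        "Wr": h2.T @ gr, "br": gr.sum(axis=0),
        "Wp": h2.T @ gp, "bp": gp.sum(axis=0),
    }
    g_h2 = gk @ w["Wk"].T + gr @ w["Wr"].T + gp @ w["Wp"].T
    g_z3 = g_h2 * (cache["z3"] > 0)
    grads["W3"] = m.T @ g_z3
    grads["b3"] = g_z3.sum(axis=0)
    g_m = g_z3 @ w["W3"].T
    if config.bottleneck_activation == "relu":
        g_m = g_m * (cache["z2"] > 0)
    grads["W2"] = h1.T @ g_m
    grads["b2"] = g_m.sum(axis=0)
    g_h1 = g_m @ w["W2"].T
    g_z1 = g_h1 * (cache["z1"] > 0)
    grads["W1"] = norm.T @ g_z1
    grads["b1"] = g_z1.sum(axis=0)
    return loss, grads


def _init_weights(q: int, hidden: int, rng: np.random.Generator):
    def uniform(fan_in, shape):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return {
        "W1": uniform(q, (q, hidden)), "b1": np.zeros(hidden),
        "W2": uniform(hidden, (hidden, 1)), "b2": np.zeros(1),
        "W3": uniform(1, (1, hidden)), "b3": np.zeros(hidden),
        "Wk": uniform(hidden, (hidden, q)), "bk": np.zeros(q),
        "Wr": uniform(hidden, (hidden, q)), "br": np.zeros(q),
        "Wp": uniform(hidden, (hidden, q)), "bp": np.zeros(q),
    }


def _warm_start(w, x, norm, s, config: TrainConfig):
    """Data-dependent warm start of the seeded random initialization.

    A randomly initialized one-neuron bottleneck tends to converge to a
    "mean-only" saddle under a short training budget: the output-head
    biases absorb the per-gene means while the latent stays constant. Two
    standard measures avoid it: the encoder is warm-started along the first
    principal axis of the normalized matrix (routed through two ReLU units
    carrying its positive and negative parts, so the bottleneck starts
    informative and strictly positive), and the mean-head bias starts at
    the per-gene log mean so reconstructing means is free from step one.
    Deterministic given the data and seed.
    """
    if w["W1"].shape[1] < 2:
        return w
    # first right singular vector of the (already centered) normalized matrix
    _, _, vt = np.linalg.svd(norm, full_matrices=False)
    v1 = vt[0]
    v1 = v1 * np.sign(v1[np.argmax(np.abs(v1))] or 1.0)
    t = norm @ v1
    g = 1.0 / (t.std() if t.std() > 0 else 1.0)
    w["W1"][:, 0] = v1 * g
    w["W1"][:, 1] = -v1 * g
    w["W2"][:, 0] *= 0.1  # keep the random carriers quiet initially
    w["W2"][0, 0] = 1.0
    w["W2"][1, 0] = -1.0
    if not config.use_bias:
        return w
    if config.bottleneck_activation == "relu":
        w["b2"][0] = -(t * g).min() + 0.1  # bottleneck positive for every cell
    if config.head_mode != "dca":
        return w
    # Decoder warm start: route the latent and its reflection through the
    # first two decoding units, then set the mean head to the per-gene
    # log-linear regression of scaled counts on the initial latent, so the
    # model starts as a working one-factor log-linear model.
    m0 = t * g + w["b2"][0] if config.bottleneck_activation == "relu" else t * g
    m0 = np.maximum(m0, 0.0) if config.bottleneck_activation == "relu" else m0
    w["W3"][0, :] *= 0.1
    w["b3"][:2] = 0.0
    w["W3"][0, 0] = 1.0
    w["W3"][0, 1] = -1.0
    w["b3"][1] = m0.max() + 0.1  # second unit carries the reflected latent
    target = np.log(x / s[:, None] + 0.5)  # pseudo-count log of scaled counts
    design = np.column_stack([np.ones_like(m0), m0])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    beta = np.clip(coef[1], -3.0, 3.0)
    w["Wk"][:, :] *= 0.1
    w["Wk"][0, :] = beta
    w["Wk"][1, :] = 0.0
    w["bk"][:] = np.clip(coef[0], np.log(1e-4), np.log(1e5))
    return w


class _Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, keys, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}

    def step(self, w, grads, skip=()):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            if k in skip:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            w[k] = w[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class MTISEncoder(BaseEstimator, TransformerMixin):
    """ZINB autoencoder producing a one-dimensional per-cell latent score.

    Parameters
    ----------
    hidden : int, default=64
        Width of the encoding and decoding layers.
    epochs : int, default=300
        Training epochs.
    learning_rate : float, default=1e-3
        Adam learning rate.
    head_mode : {"dca", "literal"}, default="dca"
        Output-head parameterization (see module docstring).
    bottleneck_activation : {"relu", "linear"}, default="relu"
        Activation of the one-neuron middle layer.
    use_bias : bool, default=True
        Include bias terms; disabling them reproduces the pure
        matrix-product formulation exactly.
    loss_threshold : float or None, default=None
        Stop early once the epoch loss falls below this value.
    random_state : int, default=0
        Seed for weight initialization (and mini-batch shuffling).

    Attributes
    ----------
    weights_ : dict of ndarray
        Trained weight matrices and biases.
    loss_history_ : ndarray
        Mean ZINB negative log-likelihood per epoch run.
    norm_center_, norm_scale_ : ndarray
        Per-gene normalization statistics frozen at fit time.
    median_total_ : float
        Median library size of the training cells (size-factor denominator).
    size_factors_ : SizeFactors
        Size factors of the training cells.
    gene_symbols_ : list of str or None
        Training gene set when fitted on a :class:`CellGeneMatrix`.
    """

    def __init__(
        self,
        hidden: int = 64,
        epochs: int = 300,
        learning_rate: float = 1e-3,
        head_mode: str = "dca",
        bottleneck_activation: str = "relu",
        use_bias: bool = True,
        loss_threshold: float | None = None,
        random_state: int = 0,
        validation_fraction: float = 0.1,
        patience: int = 15,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.head_mode = head_mode
        self.bottleneck_activation = bottleneck_activation
        self.use_bias = use_bias
        self.loss_threshold = loss_threshold
        self.random_state = random_state
        self.validation_fraction = validation_fraction
        self.patience = patience

    # -- helpers ----------------------------------------------------------

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            hidden=self.hidden,
            seed=self.random_state,
            head_mode=self.head_mode,
            loss_threshold=self.loss_threshold,
            bottleneck_activation=self.bottleneck_activation,
            use_bias=self.use_bias,
            validation_fraction=self.validation_fraction,
            patience=self.patience,
        )

    @staticmethod
    def _as_counts(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
        if isinstance(X, CellGeneMatrix):
            return X.counts.astype(float), list(X.gene_symbols), list(X.cell_ids)
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be a 2-D count matrix (cells x genes)")
        if np.any(x < 0) or np.any(x != np.round(x)):
            raise ValueError("X must hold nonnegative integer counts")
        return x, None, None

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a cells-x-genes count matrix (array or CellGeneMatrix)."""
        config = self._config()
        x, genes, _ = self._as_counts(X)
        n, q = x.shape
        norm, sf, stats = normalize_counts(x)
        rng = np.random.default_rng(config.seed)
        w = _init_weights(q, config.hidden, rng)
        w = _warm_start(w, x, norm, sf.factor, config)
        skip = () if config.use_bias else tuple(k for k in w if k.startswith("b"))
        opt = _Adam(w.keys(), config.learning_rate)
        losses: list[float] = []
        val_losses: list[float] = []

        # seeded validation split for early stopping (skipped on tiny data)
        use_val = (
            config.validation_fraction > 0
            and config.patience > 0
            and n >= _MIN_CELLS_FOR_VALIDATION
        )
        split_rng = np.random.default_rng([config.seed, 1717])
        perm = split_rng.permutation(n)
        n_val = int(round(config.validation_fraction * n)) if use_val else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        best_val, best_w, bad_epochs = np.inf, None, 0

        for _ in range(config.epochs):
            order = rng.permutation(tr_idx.size)
            batch_losses = []
            for start in range(0, tr_idx.size, _BATCH_SIZE):
                idx = tr_idx[order[start : start + _BATCH_SIZE]]
                loss_b, grads = _loss_and_grads(
                    x[idx], norm[idx], sf.factor[idx], w, config
                )
                opt.step(w, grads, skip=skip)
                batch_losses.append(loss_b)
            loss = float(np.mean(batch_losses))
            if not np.isfinite(loss):
                raise RuntimeError(
                    "non-finite training loss; reduce learning_rate "
                    f"(lr={config.learning_rate}, clamps mean={MEAN_CLAMP}, "
                    f"dispersion={DISP_CLAMP})"
                )
            losses.append(loss)
            if config.loss_threshold is not None and loss < config.loss_threshold:
                break
            if n_val:
                val_loss, _ = _loss_and_grads(
                    x[val_idx], norm[val_idx], sf.factor[val_idx], w, config
                )
                val_losses.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_w = {k: v.copy() for k, v in w.items()}
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= config.patience:
                        break
        if best_w is not None:
            w = best_w  # restore the best-validation weights
        self.weights_ = w
        self.val_loss_history_ = np.asarray(val_losses)
        self.loss_history_ = np.asarray(losses)
        self.norm_center_ = stats["center"]
        self.norm_scale_ = stats["scale"]
        self.median_total_ = sf.median_total
        self.size_factors_ = sf
        self.gene_symbols_ = genes
        self.n_features_in_ = q
        return self

    def _check_genes(self, genes: list[str] | None) -> None:
        if genes is None or self.gene_symbols_ is None:
            return
        if genes != self.gene_symbols_:
            missing = sorted(set(self.gene_symbols_) - set(genes))
            extra = sorted(set(genes) - set(self.gene_symbols_))
            raise ValueError(
                "gene set differs from the training gene set "
                f"(missing={missing}, extra={extra}, order must match)"
            )

    def transform(self, X) -> np.ndarray:
        """Per-cell MTIS as an (n_cells, 1) array."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("MTISEncoder is not fitted")
        x, genes, _ = self._as_counts(X)
        self._check_genes(genes)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {x.shape[1]} genes, model expects {self.n_features_in_}"
            )
        norm, _, _ = normalize_counts(
            x, self.norm_center_, self.norm_scale_, self.median_total_
        )
        mtis, _ = forward(norm, self.weights_, self._config())
        return mtis[:, None]

    def mtis_table(self, X: CellGeneMatrix) -> pd.DataFrame:
        """MTIS as a two-column table (cell_id, mtis)."""
        mtis = self.transform(X)[:, 0]
        cell_ids = (
            X.cell_ids
            if isinstance(X, CellGeneMatrix)
            else [str(i) for i in range(len(mtis))]
        )
        return pd.DataFrame({"cell_id": cell_ids, "mtis": mtis})

    def decode(self, X) -> ZINBParams:
        """ZINB parameter matrices for the cells of ``X``."""
        x, genes, _ = self._as_counts(X)
        self._check_genes(genes)
        norm, sf, _ = normalize_counts(
            x, self.norm_center_, self.norm_scale_, self.median_total_
        )
        _, dc = forward(norm, self.weights_, self._config())
        return decode_heads(dc, sf, self.weights_, self.head_mode)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write a JSON text checkpoint (weights, normalization, config)."""
        path = Path(path)
        payload = {
            "config": asdict(self._config()),
            "weights": {k: v.tolist() for k, v in self.weights_.items()},
            "norm_center": self.norm_center_.tolist(),
            "norm_scale": self.norm_scale_.tolist(),
            "median_total": self.median_total_,
            "loss_history": self.loss_history_.tolist(),
            "gene_symbols": self.gene_symbols_,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MTISEncoder":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        est = cls(
            hidden=cfg["hidden"],
            epochs=cfg["epochs"],
            learning_rate=cfg["learning_rate"],
            head_mode=cfg["head_mode"],
            bottleneck_activation=cfg["bottleneck_activation"],
            use_bias=cfg["use_bias"],
            loss_threshold=cfg["loss_threshold"],
            random_state=cfg["seed"],
            validation_fraction=cfg.get("validation_fraction", 0.1),
            patience=cfg.get("patience", 15),
        )
        est.weights_ = {k: np.asarray(v) for k, v in payload["weights"].items()}
        est.norm_center_ = np.asarray(payload["norm_center"])
        est.norm_scale_ = np.asarray(payload["norm_scale"])
        est.median_total_ = payload["median_total"]
        est.loss_history_ = np.asarray(payload["loss_history"])
        est.gene_symbols_ = payload["gene_symbols"]
        est.n_features_in_ = len(est.norm_center_)
        return est
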