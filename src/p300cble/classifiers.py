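"""Three P300 classifiers behind one score contract.

Every model maps a feature vector x to a scalar score ``w . f(x) + b`` whose
magnitude expresses how P300-like the trial is:

* least squares (LS): ordinary regression of the +-1 class labels on the
  features, intercept included;
* stepwise linear discriminant analysis (SWLDA): forward/backward stepwise
  regression by partial-F p-values (enter p < 0.05, remove p > 0.10, at most
  60 features), final weights an ordinary LS fit on the selected features;
* sparse autoencoder (SAE): a two-layer sigmoid autoencoder trained with L2
  weight decay and a Kullback-Leibler sparsity penalty; the decoder is then
  discarded and a two-class softmax on the hidden code supplies the score
  (the softmax probability of the target class).

Feature standardization (z-scoring with training statistics) is part of
every model, so ``score`` accepts raw feature matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .preprocess import FeatureMatrix, Standardizer

__all__ = [
    "LinearModel",
    "SaeModel",
    "fit_ls",
    "fit_swlda",
    "fit_sae",
    "score",
    "sae_cost_grad",
    "kl_sparsity",
]

logger = logging.getLogger(__name__)


@dataclass
class LinearModel:
    """Linear scorer ``w . x_std + b`` (LS or SWLDA)."""

    weights: np.ndarray
    bias: float
    standardizer: Standardizer
    method: str = "ls"
    #: indices of features with (potentially) non-zero weight
    selected_features: np.ndarray | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        return Xs @ self.weights + self.bias


@dataclass
class SaeModel:
    """Sparse-autoencoder encoder plus a two-class softmax head.

    ``score`` is the softmax probability of the target class, in (0, 1).
    Inputs are z-scored then min-max rescaled to [0, 1] (sigmoid decoder
    range) using training statistics stored with the model.
    """

    encoder_weights: np.ndarray  # L x D
    encoder_bias: np.ndarray  # L
    decoder_weights: np.ndarray  # D x L (kept for reconstruction diagnostics)
    decoder_bias: np.ndarray  # D
    softmax_weights: np.ndarray  # 2 x (L + 1), class 0 = non-target, 1 = target
    standardizer: Standardizer
    minmax_lo: np.ndarray
    minmax_range: np.ndarray
    hidden_units: int
    hyperparams: dict = field(default_factory=dict)
    training_trace: list[float] = field(default_factory=list)
    method: str = "sae"

    def _rescale(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        return np.clip((Xs - self.minmax_lo) / self.minmax_range, 0.0, 1.0)

    def encode(self, X: np.ndarray) -> np.ndarray:
        X01 = self._rescale(X)
        return _sigmoid(X01 @ self.encoder_weights.T + self.encoder_bias)

    def reconstruct(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(input on [0,1] scale, its reconstruction) for diagnostics."""
        X01 = self._rescale(X)
        U = _sigmoid(X01 @ self.encoder_weights.T + self.encoder_bias)
        return X01, _sigmoid(U @ self.decoder_weights.T + self.decoder_bias)

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = self.encode(X)
        Z1 = np.column_stack([Z, np.ones(len(Z))])
        logits = Z1 @ self.softmax_weights.T  # N x 2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e[:, 1] / e.sum(axis=1)


def score(model, X: np.ndarray) -> np.ndarray:
    """Per-trial scores; higher means more P300-like. Deterministic."""
    return model.score(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# least squares


def fit_ls(fm: FeatureMatrix) -> LinearModel:
    """Regress the +-1 labels on the (standardized, intercept-augmented)
    features via the normal equations, solved by factorization.

    A rank-deficient design falls back to the minimum-norm solution (which
    is what the factorization-based solver returns) with a warning.
    """
    std = Standardizer.fit(fm.X)
    Xs = std.transform(fm.X)
    n, d = Xs.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    Xa = np.column_stack([Xs, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(Xa, fm.y, rcond=None)
    if rank < min(Xa.shape):
        logger.warning("rank-deficient design (rank %d < %d); minimum-norm solution", rank, d + 1)
    return LinearModel(
        weights=coef[:-1],
        bias=float(coef[-1]),
        standardizer=std,
        method="ls",
        selected_features=np.arange(d),
    )


# ---------------------------------------------------------------------------
# stepwise LDA (stepwise regression of +-1 labels, partial-F entry/removal)


def fit_swlda(
    fm: FeatureMatrix,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_features: int = 60,
) -> LinearModel:
    """Forward/backward stepwise regression on the +-1 labels.

    Forward step: among excluded features, the candidate whose addition
    yields the smallest partial-F p-value enters if p < ``p_enter`` (ties to
    the lowest column index).  Backward step: any included feature whose
    coefficient p-value exceeds ``p_remove`` leaves (largest p first).  The
    loop stops when neither step changes the model or ``max_features`` is
    reached; final weights are an ordinary LS fit on the selected features.
    """
    std = Standardizer.fit(fm.X)
    X = std.transform(fm.X)
    y = fm.y.astype(float)
    n, d = X.shape
    if (fm.y > 0).sum() < 2 or (fm.y < 0).sum() < 2:
        raise ValueError("need at least 2 trials per class")

    col_ssq = (X**2).sum(axis=0)
    selected: list[int] = []
    # Q: orthonormal basis of [1, X[:, selected]]
    Q = np.ones((n, 1)) / np.sqrt(n)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)

    def candidate_pvalues() -> np.ndarray:
        """Partial-F p-value of adding each excluded column, vectorized."""
        C = X - Q @ (Q.T @ X)  # residual columns against current basis
        ssq = (C**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            reduction = (C.T @ r) ** 2 / ssq
        pvals = np.ones(d)
        dof = n - (len(selected) + 2)  # intercept + selected + candidate
        if dof <= 0:
            return pvals
        degenerate = ssq <= 1e-10 * np.maximum(col_ssq, 1e-300)
        new_rss = np.maximum(rss - reduction, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = reduction / (new_rss / dof)
        F = np.where(np.isfinite(F), F, np.inf)
        pv = sps.f.sf(F, 1, dof)
        pvals = np.where(degenerate, 1.0, pv)
        pvals[selected] = np.inf  # already in
        return pvals

    def coef_pvalues(sel: list[int]) -> np.ndarray:
        """Two-sided t-test p-values of the selected coefficients."""
        Xa = np.column_stack([np.ones(n), X[:, sel]])
        coef, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
        resid = y - Xa @ coef
        dof = n - Xa.shape[1]
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(Xa.T @ Xa)
        se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
        t = coef / se
        return 2 * sps.t.sf(np.abs(t), dof)[1:]  # drop intercept

    def rebuild_basis() -> None:
        nonlocal Q, r, rss
        Xa = np.column_stack([np.ones(n), X[:, selected]])
        Q, _ = np.linalg.qr(Xa)
        r = y - Q @ (Q.T @ y)
        rss = float(r @ r)

    changed = True
    while changed and len(selected) < max_features:
        changed = False
        # forward
        pvals = candidate_pvalues()
        j = int(np.argmin(pvals))  # argmin takes the lowest index on ties
        if pvals[j] < p_enter:
            selected.append(j)
            rebuild_basis()
            changed = True
            if not len(selected) < max_features:
                pass
        elif not selected:
            raise RuntimeError(
                "empty model: no feature reaches the entry threshold "
                f"(min p = {pvals.min():.3g} >= {p_enter})"
            )
        # backward
        while len(selected) > 1:
            pv = coef_pvalues(selected)
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                removed = selected.pop(worst)
                logger.debug("swlda: removed feature %d (p=%.3g)", removed, pv[worst])
                rebuild_basis()
                changed = True
            else:
                break

    sel = sorted(selected)
    Xa = np.column_stack([np.ones(n), X[:, sel]])
    coef, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
    weights = np.zeros(d)
    weights[sel] = coef[1:]
    return LinearModel(
        weights=weights,
        bias=float(coef[0]),
        standardizer=std,
        method="swlda",
        selected_features=np.asarray(sel, dtype=int),
    )


# ---------------------------------------------------------------------------
# sparse autoencoder


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || rho_hat) for Bernoulli activations."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    )


def _unpack(theta: np.ndarray, d: int, hidden: int):
    i = 0
    W1 = theta[i : i + hidden * d].reshape(hidden, d); i += hidden * d
    b1 = theta[i : i + hidden]; i += hidden
    W2 = theta[i : i + d * hidden].reshape(d, hidden); i += d * hidden
    b2 = theta[i : i + d]
    return W1, b1, W2, b2


def sae_cost_grad(
    theta: np.ndarray,
    X01: np.ndarray,
    hidden: int,
    lam: float,
    beta: float,
    rho: float,
) -> tuple[float, np.ndarray]:
    """Sparse-autoencoder cost and its analytic gradient.

    Cost = (1/N) sum of squared reconstruction errors over all N trials and
    D inputs + lam * (sum of squared encoder and decoder weights, biases
    excluded) + beta * sum_i KL(rho || rho_hat_i), where rho_hat_i is the
    mean sigmoid activation of hidden unit i over the training set.
    """
    n, d = X01.shape
    W1, b1, W2, b2 = _unpack(theta, d, hidden)

    U = _sigmoid(X01 @ W1.T + b1)  # N x L
    Xhat = _sigmoid(U @ W2.T + b2)  # N x D

    rho_hat = np.clip(U.mean(axis=0), 1e-10, 1 - 1e-10)
    kl = kl_sparsity(rho, rho_hat)
    err = Xhat - X01
    cost = float((err**2).sum()) / n + lam * (float((W1**2).sum()) + float((W2**2).sum())) + beta * kl

    delta2 = (2.0 / n) * err * Xhat * (1 - Xhat)  # N x D
    gW2 = delta2.T @ U + 2 * lam * W2
    gb2 = delta2.sum(axis=0)
    sparsity_grad = (beta / n) * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat))  # per unit
    delta1 = (delta2 @ W2 + sparsity_grad[None, :]) * U * (1 - U)  # N x L
    gW1 = delta1.T @ X01 + 2 * lam * W1
    gb1 = delta1.sum(axis=0)

    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    if not np.isfinite(cost) or not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite sparse-autoencoder cost or gradient")
    return cost, grad


def _softmax_fit(Z: np.ndarray, y: np.ndarray, ridge: float = 1e-4) -> np.ndarray:
    """Two-class softmax by cross-entropy; returns 2 x (L+1) weights."""
    n, L = Z.shape
    Z1 = np.column_stack([Z, np.ones(n)])
    t = (y > 0).astype(float)  # 1 = target

    def f(w):
        # one free logit (class 1 minus class 0) is enough for two classes
        a = Z1 @ w
        # log(1+e^a) computed stably
        ce = np.mean(np.logaddexp(0.0, a) - t * a)
        p = _sigmoid(a)
        g = Z1.T @ (p - t) / n + ridge * w
        return ce + 0.5 * ridge * float(w @ w), g

    res = optimize.minimize(f, np.zeros(L + 1), jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    w = res.x
    # express as two class weight vectors (class 0 fixed at zero logit)
    return np.vstack([np.zeros_like(w), w])


def fit_sae(
    fm: FeatureMatrix,
    hidden: int = 200,
    lam: float = 0.004,
    beta: float = 4.0,
    rho: float = 0.05,
    max_iter: int = 400,
    seed: int = 0,
    dtype: type = np.float64,
) -> SaeModel:
    """Train the sparse autoencoder, then the softmax head on its code.

    The optimizer is deterministic L-BFGS from a seeded uniform
    initialization; the cost at each accepted iterate is recorded in
    ``training_trace``.  The decoder is kept only for diagnostics; scoring
    uses encoder + softmax.
    """
    std = Standardizer.fit(fm.X)
    Xs = std.transform(fm.X)
    lo = Xs.min(axis=0)
    rng_span = Xs.max(axis=0) - lo
    rng_span = np.where(rng_span > 0, rng_span, 1.0)
    X01 = ((Xs - lo) / rng_span).astype(dtype)  # float32 halves training time
    n, d = X01.shape

    rng = np.random.default_rng(seed)
    r1 = np.sqrt(6.0 / (d + hidden))
    theta0 = np.concatenate([
        rng.uniform(-r1, r1, hidden * d),
        np.zeros(hidden),
        rng.uniform(-r1, r1, d * hidden),
        np.zeros(d),
    ])

    trace: list[float] = []
    last_cost = [np.inf]

    def fun(theta):
        c, g = sae_cost_grad(theta.astype(dtype), X01, hidden, lam, beta, rho)
        last_cost[0] = c
        return c, g.astype(np.float64)

    def cb(_theta):
        # the last line-search evaluation is the accepted iterate
        trace.append(last_cost[0])

    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxcor": 10}, callback=cb,
    )
    W1, b1, W2, b2 = _unpack(res.x, d, hidden)

    U = _sigmoid(X01 @ W1.T + b1)
    softmax_w = _softmax_fit(U, fm.y)

    return SaeModel(
        encoder_weights=W1,
        encoder_bias=b1,
        decoder_weights=W2,
        decoder_bias=b2,
        softmax_weights=softmax_w,
        standardizer=std,
        minmax_lo=lo,
        minmax_range=rng_span,
        hidden_units=hidden,
        hyperparams={"lambda": lam, "beta": beta, "rho": rho,
                     "max_iter": max_iter, "seed": seed,
                     "decoder_transfer": "sigmoid"},
        training_trace=trace,
    )
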