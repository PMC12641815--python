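"""t-distributed stochastic neighbor embedding, implemented from scratch.

The embedding minimizes the Kullback–Leibler divergence

    L = sum_ij p_ij log(p_ij / q_ij)

between a high-dimensional affinity distribution P and a low-dimensional
Student-t affinity distribution Q.  Conditional affinities use per-point
Gaussian bandwidths sigma_i calibrated by binary search so that the Shannon
entropy of each conditional row matches log2(perplexity); the joint P is the
symmetrized average p_ij = (p_{j|i} + p_{i|j}) / (2n).  Q uses the heavy-
tailed kernel (1 + ||y_i - y_j||^2)^{-1} normalized over all ordered pairs.
Optimization is momentum gradient descent on the analytic gradient

    dL/dy_i = 4 sum_j (p_ij - q_ij) (y_i - y_j) (1 + ||y_i - y_j||^2)^{-1}.

Everything is dense (no Barnes–Hut), sized for library-scale inputs of a
few thousand rows, and exactly testable against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "TSNEConfig",
    "AffinityModel",
    "EmbeddingResult",
    "conditional_affinities",
    "symmetrize",
    "low_dim_affinities",
    "kl_loss",
    "gradient",
    "fit_tsne",
]

_Q_FLOOR = 1e-12


@dataclass
class TSNEConfig:
    perplexity: float = 30.0
    initial_dims: int = 30  # PCA pre-reduction target
    out_dims: int = 2
    n_iter: int = 1000
    learning_rate: float = 200.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration: float = 1.0  # >1 enables; off by default so the
    early_exaggeration_iters: int = 0  # loss trace is monotone-comparable
    init_mode: str = "gaussian"  # or "pca": deterministic, keeps global order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for a in (self.momentum_early, self.momentum_late):
            if not 0.0 <= a < 1.0:
                raise ValueError("momentum must be in [0, 1)")


@dataclass
class AffinityModel:
    P: np.ndarray  # n×n symmetric joint affinities, sum 1
    sigmas: np.ndarray  # per-point Gaussian bandwidths
    target_perplexity: float


@dataclass
class EmbeddingResult:
    Y: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def _entropy_bits(p: np.ndarray) -> float:
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def conditional_affinities(
    X: np.ndarray, perplexity: float, tol: float = 1e-4, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized Gaussian conditionals with perplexity-matched bandwidths.

    For each point i a binary search on the precision beta_i = 1/(2 sigma_i^2)
    drives 2^H(p_{.|i}) to ``perplexity`` within ``tol``.  Returns the n×n
    conditional matrix (rows sum to 1, zero diagonal) and the sigmas.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if perplexity >= n - 1:
        raise ValueError(f"perplexity {perplexity} must be < n - 1 = {n - 1}")
    D2 = squareform(pdist(X, "sqeuclidean"))
    target_bits = np.log2(perplexity)
    P = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        d2 = np.delete(D2[i], i)
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        for _ in range(max_iter):
            w = np.exp(-d2 * beta)
            total = w.sum()
            if total <= 0:  # beta too large for float range
                beta_hi = beta
                beta = (beta_lo + beta_hi) / 2
                continue
            p = w / total
            bits = _entropy_bits(p)
            if abs(2.0**bits - perplexity) < tol:
                break
            if bits > target_bits:  # entropy too high -> sharpen
                beta_lo = beta
                beta = beta * 2 if np.isinf(beta_hi) else (beta_lo + beta_hi) / 2
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0 else (beta_lo + beta_hi) / 2
        else:
            w = np.exp(-d2 * beta)
            total = w.sum()
            if total > 0:
                p = w / total
            else:
                # beta -> inf limit (entropy floor above target): all mass
                # on the nearest neighbor(s), split evenly
                nearest = (d2 == d2.min()).astype(float)
                p = nearest / nearest.sum()
        row = np.zeros(n)
        row[np.arange(n) != i] = p
        P[i] = row
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return P, sigmas


def symmetrize(P_conditional: np.ndarray, n: int | None = None) -> AffinityModel:
    """Joint affinities p_ij = (p_{j|i} + p_{i|j}) / (2n)."""
    Pc = np.asarray(P_conditional, dtype=float)
    if n is None:
        n = Pc.shape[0]
    P = (Pc + Pc.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    return AffinityModel(P=P, sigmas=np.array([]), target_perplexity=float("nan"))


def low_dim_affinities(Y: np.ndarray) -> np.ndarray:
    """Student-t joint affinities of the map, normalized over ordered pairs.

    Entries are floored at 1e-12 after normalization so the KL loss stays
    finite when a pair drifts far apart.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in map coordinates")
    num = 1.0 / (1.0 + squareform(pdist(Y, "sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return np.maximum(Q, _Q_FLOOR) * (num > 0)


def kl_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL divergence sum_ij p_ij log(p_ij / q_ij); zero-p terms contribute 0."""
    mask = P > 0
    return float((P[mask] * np.log(P[mask] / Q[mask])).sum())


def gradient(P: np.ndarray, Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic dL/dY; rows sum to zero (translation invariance)."""
    Y = np.asarray(Y, dtype=float)
    num = 1.0 / (1.0 + squareform(pdist(Y, "sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    PQ = (P - Q) * num
    return 4.0 * (np.diag(PQ.sum(axis=1)) - PQ) @ Y


def fit_tsne(
    X: np.ndarray,
    config: TSNEConfig | None = None,
    init: np.ndarray | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray, float], None] | None = None,
) -> EmbeddingResult:
    """Run the full embedding: PCA pre-reduction, affinities, momentum descent.

    ``init`` overrides the seeded small-variance Gaussian initialization
    (used e.g. for permutation-equivariance checks).  ``callback(t, Y, Q,
    loss)`` is invoked every iteration after the update.
    """
    config = config or TSNEConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < config.out_dims + 1:
        raise ValueError("need more rows than output dimensions")

    if X.shape[1] > config.initial_dims:
        X = PCA(
            n_components=config.initial_dims, random_state=config.seed
        ).fit_transform(X)

    Pc, _ = conditional_affinities(X, config.perplexity)
    P = symmetrize(Pc).P
    P_run = P * config.early_exaggeration if config.early_exaggeration > 1 else P

    rng = np.random.default_rng(config.seed)
    if init is not None:
        Y = np.asarray(init, dtype=float).copy()
    elif config.init_mode == "pca":
        Y = PCA(n_components=config.out_dims, random_state=config.seed).fit_transform(X)
        Y = Y / Y[:, 0].std() * 1e-2  # small-variance start, PC1 scale preserved
    else:
        Y = rng.normal(0.0, 1e-2, (n, config.out_dims))
    velocity = np.zeros_like(Y)
    trace: list[float] = []
    for t in range(config.n_iter):
        if config.early_exaggeration > 1 and t == config.early_exaggeration_iters:
            P_run = P
        Q = low_dim_affinities(Y)
        loss = kl_loss(P, Q)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at iteration {t}")
        trace.append(loss)
        grad = gradient(P_run, Q, Y)
        alpha = (
            config.momentum_early
            if t < config.momentum_switch_iter
            else config.momentum_late
        )
        velocity = alpha * velocity - config.learning_rate * grad
        Y = Y + velocity
        Y = Y - Y.mean(axis=0)
        if callback is not None:
            callback(t, Y, Q, loss)
    return EmbeddingResult(Y=Y, loss_trace=trace, iterations_run=config.n_iter)
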