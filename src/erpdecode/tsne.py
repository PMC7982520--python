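"""From-scratch t-SNE (t-distributed stochastic neighbor embedding).

High-dimensional similarities are Gaussian conditional probabilities

    p(j|i) = exp(-||D_i - D_j||^2 / 2 sigma_i^2) / sum_{k!=i} exp(-||D_i - D_k||^2 / 2 sigma_i^2)

with per-point bandwidths sigma_i calibrated by bisection so that every
row's Shannon perplexity 2^H(P_i) matches a common target.  The default
cost is the canonical symmetric formulation: joint probabilities
p_ij = (p(j|i) + p(i|j)) / 2n against joint-normalized Student-t
similarities q_ij ~ (1 + ||d_i - d_j||^2)^-1, minimized by momentum
gradient descent on the Kullback-Leibler divergence

    C = sum_ij p_ij log(p_ij / q_ij),
    dC/dd_i = 4 sum_j (p_ij - q_ij)(d_i - d_j)(1 + ||d_i - d_j||^2)^-1.

A literal per-point ("conditional") cost variant - row-normalized Student-t
similarities with the exact gradient of sum_i KL(P_i || Q_i) - is available
behind ``variant="conditional"``.  Either way the gradient is the exact
derivative of the implemented cost (verified against finite differences in
the test suite).

The optimizer is the reference t-SNE recipe: small Gaussian initialization,
early exaggeration, momentum switching, and per-parameter adaptive gains.
All O(n^2) work runs in preallocated buffers so large inputs (tens of
thousands of datapoints on one core) stay tractable; pass
``dtype=np.float32`` for the big runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatapointMatrix",
    "AffinityMatrix",
    "Embedding",
    "conditional_affinities",
    "symmetrize",
    "low_dim_affinities",
    "kl_cost",
    "kl_gradient",
    "run_tsne",
]

_Q_FLOOR = 1e-12

try:  # optional single-pass kernels for large inputs
    import numba as _numba
except ImportError:  # pragma: no cover - numba is available in practice
    _numba = None

#: problem size above which the fused pairwise kernels take over
_FUSED_MIN_N = 1500

if _numba is not None:

    @_numba.njit(fastmath=True, nogil=True, cache=False)
    def _fused_joint_grad(Y, P, grad):  # pragma: no cover - exercised via run_tsne
        """Gradient of the joint-variant KL cost, without materializing Q.

        Two passes over the (i, j) pairs: one accumulates the kernel
        normalizer s, the second accumulates the per-point gradient
        4 (p_ij - q_ij) w_ij (y_i - y_j) directly.  Returns s.
        """
        n, d = Y.shape
        s = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d2 = 0.0
                for k in range(d):
                    diff = Y[i, k] - Y[j, k]
                    d2 += diff * diff
                s += 2.0 / (1.0 + d2)
        inv_s = 1.0 / s
        for i in range(n):
            for k in range(d):
                grad[i, k] = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d2 = 0.0
                for k in range(d):
                    diff = Y[i, k] - Y[j, k]
                    d2 += diff * diff
                w = 1.0 / (1.0 + d2)
                c = 4.0 * (P[i, j] - w * inv_s) * w
                for k in range(d):
                    g = c * (Y[i, k] - Y[j, k])
                    grad[i, k] += g
                    grad[j, k] -= g
        return s

    @_numba.njit(fastmath=True, nogil=True, cache=False)
    def _fused_joint_plogq(Y, P, floor):  # pragma: no cover - exercised via run_tsne
        """sum_ij p_ij log(max(q_ij, floor)) for the joint-variant cost."""
        n, d = Y.shape
        s = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d2 = 0.0
                for k in range(d):
                    diff = Y[i, k] - Y[j, k]
                    d2 += diff * diff
                s += 2.0 / (1.0 + d2)
        inv_s = 1.0 / s
        acc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d2 = 0.0
                for k in range(d):
                    diff = Y[i, k] - Y[j, k]
                    d2 += diff * diff
                q = inv_s / (1.0 + d2)
                if q < floor:
                    q = floor
                acc += 2.0 * P[i, j] * np.log(q)
        return acc


@dataclass
class DatapointMatrix:
    """n x m matrix of datapoints, one row per (trial, channel) time series."""

    X: np.ndarray
    row_index: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (datapoints x samples)")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 datapoints")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.row_index is not None and len(self.row_index) != self.X.shape[0]:
            raise ValueError("row_index length must equal the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class AffinityMatrix:
    """Pairwise affinities, either conditional rows p(j|i) or a joint p_ij."""

    P: np.ndarray
    perplexity: float
    mode: str  # {"conditional", "joint"}
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("conditional", "joint"):
            raise ValueError(f"mode must be 'conditional' or 'joint', got {self.mode!r}")


@dataclass
class Embedding:
    """Low-dimensional coordinates with the optimization trace that made them."""

    Y: np.ndarray
    cost_trace: np.ndarray
    seed: int
    hyperparams: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# High-dimensional affinities
# ---------------------------------------------------------------------------

def _pairwise_sq_block(X: np.ndarray, rows: slice, row_norms: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between X[rows] and all rows of X."""
    G = X[rows] @ X.T
    D2 = row_norms[rows][:, None] + row_norms[None, :]
    D2 -= G
    D2 -= G
    np.maximum(D2, 0.0, out=D2)
    return D2


def conditional_affinities(
    X: DatapointMatrix | np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-7,
    max_steps: int = 64,
    block_rows: int | None = None,
) -> AffinityMatrix:
    """Gaussian conditional affinities with per-row bandwidths.

    Each row's precision ``beta_i = 1 / (2 sigma_i^2)`` is found by bisection
    (with dynamic bracket expansion) until the row entropy H satisfies
    ``|H - log2(perplexity)| < tol``, i.e. the row perplexity 2^H matches the
    target.  The diagonal is exactly zero and every row sums to one.

    The target is auto-clamped to ``(n - 1) / 3`` for small n.
    """
    if isinstance(X, DatapointMatrix):
        X = X.X
    X = np.asarray(X)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 datapoints")
    dtype = X.dtype if X.dtype in (np.float32, np.float64) else np.float64
    X = np.ascontiguousarray(X, dtype=dtype)
    perplexity = float(min(perplexity, max((n - 1) / 3.0, 1.0 + 1e-6)))
    target_h = np.log2(perplexity)

    if block_rows is None:
        block_rows = max(16, min(n, int(2 ** 26 // max(n, 1)) or 16))
    P = np.empty((n, n), dtype=dtype)
    sigmas = np.empty(n, dtype=np.float64)
    row_norms = np.einsum("ij,ij->i", X, X)
    ln2 = np.log(2.0)

    for start in range(0, n, block_rows):
        rows = slice(start, min(start + block_rows, n))
        b = rows.stop - rows.start
        D2 = _pairwise_sq_block(X, rows, row_norms)
        idx = np.arange(rows.start, rows.stop)
        D2[np.arange(b), idx] = np.inf          # exclude self from the shift
        shift = D2.min(axis=1)                  # guards exp underflow; P is shift-invariant
        D2 -= shift[:, None]
        D2[np.arange(b), idx] = 0.0             # finite diagonal; W diagonal is forced to 0

        beta = np.ones(b)
        beta_lo = np.full(b, -np.inf)
        beta_hi = np.full(b, np.inf)
        W = np.empty_like(D2)
        tmp = np.empty_like(D2)
        for step in range(max_steps + 1):
            np.multiply(D2, -beta[:, None], out=W, casting="unsafe")
            np.exp(W, out=W)
            W[np.arange(b), idx] = 0.0
            sumW = W.sum(axis=1, dtype=np.float64)
            np.multiply(D2, W, out=tmp)
            # natural-log entropy of the normalized row
            h_nat = np.log(sumW) + beta * tmp.sum(axis=1, dtype=np.float64) / sumW
            diff = h_nat / ln2 - target_h
            if np.all(np.abs(diff) < tol) or step == max_steps:
                break
            too_high = diff > 0  # entropy too large -> increase beta (narrow kernel)
            beta_lo = np.where(too_high, beta, beta_lo)
            beta_hi = np.where(too_high, beta_hi, beta)
            grow = np.isinf(np.where(too_high, beta_hi, -beta_lo))
            beta = np.where(
                grow,
                np.where(too_high, beta * 2.0, beta / 2.0),
                (beta_lo + beta_hi) / 2.0,
            )
        W /= sumW[:, None]
        P[rows] = W.astype(dtype)
        sigmas[rows] = np.sqrt(1.0 / (2.0 * beta))

    return AffinityMatrix(P=P, perplexity=perplexity, mode="conditional", sigmas=sigmas)


def symmetrize(P_cond: AffinityMatrix) -> AffinityMatrix:
    """Joint probabilities p_ij = (p(j|i) + p(i|j)) / 2n from conditional rows."""
    if P_cond.mode != "conditional":
        raise ValueError("symmetrize expects a conditional-mode AffinityMatrix")
    n = P_cond.P.shape[0]
    P = P_cond.P + P_cond.P.T
    P /= 2.0 * n
    return AffinityMatrix(P=P, perplexity=P_cond.perplexity, mode="joint", sigmas=P_cond.sigmas)


# ---------------------------------------------------------------------------
# Low-dimensional affinities, cost and gradient
# ---------------------------------------------------------------------------

def _student_t_weights(Y: np.ndarray) -> np.ndarray:
    """Unnormalized Student-t kernel (1 + ||d_i - d_j||^2)^-1 with zero diagonal."""
    Y = np.asarray(Y, dtype=np.float64)
    r = np.einsum("ij,ij->i", Y, Y)
    D2 = r[:, None] + r[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(D2, 0.0, out=D2)
    W = 1.0 / (1.0 + D2)
    np.fill_diagonal(W, 0.0)
    return W


def low_dim_affinities(Y: np.ndarray, mode: str = "joint") -> AffinityMatrix:
    """Student-t similarities q ~ (1 + ||d_i - d_j||^2)^-1.

    ``mode="joint"`` normalizes over all pairs; ``mode="conditional"``
    normalizes each row (the literal per-point form).  Entries are floored
    at 1e-12 so that log(q) stays finite for distant pairs.
    """
    W = _student_t_weights(Y)
    if mode == "joint":
        Q = W / W.sum()
    elif mode == "conditional":
        Q = W / W.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    off = ~np.eye(Q.shape[0], dtype=bool)
    Q[off] = np.maximum(Q[off], _Q_FLOOR)
    return AffinityMatrix(P=Q, perplexity=np.nan, mode=mode)


def kl_cost(P: AffinityMatrix, Q: AffinityMatrix) -> float:
    """Kullback-Leibler divergence C = sum_ij p log(p / q), with 0 log 0 = 0."""
    if P.P.shape != Q.P.shape:
        raise ValueError(f"shape mismatch: {P.P.shape} vs {Q.P.shape}")
    if P.mode != Q.mode:
        raise ValueError(f"mode mismatch: {P.mode} vs {Q.mode}")
    p = np.asarray(P.P, dtype=np.float64)
    q = np.maximum(np.asarray(Q.P, dtype=np.float64), _Q_FLOOR)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_gradient(P: AffinityMatrix, Y: np.ndarray, variant: str | None = None) -> np.ndarray:
    """Exact gradient of the KL cost with respect to the coordinates d_i.

    ``variant="joint"`` (the default for a joint-mode P) is the closed form
    4 sum_j (p_ij - q_ij)(d_i - d_j)(1 + ||d_i - d_j||^2)^-1.  For a
    conditional-mode P the gradient of sum_i KL(P_i || Q_i) with
    row-normalized Student-t similarities is
    2 sum_j (p(j|i) + p(i|j) - q(j|i) - q(i|j)) (d_i - d_j) w_ij.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if P.P.shape[0] != Y.shape[0]:
        raise ValueError(f"P has {P.P.shape[0]} points, Y has {Y.shape[0]}")
    variant = variant or P.mode
    W = _student_t_weights(Y)
    p = np.asarray(P.P, dtype=np.float64)
    if variant == "joint":
        Q = W / W.sum()
        M = 4.0 * (p - Q) * W
    elif variant == "conditional":
        Q = W / W.sum(axis=1, keepdims=True)
        M = 2.0 * (p + p.T - Q - Q.T) * W
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return M.sum(axis=1)[:, None] * Y - M @ Y


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _plogp(P: np.ndarray) -> float:
    mask = P > 0
    vals = P[mask].astype(np.float64)
    return float(np.sum(vals * np.log(vals)))


def run_tsne(
    X: DatapointMatrix | np.ndarray,
    dims: int = 5,
    perplexity: float = 30.0,
    iterations: int = 1000,
    learning_rate: float | str = 100.0,
    momentum: float = 0.5,
    final_momentum: float = 0.8,
    momentum_switch_iter: int = 250,
    early_exaggeration: float = 4.0,
    exaggeration_iters: int = 50,
    seed: int = 0,
    variant: str = "joint",
    dtype=None,
    cost_every: int = 1,
    use_gains: bool = True,
    perplexity_tol: float = 1e-7,
) -> Embedding:
    """Embed the rows of ``X`` into ``dims`` dimensions (default 5).

    Momentum gradient descent from an N(0, 1e-4) initialization under
    ``seed``; the same seed always yields the same embedding.  The cost is
    recorded every ``cost_every`` iterations.  ``learning_rate="auto"``
    scales as max(100, n / 12), useful for large inputs.
    """
    if isinstance(X, DatapointMatrix):
        X = X.X
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 datapoints to embed")
    if dtype is None:
        dtype = X.dtype if X.dtype == np.float32 else np.float64
    dtype = np.dtype(dtype).type

    eta = max(100.0, n / 12.0) if learning_rate == "auto" else float(learning_rate)

    cond = conditional_affinities(X, perplexity, tol=perplexity_tol)
    if variant == "joint":
        P = symmetrize(cond).P.astype(dtype)
    elif variant == "conditional":
        P = cond.P.astype(dtype)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    rng = np.random.default_rng(seed)
    Y = (rng.standard_normal((n, dims)) * 1e-2).astype(dtype)
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)

    plogp_true = _plogp(P)
    exag = float(early_exaggeration) if exaggeration_iters > 0 else 1.0
    if exag != 1.0:
        P *= dtype(exag)

    fused = (
        _numba is not None and variant == "joint" and n >= _FUSED_MIN_N
    )
    if fused:
        grad = np.empty_like(Y)
    else:
        # preallocated n x n buffers: D2 doubles as the coefficient matrix
        D2 = np.empty((n, n), dtype=dtype)
        W = np.empty((n, n), dtype=dtype)
        r = np.empty(n, dtype=dtype)
        PY = np.empty((n, dims), dtype=dtype)
        diag = np.arange(n)

    costs: list[float] = []
    cost_iters: list[int] = []
    for it in range(iterations):
        if it == exaggeration_iters and exag != 1.0:
            P /= dtype(exag)
            exag = 1.0
        mom = momentum if it < momentum_switch_iter else final_momentum
        record = it % cost_every == 0 or it == iterations - 1

        if fused:
            if record:
                plogq = float(_fused_joint_plogq(Y, P, _Q_FLOOR))
                costs.append(plogp_true - plogq / exag)
                cost_iters.append(it)
            _fused_joint_grad(Y, P, grad)
        else:
            np.matmul(Y, Y.T, out=D2)
            D2 *= dtype(-2.0)
            np.einsum("ij,ij->i", Y, Y, out=r)
            D2 += r[:, None]
            D2 += r[None, :]
            D2 += dtype(1.0)
            np.reciprocal(D2, out=W)        # W = (1 + ||d_i - d_j||^2)^-1
            W[diag, diag] = dtype(0.0)

            if record:
                if variant == "joint":
                    np.multiply(W, dtype(1.0 / W.sum()), out=D2)
                else:
                    D2[:] = W / W.sum(axis=1, keepdims=True)
                np.maximum(D2, dtype(_Q_FLOOR), out=D2)
                D2[diag, diag] = dtype(1.0)  # p_ii = 0; avoid log(0)
                np.log(D2, out=D2)
                plogq = float(np.einsum("ij,ij->", P, D2))
                # P may hold exaggerated values; report the cost of the true
                # (unexaggerated) distribution.
                costs.append(plogp_true - plogq / exag)
                cost_iters.append(it)

            if variant == "joint":
                s = float(W.sum())
                np.multiply(W, dtype(-1.0 / s), out=D2)
                D2 += P
                D2 *= W                      # D2 = 4^-1 * grad coefficients
                coef_scale = 4.0
            else:
                sums = W.sum(axis=1)
                Q = W / sums[:, None]
                M = P + P.T
                M -= Q
                M -= Q.T
                M *= W
                D2[:] = M
                coef_scale = 2.0

            rowsum = D2.sum(axis=1)
            np.matmul(D2, Y, out=PY)
            grad = rowsum[:, None] * Y
            grad -= PY
            grad *= dtype(coef_scale)

        if use_gains:
            same_sign = np.sign(grad) == np.sign(velocity)
            gains = np.where(same_sign, gains * dtype(0.8), gains + dtype(0.2))
            np.maximum(gains, dtype(0.01), out=gains)
            grad = grad * gains
        velocity *= dtype(mom)
        velocity -= dtype(eta) * grad
        Y += velocity
        Y -= Y.mean(axis=0)

    hyper = {
        "dims": dims,
        "perplexity": float(cond.perplexity),
        "iterations": iterations,
        "learning_rate": eta,
        "momentum": momentum,
        "final_momentum": final_momentum,
        "momentum_switch_iter": momentum_switch_iter,
        "early_exaggeration": early_exaggeration,
        "exaggeration_iters": exaggeration_iters,
        "variant": variant,
        "use_gains": use_gains,
        "cost_every": cost_every,
        "cost_iterations": cost_iters,
        "dtype": np.dtype(dtype).name,
    }
    return Embedding(
        Y=np.asarray(Y, dtype=np.float64),
        cost_trace=np.asarray(costs, dtype=np.float64),
        seed=int(seed),
        hyperparams=hyper,
    )
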