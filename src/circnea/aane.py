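"""Accelerated attributed network embedding solved by ADMM.

The embedding Q (one d-vector per node) approximately factorizes the
attribute cosine-similarity matrix S (S ~ QQ^T) while an edge-weighted
penalty pulls embeddings of strongly connected nodes together:

    L = ||S - QQ^T||_F^2 + lambda * sum_ij w_ij ||q_i - q_j||_2

The non-smooth penalty is handled by splitting Q into a copy Z with scaled
dual U and sweeping row-wise closed-form updates of q_i and z_i (each a
d x d linear solve) in alternation, Gauss-Seidel style, until the relative
change of L falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AaneProblem:
    """Problem data and hyperparameters for one embedding run.

    S must be symmetric with unit diagonal (attribute cosine similarity);
    W symmetric nonnegative with zero diagonal (network edge weights).
    lambda_ balances smoothness against factorization fidelity; rho is the
    ADMM penalty.  Defaults follow common practice for this method family.
    """

    S: np.ndarray
    W: np.ndarray
    d: int = 64
    lambda_: float = 0.05
    rho: float = 5.0
    max_iter: int = 50
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        N = self.S.shape[0]
        if self.S.shape != (N, N) or self.W.shape != (N, N):
            raise ValueError("S and W must be square and of equal size")
        if np.abs(self.S - self.S.T).max() > 1e-8 or np.abs(self.W - self.W.T).max() > 1e-8:
            raise ValueError("S and W must be symmetric")
        if (self.W < 0).any():
            raise ValueError("W must be nonnegative")
        if not (1 <= self.d <= N):
            raise ValueError("embedding dimension must satisfy 1 <= d <= N")
        if self.lambda_ < 0 or self.rho <= 0:
            raise ValueError("need lambda >= 0 and rho > 0")


@dataclass
class AaneState:
    Q: np.ndarray
    Z: np.ndarray
    U: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    @property
    def embedding(self) -> np.ndarray:
        return (self.Q + self.Z) / 2.0


_EPS = 1e-10  # guards the ||q_i - z_j|| denominators


def attribute_similarity(attributes: np.ndarray) -> np.ndarray:
    """Cosine similarity between attribute rows; symmetric, unit diagonal.

    All-zero rows have no direction: their off-diagonal similarity is
    defined as 0 (diagonal 1) and a warning is emitted.
    """
    import warnings

    X = np.asarray(attributes, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero attribute row(s); similarity set to 0", stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def objective(S: np.ndarray, W: np.ndarray, Q: np.ndarray, lambda_: float) -> float:
    """L = ||S - QQ^T||_F^2 + lambda * sum_{i<j reachable} w_ij ||q_i - q_j||_2."""
    frob = float(np.sum((S - Q @ Q.T) ** 2))
    ii, jj = np.nonzero(np.triu(W, 1))
    pen = float(np.sum(W[ii, jj] * np.linalg.norm(Q[ii] - Q[jj], axis=1))) if len(ii) else 0.0
    # W is symmetric: count each undirected edge once on each side
    return frob + lambda_ * 2.0 * pen


def aane_fit(problem: AaneProblem) -> AaneState:
    """Run the ADMM sweeps and return the embedding state.

    Rows are updated in ascending index order within each sweep, using the
    latest available neighbour values (Gauss-Seidel), which is deterministic
    for a fixed seed.  Stops when the relative objective change drops below
    ``tol`` or after ``max_iter`` sweeps.  The returned embedding is
    (Q + Z) / 2.
    """
    S, W = problem.S, problem.W
    N, d = S.shape[0], problem.d
    lam, rho = problem.lambda_, problem.rho
    rng = np.random.default_rng(problem.seed)
    Q = rng.normal(0.0, 0.01, size=(N, d))
    Z = Q.copy()
    U = np.zeros((N, d))
    neighbors = [np.nonzero(W[i])[0] for i in range(N)]
    trace = [objective(S, W, Q, lam)]
    eye = np.eye(d)
    for _ in range(problem.max_iter):
        # q_i update (Eq-22-style): normal equations with Z fixed
        ZtZ = Z.T @ Z
        for i in range(N):
            nb = neighbors[i]
            rhs = 2.0 * S[i] @ Z + rho * (Z[i] - U[i])
            coef = rho
            if len(nb):
                diff = np.linalg.norm(Q[i] - Z[nb], axis=1) + _EPS
                wts = W[i, nb] / diff
                rhs = rhs + lam * wts @ Z[nb]
                coef = coef + lam * wts.sum()
            P = 2.0 * ZtZ + coef * eye
            Q[i] = np.linalg.solve(P, rhs)
        # z_i update (Eq-23-style): symmetric role with Q fixed
        QtQ = Q.T @ Q
        for i in range(N):
            nb = neighbors[i]
            rhs = 2.0 * S[i] @ Q + rho * (Q[i] + U[i])
            coef = rho
            if len(nb):
                diff = np.linalg.norm(Z[i] - Q[nb], axis=1) + _EPS
                wts = W[i, nb] / diff
                rhs = rhs + lam * wts @ Q[nb]
                coef = coef + lam * wts.sum()
            L = 2.0 * QtQ + coef * eye
            Z[i] = np.linalg.solve(L, rhs)
        U += Q - Z
        val = objective(S, W, Q, lam)
        if not np.isfinite(val):
            raise FloatingPointError("AANE diverged; reduce rho/lambda")
        trace.append(val)
        prev = trace[-2]
        if prev > 0 and abs(prev - val) / prev < problem.tol:
            break
    return AaneState(Q=Q, Z=Z, U=U, objective_trace=trace)


def embed_nodes(
    attributes: np.ndarray,
    similarity: np.ndarray,
    d: int = 64,
    lambda_: float = 0.05,
    rho: float = 5.0,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Embed one side of the bipartite problem.

    ``attributes`` are the side's fused feature rows (reduced CM or DM);
    ``similarity`` the side's fused similarity matrix (CS or DS), whose
    off-diagonal entries become edge weights W (diagonal zeroed, negatives
    clipped).  Returns the N x d embedding Q.
    """
    S = attribute_similarity(attributes)
    W = np.clip(np.asarray(similarity, dtype=float), 0.0, None)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    d = min(d, S.shape[0])
    state = aane_fit(AaneProblem(S=S, W=W, d=d, lambda_=lambda_, rho=rho, max_iter=max_iter, tol=tol, seed=seed))
    return state.embedding
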