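"""Kullback-Leibler non-negative matrix factorization by multiplicative updates.

Factorizes a non-negative expression matrix ``A`` (genes x samples) as
``A ~ W H`` with ``W`` (genes x k) holding the metagene basis and ``H``
(k x samples) the per-sample metagene expression.  The objective is the
generalized KL divergence

    D(A || WH) = sum_ij [ A_ij * log(A_ij / (WH)_ij) - A_ij + (WH)_ij ]

(natural log, 0*log 0 = 0), minimised by the classic multiplicative update
rules; samples are clustered by the row index of the largest entry in their
H column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix

EPS = 1e-12


def _as_array(A) -> np.ndarray:
    if isinstance(A, ExpressionMatrix):
        return A.values
    return np.asarray(A, dtype=float)


def kl_divergence(A, W, H) -> float:
    """Generalized Kullback-Leibler divergence D(A || WH).

    Uses the convention ``0 * log(0/x) = 0``.  Raises ``ValueError`` when the
    reconstruction is exactly zero at a position where ``A`` is positive
    (the divergence would be infinite); inside the solver this is prevented
    by epsilon flooring.
    """
    A = _as_array(A)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    WH = W @ H
    if (A < 0).any() or (W < 0).any() or (H < 0).any():
        raise ValueError("kl_divergence requires non-negative inputs")
    pos = A > 0
    if np.any(WH[pos] == 0):
        raise ValueError("(WH)_ij == 0 where A_ij > 0: divergence is infinite")
    term = np.zeros_like(A)
    term[pos] = A[pos] * np.log(A[pos] / WH[pos])
    return float(np.sum(term - A + WH))


@dataclass
class Factorization:
    """One NMF solution: basis ``W``, coefficients ``H`` and the divergence trace."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    divergence_trace: list[float] = field(default_factory=list)
    seed: int = 0
    n_iter: int = 0
    converged: bool = False

    @property
    def final_divergence(self) -> float:
        return self.divergence_trace[-1]


def _mu_step(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative KL update of H then W (Lee-Seung rules)."""
    WH = np.maximum(W @ H, EPS)
    H = H * (W.T @ (A / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    H = np.maximum(H, EPS)
    WH = np.maximum(W @ H, EPS)
    W = W * ((A / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    W = np.maximum(W, EPS)
    return W, H


def nmf_fit(
    A,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    check_interval: int = 10,
    patience: int = 10,
) -> Factorization:
    """Fit KL-divergence NMF with multiplicative updates.

    ``W`` and ``H`` are initialized i.i.d. uniform on (0, 1) scaled to the
    magnitude of ``A`` and updated until ``max_iter`` iterations or until the
    relative change in the divergence stays below ``tol`` for ``patience``
    consecutive checks (checked every ``check_interval`` iterations).
    Deterministic given ``seed``.
    """
    X = _as_array(A)
    if X.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    n, m = X.shape
    if (X < 0).any():
        raise ValueError("A must be non-negative")
    if not X.any():
        raise ValueError("A is all zero; nothing to factorize")
    if rank < 2:
        raise ValueError(f"rank must be >= 2, got {rank}")
    if rank >= min(n, m):
        raise ValueError(f"rank must be < min(N, M) = {min(n, m)}, got {rank}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / rank)
    W = np.maximum(rng.uniform(size=(n, rank)) * scale, EPS)
    H = np.maximum(rng.uniform(size=(rank, m)) * scale, EPS)

    trace = [kl_divergence(X, W, H)]
    quiet = 0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        W, H = _mu_step(X, W, H)
        if n_iter % check_interval == 0 or n_iter == max_iter:
            d = kl_divergence(X, W, H)
            prev = trace[-1]
            trace.append(d)
            rel = abs(prev - d) / max(abs(prev), EPS)
            quiet = quiet + 1 if rel < tol else 0
            if quiet >= patience:
                converged = True
                break
    return Factorization(
        W=W, H=H, rank=rank, divergence_trace=trace, seed=seed,
        n_iter=n_iter, converged=converged,
    )


def assign_clusters(f: Factorization) -> np.ndarray:
    """Cluster index per sample: argmax over metagene rows of each H column.

    Ties are broken toward the lowest metagene index (numpy argmax order).
    """
    return np.argmax(f.H, axis=0)


def explained_variance(A, f: Factorization) -> float:
    """Fraction of the squared mass of ``A`` captured by ``W H``:
    ``1 - ||A - WH||^2 / ||A||^2``.  Equals 1 iff the reconstruction is exact."""
    X = _as_array(A)
    resid = X - f.W @ f.H
    denom = float(np.sum(X**2))
    if denom == 0:
        raise ValueError("A is all zero")
    return 1.0 - float(np.sum(resid**2)) / denom


class KLNMF(TransformerMixin, BaseEstimator):
    """KL-divergence NMF as a scikit-learn style transformer.

    ``fit(X)`` factorizes ``X ~ W_ @ components_`` where rows of ``X`` are
    genes and columns are samples (the field's ``A = W H`` orientation).

    Parameters
    ----------
    n_components : int
        Factorization rank ``k`` (number of metagenes), >= 2.
    max_iter, tol, check_interval, patience :
        Stopping rule of :func:`nmf_fit`.
    random_state : int
        Seed for the uniform initialization.

    Attributes
    ----------
    W_ : ndarray of shape (n_genes, n_components)
        Basis (metagene) matrix.
    components_ : ndarray of shape (n_components, n_samples)
        Coefficient matrix ``H``.
    reconstruction_err_ : float
        Final KL divergence.
    divergence_trace_ : list of float
    n_iter_ : int
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 2000,
        tol: float = 1e-6,
        check_interval: int = 10,
        patience: int = 10,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.check_interval = check_interval
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y=None):
        f = nmf_fit(
            X,
            rank=self.n_components,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
            check_interval=self.check_interval,
            patience=self.patience,
        )
        self.factorization_ = f
        self.W_ = f.W
        self.components_ = f.H
        self.reconstruction_err_ = f.final_divergence
        self.divergence_trace_ = f.divergence_trace
        self.n_iter_ = f.n_iter
        return self

    def transform(self, X):
        """Project new gene rows onto the fitted metagenes.

        Holds ``components_`` (H) fixed and solves for the basis rows of
        ``X`` by multiplicative updates; returns the (n_genes, k) loadings.
        """
        X = _as_array(X)
        H = self.components_
        rng = np.random.default_rng(self.random_state)
        W = np.maximum(rng.uniform(size=(X.shape[0], H.shape[0])) * np.sqrt(X.mean() / H.shape[0]), EPS)
        for _ in range(self.max_iter):
            WH = np.maximum(W @ H, EPS)
            W_new = W * ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
            W_new = np.maximum(W_new, EPS)
            if np.max(np.abs(W_new - W) / np.maximum(W, EPS)) < self.tol:
                W = W_new
                break
            W = W_new
        return W

    def predict(self, X=None) -> np.ndarray:
        """Cluster index per sample from the fitted H (column argmax)."""
        return assign_clusters(self.factorization_)
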