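"""Sparse multiplicative-update NMF for symmetric adjacency matrices.

Minimizes the Frobenius reconstruction error ||A - W H||_F with W, H >= 0 by
Lee-Seung multiplicative updates.  The adjacency is kept sparse (CSR), so
each update costs O(nnz * k) plus small dense terms; the reconstruction error
is tracked per iteration (it is non-increasing up to floating-point noise,
which the tests assert) and restarts are seeded deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import svds

_EPS = 1e-10


def _nndsvda_init(A: sparse.csr_matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD-based initialization (NNDSVD with average fill).

    Each truncated-SVD factor pair is replaced by whichever of its positive
    or negative parts carries more mass; zeros are filled with the matrix
    mean so multiplicative updates can move every entry.
    """
    n, m = A.shape
    # fixed start vector makes the Lanczos iteration reproducible
    u, s, vt = svds(A.astype(float), k=k, v0=np.ones(min(n, m)) / np.sqrt(min(n, m)))
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    for j in range(k):
        x, y = u[:, j], vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp = np.linalg.norm(xp) * np.linalg.norm(yp)
        mn = np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn:
            xu, yu, sig = xp, yp, mp
        else:
            xu, yu, sig = xn, yn, mn
        if sig > 0:
            scale = np.sqrt(s[j] * sig)
            W[:, j] = scale * xu / np.linalg.norm(xu)
            H[j] = scale * yu / np.linalg.norm(yu)
    avg = max(float(A.mean()), _EPS)
    W[W <= 0] = avg
    H[H <= 0] = avg
    return W, H


@dataclass
class NMFResult:
    W: np.ndarray  # n x k
    H: np.ndarray  # k x n
    error_history: list[float]
    converged: bool

    @property
    def reconstruction_error(self) -> float:
        return self.error_history[-1]


def _frobenius_error(norm_a2: float, W: np.ndarray, H: np.ndarray, AHt: np.ndarray) -> float:
    # ||A - WH||^2 = ||A||^2 - 2 <A, WH> + ||WH||^2, all computable without
    # materializing WH: <A, WH> = sum(W * (A H^T)), ||WH||^2 = <W^T W, H H^T>.
    cross = float(np.sum(W * AHt))
    gram = float(np.sum((W.T @ W) * (H @ H.T)))
    return float(np.sqrt(max(norm_a2 - 2.0 * cross + gram, 0.0)))


def nmf_multiplicative(
    A: sparse.csr_matrix,
    k: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    init: str = "random",
) -> NMFResult:
    """One multiplicative-update run from a seeded random or NNDSVDa start.

    Stops early when the relative error improvement over an iteration drops
    below ``tol``; ``converged`` is False if ``max_iter`` was exhausted first.
    """
    n, m = A.shape
    if n != m:
        raise ValueError("A must be square")
    if not (0 < k < n):
        raise ValueError("k must satisfy 0 < k < n")
    A = A.tocsr().astype(float)
    At = A.T.tocsr()
    if init == "nndsvda":
        W, H = _nndsvda_init(A, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(max(A.mean(), _EPS) / k)
        W = rng.uniform(0.1, 1.0, (n, k)) * scale
        H = rng.uniform(0.1, 1.0, (k, n)) * scale
    else:
        raise ValueError(f"unknown init: {init}")
    norm_a2 = float((A.data**2).sum())

    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        AHt = A @ H.T  # n x k
        W *= AHt / (W @ (H @ H.T) + _EPS)
        WtA = (At @ W).T  # k x n
        H *= WtA / ((W.T @ W) @ H + _EPS)
        err = _frobenius_error(norm_a2, W, H, A @ H.T)
        history.append(err)
        if len(history) >= 2:
            prev = history[-2]
            if prev > 0 and (prev - err) / max(prev, _EPS) < tol:
                converged = True
                break
    return NMFResult(W=W, H=H, error_history=history, converged=converged)


def nmf_best_of(
    A: sparse.csr_matrix,
    k: int,
    seed: int,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> NMFResult:
    """Best of ``n_restarts`` seeded runs by final reconstruction error.

    The first restart starts from the deterministic NNDSVDa initialization
    (which lands dense blocks on separate components); the remaining
    restarts are random, seeded from ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best: NMFResult | None = None
    for i, s in enumerate(child_seeds):
        res = nmf_multiplicative(
            A, k, int(s), max_iter=max_iter, tol=tol,
            init="nndsvda" if i == 0 else "random",
        )
        if best is None or res.reconstruction_error < best.reconstruction_error:
            best = res
    assert best is not None
    return best
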