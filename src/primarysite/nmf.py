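"""Non-negative matrix factorization with generalized KL loss and masking.

Multiplicative-update NMF minimizing the mean generalized Kullback-Leibler
divergence D(V || WH), optionally restricted to a boolean mask of observed
entries. Masked (held-out) entries are ignored by the loss and can afterwards
be imputed as (WH), which is the basis of the rank-selection procedure:
factorize with a fraction of entries hidden and score the imputation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def _kl_loss(V: np.ndarray, WH: np.ndarray, mask: np.ndarray | None) -> float:
    """Mean generalized KL divergence over observed entries."""
    if mask is None:
        v, wh = V.ravel(), WH.ravel()
    else:
        v, wh = V[mask], WH[mask]
    wh = np.maximum(wh, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(v > 0, v * np.log(np.maximum(v, _EPS) / wh), 0.0)
    return float(np.mean(term - v + wh))


@dataclass
class NMFResult:
    W: np.ndarray  # samples x rank
    H: np.ndarray  # rank x bins
    loss: float
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


def nmf_kl(
    V: np.ndarray,
    rank: int,
    mask: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | np.random.Generator = 0,
    check_every: int = 10,
) -> NMFResult:
    """Factorize V ~= W @ H under generalized KL loss, multiplicative updates.

    Parameters
    ----------
    V
        Non-negative samples x bins matrix.
    rank
        Number of components, at least 1 and at most min(V.shape).
    mask
        Optional boolean matrix of entries included in the loss; masked-out
        entries are ignored during fitting (and can be imputed from W @ H).
    max_iter, tol
        Updates stop at ``max_iter`` or when the relative loss change over a
        ``check_every``-iteration window falls below ``tol``.
    seed
        Integer seed or a ``numpy.random.Generator``; W and H are initialized
        uniformly in (0, 1] scaled to V's mean, so runs are reproducible.

    Notes
    -----
    Multiplicative updates never produce negative entries and the masked loss
    is monotone non-increasing (to numerical precision).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-dimensional")
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if V.sum() == 0:
        raise ValueError("V is all zero; nothing to factorize")
    n, m = V.shape
    if not 1 <= rank <= min(n, m):
        raise ValueError(f"rank must be in [1, {min(n, m)}], got {rank}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != V.shape:
            raise ValueError("mask shape must match V")
        M = mask.astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / rank)
    W = (1.0 - rng.random((n, rank))) * scale  # uniform in (0, 1], scaled
    H = (1.0 - rng.random((rank, m))) * scale

    prev = _kl_loss(V, W @ H, mask)
    loss = prev
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        if mask is None:
            W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
            WH = np.maximum(W @ H, _EPS)
            H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        else:
            ratio = M * (V / WH)
            W *= ratio @ H.T / np.maximum(M @ H.T, _EPS)
            WH = np.maximum(W @ H, _EPS)
            ratio = M * (V / WH)
            H *= W.T @ ratio / np.maximum(W.T @ M, _EPS)
        if it % check_every == 0 or it == max_iter:
            loss = _kl_loss(V, W @ H, mask)
            denom = max(abs(prev), _EPS)
            if prev - loss >= 0 and (prev - loss) / denom < tol:
                converged = True
                break
            prev = loss
    return NMFResult(W=W, H=H, loss=loss, n_iter=it, converged=converged)


def impute_mse(V: np.ndarray, result: NMFResult, mask: np.ndarray) -> float:
    """Mean squared error of (W @ H) against V on masked-out (held-out) entries."""
    held_out = ~np.asarray(mask, dtype=bool)
    if not held_out.any():
        raise ValueError("mask hides no entries; nothing to score")
    diff = result.reconstruct()[held_out] - np.asarray(V, dtype=float)[held_out]
    return float(np.mean(diff**2))
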