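"""Closed-form network propagation of expression profiles.

The interactive effect F minimizes ``(F-X)^T(F-X) + mu F^T L F``, i.e. a
Tikhonov-regularized smoothing of each sample's expression vector over the
graph, solved exactly as ``F = (I + mu L)^{-1} X``. The combined effect mixes
it with the raw (independent) effect through the logistic combining ratio
``theta = sigmoid(alpha)``: ``Z = theta F + (1-theta) X``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass
class PropagationResult:
    """Interactive effect F, combined effect Z, and the realized mixing."""

    F: np.ndarray
    Z: np.ndarray
    theta: float
    mu: float


class PropagationOperator:
    """Cached Cholesky factorization of ``Phi = I + mu L`` for one mu.

    ``I + mu L`` is symmetric positive definite for mu >= 0 (L is PSD), so a
    single factorization serves every sample column and every solve against L.
    """

    def __init__(self, L: np.ndarray, mu: float):
        if mu < 0:
            raise ValueError(f"mu must be >= 0, got {mu}")
        self.L = np.asarray(L, dtype=float)
        self.mu = float(mu)
        phi = np.eye(L.shape[0]) + mu * self.L
        try:
            self._factor = cho_factor(phi)
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(phi)
            raise np.linalg.LinAlgError(
                f"factorization of I + mu*L failed (mu={mu}, cond~{cond:.3g})"
            ) from exc

    def solve(self, B: np.ndarray) -> np.ndarray:
        """Phi^{-1} B via the cached factorization."""
        return cho_solve(self._factor, np.asarray(B, dtype=float))


def propagate(X: np.ndarray, L: np.ndarray, mu: float) -> np.ndarray:
    """Interactive effect ``F = (I + mu L)^{-1} X`` (SPD solve, no inverse)."""
    X = np.asarray(X, dtype=float)
    if mu == 0:
        return X.copy()
    return PropagationOperator(L, mu).solve(X)


def combine(X: np.ndarray, F: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """Convex combination ``Z = theta F + (1-theta) X``, theta = sigmoid(alpha)."""
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if X.shape != F.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs F {F.shape}")
    theta = sigmoid(alpha)
    return theta, theta * F + (1.0 - theta) * X


def sigmoid(a: float) -> float:
    # split to avoid overflow for large |a|
    if a >= 0:
        return 1.0 / (1.0 + np.exp(-a))
    e = np.exp(a)
    return e / (1.0 + e)


def propagation_result(
    X: np.ndarray, L: np.ndarray, mu: float, alpha: float
) -> PropagationResult:
    F = propagate(X, L, mu)
    theta, Z = combine(X, F, alpha)
    return PropagationResult(F=F, Z=Z, theta=theta, mu=float(mu))


def smoothing_objective(F: np.ndarray, X: np.ndarray, L: np.ndarray, mu: float) -> float:
    """The scalar value of the propagation objective at F."""
    R = F - X
    return float(np.sum(R * R) + mu * np.sum(F * (L @ F)))
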