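"""Robust principal component analysis via inexact augmented Lagrange multipliers.

Gross, sparse artifacts (electrode pops, motion spikes) sit on top of EEG
whose channel-by-time matrix is approximately low rank.  Robust PCA splits
the observed matrix ``M`` into a low-rank part ``A`` and a sparse part ``E``
by solving

    min ||A||_* + lambda ||E||_1   s.t.  A + E = M,

with the inexact ALM iteration: singular-value thresholding of
``M - E + Y/mu`` updates ``A``, entrywise soft-thresholding of
``M - A + Y/mu`` at ``lambda/mu`` updates ``E``, then the multiplier
``Y <- Y + mu (M - A - E)`` and ``mu <- rho mu``.  Defaults are the standard
choices: ``lambda = 1/sqrt(max(m, n))``, ``mu0 = 1.25/||M||_2``,
``rho = 1.5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io_core import Recording, ValidationError


@dataclass
class RpcaResult:
    """Low-rank + sparse split of a matrix, with convergence diagnostics."""

    low_rank: np.ndarray
    sparse: np.ndarray
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


class RobustPCA(BaseEstimator):
    """Low-rank / sparse decomposition by the inexact ALM method.

    Parameters
    ----------
    lam :
        Sparsity weight; ``None`` uses ``1/sqrt(max(m, n))``.
    tol :
        Convergence threshold on ``||M - A - E||_F / ||M||_F``.
    max_iter :
        Outer-iteration cap; hitting it sets ``converged_ = False``.

    Attributes
    ----------
    low_rank_ : ndarray
        The recovered low-rank component ``A``.
    sparse_ : ndarray
        The sparse outlier component ``E``.
    n_iter_ : int
    converged_ : bool
    objective_trace_ : list of float
        Objective ``||A||_* + lam ||M - A||_1`` of the feasible point
        ``(A, M - A)`` after each outer iteration (the iterates themselves
        are infeasible until convergence, so this is the meaningful
        monotone quantity).
    """

    def __init__(self, lam: float | None = None, tol: float = 1e-7, max_iter: int = 500):
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y=None) -> "RobustPCA":
        M = np.asarray(X, dtype=float)
        if M.ndim != 2:
            raise ValidationError("RobustPCA expects a 2-D matrix")
        if not np.isfinite(M).all():
            raise ValidationError("matrix contains non-finite entries")
        if self.lam is not None and self.lam <= 0:
            raise ValidationError("lam must be positive")
        lam = self.lam if self.lam is not None else 1.0 / np.sqrt(max(M.shape))

        norm_m = np.linalg.norm(M)
        if norm_m == 0.0:
            self.low_rank_ = np.zeros_like(M)
            self.sparse_ = np.zeros_like(M)
            self.n_iter_ = 1
            self.converged_ = True
            self.objective_trace_ = [0.0]
            return self

        spec_norm = np.linalg.norm(M, 2)
        # dual scaling of Y follows Lin et al.'s J(M); keeps early iterates tame
        j_m = max(spec_norm, np.abs(M).max() / lam)
        Y = M / j_m
        mu = 1.25 / spec_norm
        rho = 1.5
        E = np.zeros_like(M)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            U, s, Vt = np.linalg.svd(M - E + Y / mu, full_matrices=False)
            s_thr = np.maximum(s - 1.0 / mu, 0.0)
            A = (U * s_thr) @ Vt
            G = M - A + Y / mu
            E = np.sign(G) * np.maximum(np.abs(G) - lam / mu, 0.0)
            Z = M - A - E
            Y = Y + mu * Z
            mu *= rho
            trace.append(float(s_thr.sum() + lam * np.abs(M - A).sum()))
            if np.linalg.norm(Z) / norm_m <= self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"robust PCA did not converge in {self.max_iter} iterations"
            )
        self.low_rank_ = A
        self.sparse_ = E
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_trace_ = trace
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the low-rank component of the fitted matrix."""
        return self.low_rank_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).low_rank_


def rpca_ialm(
    M: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> RpcaResult:
    """Functional wrapper around :class:`RobustPCA`."""
    est = RobustPCA(lam=lam, tol=tol, max_iter=max_iter).fit(M)
    return RpcaResult(
        low_rank=est.low_rank_,
        sparse=est.sparse_,
        iterations=est.n_iter_,
        converged=est.converged_,
        objective_trace=est.objective_trace_,
    )


def clean_recording(
    rec: Recording,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> Recording:
    """Replace a recording's scalp data by its low-rank RPCA component.

    Applied per recording with channels as rows (D << T).  BAD channels are
    zero on input and are kept exactly zero on output.
    """
    scalp_idx = [
        i for i, role in enumerate(rec.channel_roles) if role in ("EEG", "BAD")
    ]
    result = rpca_ialm(rec.data[scalp_idx], lam=lam, tol=tol, max_iter=max_iter)
    data = rec.data.copy()
    data[scalp_idx] = result.low_rank
    data[[i for i in scalp_idx if rec.channel_roles[i] == "BAD"]] = 0.0
    return rec.with_data(data)
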