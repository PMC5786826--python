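"""Correlated component analysis (CorrCA) and per-subject intersubject correlation.

Given N subjects' channel-by-time EEG matrices x_k(t) aligned to a common
stimulus, CorrCA finds spatial projections v that maximize correlation
*between* subjects rather than variance within one.  With the un-normalized
pair covariances

    R_kl = sum_t (x_k(t) - xbar_k)(x_l(t) - xbar_l)^T,

the average within-subject covariance R_w = (1/N) sum_k R_kk and the average
between-subject cross-covariance R_b = (1/(N(N-1))) sum_{k != l} R_kl, the
projections are the eigenvectors of R_w^{-1} R_b.  The per-subject
correlation of component i is

    C_ik = v_i^T R_bk v_i / v_i^T R_wk v_i,
    R_bk = (1/(N-1)) sum_{l != k} (R_kl + R_lk),
    R_wk = (1/(N-1)) sum_{l != k} (R_kk + R_ll),

and a subject's ISC is the sum of C_ik over the first K components
(K = 3 by default).  |C_ik| <= 1 always, by Cauchy–Schwarz.

Zeroed (BAD) channels make R_w rank deficient; the eigenproblem is solved on
the principal subspace of R_w above a relative tolerance, so those channels
contribute exactly nothing.  Forward models a_i = R_w v_i / (v_i^T R_w v_i)
map each component back to expected scalp voltages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io_core import CohortMatrix, ValidationError

DEFAULT_K = 3


@dataclass
class CovarianceSet:
    """All pairwise D x D covariances of a cohort plus their averages."""

    pair_cov: np.ndarray  # (N, N, D, D); [k, l] = R_kl
    Rw: np.ndarray
    Rb: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.pair_cov.shape[0]


@dataclass
class IscResult:
    """Per-subject, per-component correlations and their sum."""

    subjects: list[str]
    per_subject_components: np.ndarray  # (N, K) of C_ik
    isc: np.ndarray  # (N,) row sums
    condition: str = ""
    model_group: str = ""


def pair_cross_covariance(xk: np.ndarray, xl: np.ndarray) -> np.ndarray:
    """Un-normalized cross-covariance R_kl between two subjects' data."""
    xk = np.asarray(xk, dtype=float)
    xl = np.asarray(xl, dtype=float)
    if xk.shape[1] != xl.shape[1]:
        raise ValidationError("subjects must share the same number of samples")
    if xk.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    xkc = xk - xk.mean(axis=1, keepdims=True)
    xlc = xl - xl.mean(axis=1, keepdims=True)
    return xkc @ xlc.T


def assemble_covariances(cohort: CohortMatrix | np.ndarray) -> CovarianceSet:
    """Compute every R_kl and the averages R_w, R_b for a cohort tensor."""
    tensor = cohort.tensor if isinstance(cohort, CohortMatrix) else np.asarray(cohort)
    n, d, t = tensor.shape
    centered = tensor - tensor.mean(axis=2, keepdims=True)
    flat = centered.reshape(n * d, t)
    gram = flat @ flat.T  # one GEMM gives all N^2 blocks
    pair = gram.reshape(n, d, n, d).transpose(0, 2, 1, 3)
    rw = np.einsum("kkij->ij", pair) / n
    rb = (pair.sum(axis=(0, 1)) - np.einsum("kkij->ij", pair)) / (n * (n - 1))
    return CovarianceSet(pair_cov=pair, Rw=rw, Rb=rb)


class CorrCA(BaseEstimator):
    """Correlated component analysis estimator.

    Parameters
    ----------
    n_components :
        Number of components kept (default 3).
    rank_tol :
        Relative eigenvalue threshold on R_w below which directions (e.g.
        zeroed bad channels) are excluded from the whitened subspace.

    Attributes
    ----------
    projections_ : ndarray of shape (D, K)
        Unit-norm projection vectors v_i, strongest component first; sign
        fixed so each vector's largest-magnitude entry is positive.
    eigenvalues_ : ndarray of shape (K,)
        Generalized eigenvalues of (R_b, R_w), descending.
    forward_ : ndarray of shape (D, K)
        Forward-model scalp topographies a_i.
    rank_used_ : int
        Dimension of the retained R_w subspace.
    fit_group_ : list of str
        Subject ids the model was fitted on.
    """

    def __init__(self, n_components: int = DEFAULT_K, rank_tol: float = 1e-9):
        self.n_components = n_components
        self.rank_tol = rank_tol

    def fit(self, X: CohortMatrix | np.ndarray, y=None) -> "CorrCA":
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        covs = assemble_covariances(X)
        self._fit_from_covariances(covs)
        self.fit_group_ = (
            list(X.subjects) if isinstance(X, CohortMatrix) else
            [str(i) for i in range(covs.n_subjects)]
        )
        return self

    def _fit_from_covariances(self, covs: CovarianceSet) -> None:
        rw = 0.5 * (covs.Rw + covs.Rw.T)
        rb = 0.5 * (covs.Rb + covs.Rb.T)
        lam_w, u = np.linalg.eigh(rw)
        keep = lam_w > self.rank_tol * lam_w.max()
        rank = int(keep.sum())
        k = self.n_components
        if rank < k:
            warnings.warn(
                f"effective rank {rank} < requested {k} components; "
                f"returning {rank}"
            )
            k = rank
        if rank == 0:
            raise ValidationError("within-subject covariance is identically zero")
        # whiten within the retained principal subspace of R_w
        w = u[:, keep] / np.sqrt(lam_w[keep])
        rb_white = w.T @ rb @ w
        mu, y = np.linalg.eigh(0.5 * (rb_white + rb_white.T))
        order = np.argsort(mu)[::-1][:k]
        v = w @ y[:, order]
        v /= np.linalg.norm(v, axis=0, keepdims=True)
        # eigenvector sign is arbitrary: make the largest-|entry| positive
        signs = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        v *= signs
        denom = np.einsum("di,de,ei->i", v, rw, v)
        self.projections_ = v
        self.eigenvalues_ = mu[order]
        self.forward_ = (rw @ v) / denom
        self.rank_used_ = rank
        self._covariances_ = covs
        return None

    def transform(self, X: CohortMatrix | np.ndarray) -> np.ndarray:
        """Project each subject's data onto the components: (N, K, T)."""
        tensor = X.tensor if isinstance(X, CohortMatrix) else np.asarray(X)
        return np.einsum("dk,ndt->nkt", self.projections_, tensor)

    def score_subjects(self, X: CohortMatrix | np.ndarray) -> IscResult:
        """Per-subject component correlations C_ik and summed ISC."""
        return subject_isc(X, self)


def fit_corrca(
    covs: CovarianceSet, k: int = DEFAULT_K, rank_tol: float = 1e-9
) -> CorrCA:
    """Fit a :class:`CorrCA` model directly from a precomputed covariance set."""
    model = CorrCA(n_components=k, rank_tol=rank_tol)
    model._fit_from_covariances(covs)
    model.fit_group_ = [str(i) for i in range(covs.n_subjects)]
    return model


def _component_correlations(
    pair: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """C_ik for every subject k and component i from the pair covariances."""
    n = pair.shape[0]
    k_comp = v.shape[1]
    c = np.zeros((n, k_comp))
    diag = np.einsum("kkij->kij", pair)  # R_kk for each k
    sum_pair_k = pair.sum(axis=1)  # sum_l R_kl
    sum_pair_l = pair.sum(axis=0)  # sum_l R_lk
    sum_diag = diag.sum(axis=0)
    for k in range(n):
        rbk = (sum_pair_k[k] - diag[k] + sum_pair_l[k] - diag[k]) / (n - 1)
        rwk = ((n - 2) * diag[k] + sum_diag) / (n - 1)
        num = np.einsum("di,de,ei->i", v, rbk, v)
        den = np.einsum("di,de,ei->i", v, rwk, v)
        with np.errstate(invalid="ignore", divide="ignore"):
            ck = num / den
        degenerate = np.abs(den) < np.finfo(float).tiny
        if degenerate.any():
            warnings.warn("degenerate component variance; setting C_ik to 0")
            ck[degenerate] = 0.0
        c[k, :k_comp] = ck
    if np.any(np.abs(c) > 1 + 1e-9):
        raise AssertionError(
            "per-subject component correlation outside [-1, 1]; "
            "covariance accounting is inconsistent"
        )
    return c


def subject_isc(
    cohort: CohortMatrix | np.ndarray,
    model: CorrCA,
    covs: CovarianceSet | None = None,
) -> IscResult:
    """Per-subject C_ik and ISC = sum_i C_ik for every subject in the cohort."""
    is_cohort = isinstance(cohort, CohortMatrix)
    tensor = cohort.tensor if is_cohort else np.asarray(cohort)
    if model.projections_.shape[0] != tensor.shape[1]:
        raise ValidationError("model dimensionality does not match cohort channels")
    if covs is None:
        covs = assemble_covariances(tensor)
    c = _component_correlations(covs.pair_cov, model.projections_)
    return IscResult(
        subjects=list(cohort.subjects) if is_cohort else
        [str(i) for i in range(tensor.shape[0])],
        per_subject_components=c,
        isc=c.sum(axis=1),
        condition=cohort.condition if is_cohort else "",
    )


def isc_against_group(
    subject_data: np.ndarray,
    cohort: CohortMatrix | np.ndarray,
    model: CorrCA,
) -> tuple[np.ndarray, float]:
    """ISC of one held-out subject against every member of a cohort.

    The cohort plays the role of the "other subjects": the subject's
    R_bk/R_wk averages run over the cohort members only.  For a subject that
    is a member of the cohort this reproduces the corresponding
    :func:`subject_isc` row exactly.
    """
    tensor = cohort.tensor if isinstance(cohort, CohortMatrix) else np.asarray(cohort)
    y = np.asarray(subject_data, dtype=float)
    n_other = tensor.shape[0]
    d = y.shape[0]
    rbk = np.zeros((d, d))
    rwk = np.zeros((d, d))
    ryy = pair_cross_covariance(y, y)
    for l in range(n_other):
        r_yl = pair_cross_covariance(y, tensor[l])
        rbk += r_yl + r_yl.T
        rwk += ryy + pair_cross_covariance(tensor[l], tensor[l])
    rbk /= n_other
    rwk /= n_other
    v = model.projections_
    num = np.einsum("di,de,ei->i", v, rbk, v)
    den = np.einsum("di,de,ei->i", v, rwk, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / den
    degenerate = np.abs(den) < np.finfo(float).tiny
    if degenerate.any():
        warnings.warn("degenerate component variance; setting C_ik to 0")
        c[degenerate] = 0.0
    return c, float(c.sum())


def topography_similarity(model_a: CorrCA, model_b: CorrCA) -> np.ndarray:
    """|cosine| between matching forward-model topographies of two fits.

    Components are matched by index after the descending-eigenvalue sort;
    the absolute value removes the arbitrary eigenvector sign.
    """
    fa, fb = model_a.forward_, model_b.forward_
    if fa.shape[0] != fb.shape[0]:
        raise ValidationError("models have different channel dimensionality")
    k = min(fa.shape[1], fb.shape[1])
    out = np.empty(k)
    for i in range(k):
        na, nb = np.linalg.norm(fa[:, i]), np.linalg.norm(fb[:, i])
        if na == 0 or nb == 0:
            warnings.warn(f"zero-norm forward model for component {i + 1}")
            out[i] = np.nan
        else:
            out[i] = abs(float(fa[:, i] @ fb[:, i]) / (na * nb))
    return out
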