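"""Eigenvalue-spectrum power and dimensionality of a subject's EEG.

The eigenvalues of a subject's channel covariance (normalized by T-1, so
power is per-sample variance) summarize how signal energy spreads over
spatial dimensions.  Their sum is the total power; the slope of
log10(eigenvalue) against log10(rank) measures effective dimensionality —
a shallower (less negative) slope means appreciable power in more
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .io_core import ValidationError


@dataclass
class SpectrumFit:
    """Descending covariance eigenvalues with total power and log-log slope."""

    eigenvalues: np.ndarray
    total_power: float
    slope: float = float("nan")
    intercept: float = float("nan")
    n_used: int = 0


def eigenspectrum(rec_data: np.ndarray) -> SpectrumFit:
    """Eigen-decompose the channel covariance of a channels x samples matrix."""
    x = np.asarray(rec_data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a channels x samples matrix")
    if not np.isfinite(x).all():
        raise ValidationError("data contains non-finite values")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / (x.shape[1] - 1)
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.where(np.abs(lam) < 1e-15 * max(lam.max(), 1.0), 0.0, lam)
    return SpectrumFit(eigenvalues=lam, total_power=float(lam.sum()))


def fit_loglog_slope(fit: SpectrumFit, floor_tol: float = 1e-9) -> SpectrumFit:
    """OLS of log10(lambda_i) on log10(i) over eigenvalues above the floor.

    Eigenvalues below ``floor_tol`` times the largest (e.g. from zeroed bad
    channels) are excluded — their logs are undefined or meaningless.
    """
    lam = fit.eigenvalues
    usable = lam > floor_tol * lam[0]
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValidationError(
            f"need at least 3 eigenvalues above the floor, have {n_used}"
        )
    ranks = np.arange(1, n_used + 1)
    res = sps.linregress(np.log10(ranks), np.log10(lam[:n_used]))
    return replace(
        fit, slope=float(res.slope), intercept=float(res.intercept), n_used=n_used
    )


def subject_spectrum(rec_data: np.ndarray, floor_tol: float = 1e-9) -> SpectrumFit:
    """Eigenspectrum plus fitted slope in one call."""
    return fit_loglog_slope(eigenspectrum(rec_data), floor_tol=floor_tol)
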