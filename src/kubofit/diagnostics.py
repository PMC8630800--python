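"""Parameter covariance, confidence intervals, and multicollinearity
diagnostics.

The parameter variance-covariance matrix is

    V_p = [C(p_hat) / (N_D - N_p)] (J^T W J)^-1,

where the reduced-chi^2 prefactor resolves the arbitrary proportionality
of the weights W to the true inverse data variances: doubling every
weight halves (J^T W J)^-1 but doubles C, leaving V_p unchanged.

The variance inflation factor (VIF) of parameter i is the i-th diagonal
element of the inverse of the column-normalized Gram matrix
(Jhat^T W Jhat)^-1, with Jhat scaled so that the Gram diagonal is one.
Orthogonal columns give VIF = 1 for every parameter; perfect collinearity
sends VIFs to infinity, which is why a true inverse (never a
pseudo-inverse) must be used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "CovarianceReport", "VifReport", "SingularCovarianceError",
    "covariance", "confidence_intervals", "confidence_intervals_from_sigma",
    "vif", "perturbation_propagation",
]

#: VIFs above this are reported as effectively infinite (exact infinity is
#: unreachable in floating point)
HUGE_VIF = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """J^T W J is singular; carries the most collinear parameter pair."""

    def __init__(self, pair=None):
        self.pair = pair
        msg = "singular J^T W J"
        if pair is not None:
            msg += f" (largest |correlation| between parameters {pair[0]} and {pair[1]})"
        super().__init__(msg)


@dataclass
class CovarianceReport:
    vcov: np.ndarray
    sigma: np.ndarray
    dof: int
    scale: float


@dataclass
class VifReport:
    vif: np.ndarray
    condition_flag: bool


def _gram(J: np.ndarray, weights: Optional[np.ndarray]) -> np.ndarray:
    if weights is None:
        return J.T @ J
    return J.T @ (np.asarray(weights, dtype=float).ravel()[:, None] * J)


def _worst_pair(G: np.ndarray):
    d = np.sqrt(np.abs(np.diag(G)))
    d[d == 0] = 1.0
    corr = G / np.outer(d, d)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    return (min(i, j), max(i, j))


def covariance(J: np.ndarray, weights: Optional[np.ndarray],
               cost_at_min: float, n_data: int,
               n_params: int) -> CovarianceReport:
    """Parameter covariance with reduced-chi^2 scaling.

    Raises ``ValueError`` when dof <= 0 and
    :class:`SingularCovarianceError` (naming the most collinear
    parameter pair) when J^T W J cannot be inverted.
    """
    dof = n_data - n_params
    if dof <= 0:
        raise ValueError(f"need n_data > n_params (dof = {dof})")
    G = _gram(J, weights)
    # reject numerically singular systems rather than returning garbage
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= 0 or eig[0] / eig[-1] < 1e-15:
        raise SingularCovarianceError(_worst_pair(G))
    scale = cost_at_min / dof
    vcov = scale * np.linalg.inv(G)
    vcov = 0.5 * (vcov + vcov.T)
    sigma = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    return CovarianceReport(vcov=vcov, sigma=sigma, dof=dof, scale=scale)


def confidence_intervals_from_sigma(sigma: np.ndarray,
                                    level: float) -> np.ndarray:
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + 0.5 * level)
    return z * np.asarray(sigma, dtype=float)


def confidence_intervals(report: CovarianceReport,
                         level: float = 0.95) -> np.ndarray:
    """Per-parameter confidence half-widths z(level) * sigma (normal
    quantiles; N_D >> N_p in every use case here)."""
    return confidence_intervals_from_sigma(report.sigma, level)


def vif(J: np.ndarray, weights: Optional[np.ndarray] = None) -> VifReport:
    """Variance inflation factors from the column-normalized Jacobian.

    Columns are scaled so every diagonal element of Jhat^T W Jhat equals
    one; the VIFs are the diagonal of the true inverse of that matrix.
    Perfect (or numerically perfect) collinearity sets ``condition_flag``
    and reports huge/infinite entries.
    """
    J = np.asarray(J, dtype=float)
    G = _gram(J, weights)
    d = np.diag(G).copy()
    if np.any(d <= 0):
        k = int(np.nonzero(d <= 0)[0][0])
        raise ValueError(f"zero Jacobian column for parameter {k}")
    Ghat = G / np.sqrt(np.outer(d, d))
    flag = False
    try:
        inv = np.linalg.inv(Ghat)
        v = np.diag(inv).copy()
    except np.linalg.LinAlgError:
        flag = True
        v = np.full(G.shape[0], np.inf)
    eig = np.linalg.eigvalsh(Ghat)
    if eig[0] <= 0 or eig[0] / eig[-1] < 1e-14:
        # numerically perfect collinearity: the true inverse is garbage
        # (possibly even negative diagonals); report the blow-up honestly
        flag = True
        v = np.where(np.abs(v) > HUGE_VIF, np.inf, v)
    if np.any(~np.isfinite(v)) or np.any(v > HUGE_VIF) \
            or np.any(v < 1.0 - 1e-6):
        flag = True
    return VifReport(vif=v, condition_flag=flag)


def perturbation_propagation(J: np.ndarray, weights: Optional[np.ndarray],
                             dD: np.ndarray) -> np.ndarray:
    """First-order response of the least-squares optimum to a data
    perturbation: dp = (J^T W J)^-1 J^T W dD."""
    J = np.asarray(J, dtype=float)
    dD = np.asarray(dD, dtype=float).ravel()
    G = _gram(J, weights)
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= 0 or eig[0] / eig[-1] < 1e-15:
        raise SingularCovarianceError(_worst_pair(G))
    wd = dD if weights is None else np.asarray(weights).ravel() * dD
    return np.linalg.solve(G, J.T @ wd)
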