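"""Chi-square transformation and the three ordination variable sets.

Three site-score matrices feed the scalogram analysis: Y, principal axes of
the chi-square-transformed site-by-species table; F, the constrained
(canonical) axes of a redundancy analysis of that table on the environment;
and R, principal axes of the residual after the environmental fit. By the
orthogonality of fitted values and residuals, the F and R variances sum to
the total variance of the transformed table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, EnvMatrix, ValidationError

__all__ = [
    "OrdinationAxes",
    "chisq_transform",
    "pca_axes",
    "rda_axes",
    "partial_residual_axes",
]


@dataclass(frozen=True)
class OrdinationAxes:
    role: str  # "Y" | "F" | "R" (or free-form for ad-hoc PCA)
    site_scores: np.ndarray  # (n_sites, k), centred, mutually orthogonal
    variance_proportions: np.ndarray  # of total variance of the input matrix
    loadings: np.ndarray  # (n_features, k)

    def __post_init__(self) -> None:
        s = self.site_scores
        if np.max(np.abs(s.mean(axis=0))) > 1e-8 * max(1.0, np.max(np.abs(s))):
            raise ValidationError("site scores not centred")
        props = self.variance_proportions
        if np.any(props < -1e-12) or np.any(props > 1 + 1e-12):
            raise ValidationError("variance proportions outside [0, 1]")

    @property
    def k(self) -> int:
        return self.site_scores.shape[1]

    def frame(self, site_ids) -> pd.DataFrame:
        cols = {f"axis{j + 1}": self.site_scores[:, j] for j in range(self.k)}
        return pd.DataFrame({"site_id": list(site_ids), **cols})


def chisq_transform(A: AbundanceMatrix) -> np.ndarray:
    """Chi-square transformation of the count table, up-weighting rare species.

    yhat_ij = sqrt(y_++) * y_ij / (y_i+ * sqrt(y_+j)). Euclidean distances on
    the transformed matrix approximate chi-square distances between site
    profiles; the transform is invariant to a uniform rescaling of counts.
    """
    y = A.values
    row = y.sum(axis=1)
    col = y.sum(axis=0)
    grand = y.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("chi-square transform undefined with zero row/column totals")
    return np.sqrt(grand) * y / (row[:, None] * np.sqrt(col)[None, :])


def _svd_axes(x_centred: np.ndarray, k: int, total_var: float, role: str) -> OrdinationAxes:
    u, s, vt = np.linalg.svd(x_centred, full_matrices=False)
    if s.size and s[0] <= 1e-10 * max(np.sqrt(total_var), 1.0):
        # numerically zero matrix (e.g. perfect environmental filtering):
        # return zero scores rather than failing the rank check
        n, p = x_centred.shape
        return OrdinationAxes(
            role=role,
            site_scores=np.zeros((n, k)),
            variance_proportions=np.zeros(k),
            loadings=np.zeros((p, k)),
        )
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValidationError(f"k={k} exceeds rank {rank}")
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    props = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return OrdinationAxes(
        role=role,
        site_scores=scores,
        variance_proportions=props,
        loadings=vt[:k].T,
    )


def pca_axes(X: np.ndarray, k: int = 2, role: str = "Y") -> OrdinationAxes:
    """Principal axes of a matrix (centred internally), via SVD.

    Variance proportions are squared singular values over their total, i.e.
    fractions of the matrix's own total variance.
    """
    X = np.asarray(X, dtype=float)
    xc = X - X.mean(axis=0)
    total = float((xc**2).sum())
    return _svd_axes(xc, k, total, role)


def _design_matrix(E: EnvMatrix) -> np.ndarray:
    """Standardised environment design: centred, unit variance, aliased columns dropped."""
    data = E.values.copy()
    data = data - data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    keep = sd > 1e-12
    data = data[:, keep] / sd[keep]
    # drop linearly dependent columns (QR with pivoting)
    if data.shape[1]:
        q, r, piv = _qr_pivot(data)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-9 * abs(r[0, 0]))) if r.size else 0
        cols = np.sort(piv[:rank])
        data = data[:, cols]
    return data


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def _fit_on_env(A_or_X, E: EnvMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred response, fitted values and residuals of the multivariate LS fit."""
    X = np.asarray(A_or_X, dtype=float)
    n = X.shape[0]
    if E.data.shape[1] >= n:
        raise ValidationError(
            f"rank deficit: {E.data.shape[1]} environment columns for {n} sites "
            f"(need at least {E.data.shape[1] + 1} sites)"
        )
    design = _design_matrix(E)
    xc = X - X.mean(axis=0)
    if design.shape[1] == 0:
        return xc, np.zeros_like(xc), xc
    coef, *_ = np.linalg.lstsq(design, xc, rcond=None)
    fitted = design @ coef
    return xc, fitted, xc - fitted


def rda_axes(X: np.ndarray, E: EnvMatrix, k: int = 2) -> OrdinationAxes:
    """Constrained (canonical) axes: PCA of the fitted values of X on E.

    Variance proportions are fractions of the *total* variance of centred X,
    so constrained and residual proportions are complementary.
    """
    xc, fitted, _ = _fit_on_env(X, E)
    total = float((xc**2).sum())
    return _svd_axes(fitted, k, total, role="F")


def partial_residual_axes(X: np.ndarray, E: EnvMatrix, k: int = 2) -> OrdinationAxes:
    """Environment-filtered axes: PCA of the residual of X on E (orthogonal to E)."""
    xc, _, resid = _fit_on_env(X, E)
    total = float((xc**2).sum())
    return _svd_axes(resid, k, total, role="R")
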