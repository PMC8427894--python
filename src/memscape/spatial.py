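"""Moran's eigenvector maps, Moran's I permutation tests, and smoothed scalograms.

The MEM basis is the eigendecomposition of the doubly-centred spatial
weighting matrix Omega = C W C, with C = I - (1/n) 11'. For a connected
graph exactly one eigenvalue is null (the centred constant direction); the
remaining n-1 eigenvectors are centred, orthonormal, and ordered by
descending eigenvalue, so leading vectors describe broad-scale spatial
patterns and trailing ones fine-scale alternation. Under binary weights
each eigenvector u_i satisfies the identity I(u_i) = (n/W) * lambda_i,
linking the basis directly to Moran's I.

A scalogram projects a focal site-indexed variable onto the basis: R^2_i is
the squared Pearson correlation with u_i, and because the basis spans the
centred space the R^2 values sum to one. Grouping MEMs into smoothing
windows (by default two windows of equal size: 'broad' = leading half,
'fine' = trailing half) and summing R^2 within each window gives the
smoothed scalogram, tested by permuting the focal values across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AbundanceMatrix, ValidationError
from .connectivity import SpatialWeightMatrix

__all__ = [
    "MEMBasis",
    "MoranResult",
    "ScalogramResult",
    "compute_mems",
    "morans_i",
    "morans_i_test",
    "global_moran_community",
    "scalogram",
    "smoothed_scalogram_test",
    "default_windows",
]

_NULL_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class MEMBasis:
    """Orthonormal, centred spatial eigenvectors with eigenvalues and Moran's I."""

    site_ids: tuple[str, ...]
    vectors: np.ndarray  # (n_sites, n_vectors), columns ordered by descending eigenvalue
    eigenvalues: np.ndarray
    moran_i: np.ndarray  # per-vector Moran's I under the source weights
    graph_kind: str = ""

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_sites(self) -> int:
        return self.vectors.shape[0]

    def vector(self, index: int) -> np.ndarray:
        """1-based MEM accessor: ``vector(1)`` is the broadest-scale MEM."""
        if not 1 <= index <= self.n_vectors:
            raise IndexError(f"MEM index {index} out of 1..{self.n_vectors}")
        return self.vectors[:, index - 1]


@dataclass(frozen=True)
class MoranResult:
    observed: float
    expectation: float  # Monte-Carlo mean of the null draws
    variance: float  # Monte-Carlo variance of the null draws
    analytic_expectation: float  # -1/(n-1), logged alongside
    alternative: str
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class ScalogramResult:
    focal_name: str
    r2: np.ndarray  # per-MEM squared correlation, length n_vectors
    windows: tuple[tuple[int, ...], ...]  # 1-based MEM indices per window
    window_names: tuple[str, ...]
    window_sums: np.ndarray
    p_values: np.ndarray | None = None  # per-window permutation p
    p_max_statistic: float | None = None  # family-wise max-statistic p
    n_perm: int = 0
    seed: int = 0
    null_mean: np.ndarray | None = field(default=None)
    null_sd: np.ndarray | None = field(default=None)


def _centering_projector(n: int) -> np.ndarray:
    return np.eye(n) - np.ones((n, n)) / n


def _fix_signs_and_ties(values: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Deterministic orientation and ordering of eigenvectors.

    Sign: the entry of largest magnitude is made positive (first such entry
    on exact ties). Ties in eigenvalues: columns with equal eigenvalues are
    ordered lexicographically by their entries.
    """
    v = vectors.copy()
    for k in range(v.shape[1]):
        col = v[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            v[:, k] = -col
    # group equal eigenvalues (within relative tolerance) and sort lexicographically
    order = list(range(v.shape[1]))
    scale = max(np.max(np.abs(values)), 1.0)
    start = 0
    while start < len(order):
        stop = start
        while (
            stop + 1 < len(order)
            and abs(values[order[stop + 1]] - values[order[start]]) <= 1e-9 * scale
        ):
            stop += 1
        if stop > start:
            block = sorted(order[start : stop + 1], key=lambda k: tuple(np.round(v[:, k], 12)))
            order[start : stop + 1] = block
        start = stop + 1
    return v[:, order]


def _helmert_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the centred subspace (columns sum to 0)."""
    h = np.zeros((n, n - 1))
    for j in range(1, n):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def compute_mems(W: SpatialWeightMatrix) -> MEMBasis:
    """Eigendecompose the doubly-centred weight matrix into a MEM basis.

    The constant direction (the exact null of the centering projector) is
    deflated by restricting Omega = C W C to an orthonormal basis of the
    centred subspace before eigendecomposition, so a connected n-site graph
    always yields exactly n - 1 centred orthonormal eigenvectors, sorted by
    descending eigenvalue, and the basis spans the whole centred space.
    Structurally null eigenvalues among them (possible for sparse graphs)
    are retained; their count is logged.
    """
    w = W.weights
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ValidationError("weight matrix not symmetric within tolerance")
    n = W.sites.n_sites
    c = _centering_projector(n)
    omega = c @ w @ c
    omega = (omega + omega.T) / 2.0  # guard against round-off asymmetry
    h = _helmert_basis(n)
    reduced = h.T @ omega @ h
    reduced = (reduced + reduced.T) / 2.0
    values, vectors_r = np.linalg.eigh(reduced)
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = h @ vectors_r[:, order]
    scale = max(float(np.max(np.abs(values))), 1.0)
    n_null = int(np.sum(np.abs(values) <= _NULL_EIG_RTOL * scale))
    if n_null:
        import logging

        logging.getLogger("memscape").info(
            "MEM basis has %d structurally null eigenvalue(s)", n_null
        )
    vectors = _fix_signs_and_ties(values, vectors)
    total = W.total_weight
    moran = np.array([morans_i(vectors[:, k], W) for k in range(vectors.shape[1])])
    return MEMBasis(
        site_ids=W.sites.site_ids,
        vectors=vectors,
        eigenvalues=values,
        moran_i=moran,
        graph_kind=W.graph_kind,
    )


def morans_i(x: np.ndarray, W: SpatialWeightMatrix) -> float:
    """Global Moran's I of a site-indexed variable.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = np.asarray(x, dtype=float)
    n = W.sites.n_sites
    if x.shape != (n,):
        raise ValidationError(f"x has shape {x.shape}, expected ({n},)")
    z = x - x.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValidationError("Moran's I undefined for a constant variable")
    return float((n / W.total_weight) * (z @ W.weights @ z) / denom)


def _moran_null_draws(
    x: np.ndarray, W: SpatialWeightMatrix, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Moran's I under random site permutations of x (vectorised)."""
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    perms = np.empty((n_perm, n))
    for b in range(n_perm):
        perms[b] = z[rng.permutation(n)]
    quad = np.einsum("bi,ij,bj->b", perms, W.weights, perms)
    return (n / W.total_weight) * quad / denom


def morans_i_test(
    x: np.ndarray,
    W: SpatialWeightMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MoranResult:
    """Monte-Carlo permutation test of Moran's I.

    The null distribution permutes the variable across sites; the reported
    expectation and variance are the Monte-Carlo moments of the null draws
    (the analytic expectation -1/(n-1) is carried alongside). The p-value is
    (1 + #{null as-or-more extreme}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError(f"n_perm must be >= 99, got {n_perm}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    obs = morans_i(x, W)
    rng = np.random.default_rng(seed)
    null = _moran_null_draws(np.asarray(x, dtype=float), W, n_perm, rng)
    n = W.sites.n_sites
    e_mc = float(null.mean())
    if alternative == "greater":
        extreme = int(np.sum(null >= obs))
    elif alternative == "less":
        extreme = int(np.sum(null <= obs))
    else:
        centre = e_mc
        extreme = int(np.sum(np.abs(null - centre) >= abs(obs - centre)))
    p = (1 + extreme) / (n_perm + 1)
    return MoranResult(
        observed=obs,
        expectation=e_mc,
        variance=float(null.var(ddof=1)),
        analytic_expectation=-1.0 / (n - 1),
        alternative=alternative,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def global_moran_community(
    A: AbundanceMatrix,
    W: SpatialWeightMatrix,
    n_perm: int = 999,
    seed: int = 0,
    axis: int = 1,
    alternative: str = "two-sided",
) -> MoranResult:
    """Global Moran's I test of the community composition gradient.

    The focal variable is the site-score vector of principal axis ``axis`` of
    the chi-square-transformed site-by-species matrix, which up-weights rare
    species before the ordination.
    """
    from .ordination import chisq_transform, pca_axes

    x = pca_axes(chisq_transform(A), k=axis).site_scores[:, axis - 1]
    return morans_i_test(x, W, n_perm=n_perm, seed=seed, alternative=alternative)


def default_windows(n_vectors: int, n_windows: int = 2) -> tuple[tuple[int, ...], ...]:
    """Contiguous near-equal windows of 1-based MEM indices.

    With 22 MEMs and two windows this is the broad (1-11) / fine (12-22)
    smoothing scheme.
    """
    if not 1 <= n_windows <= n_vectors:
        raise ValidationError(f"cannot split {n_vectors} MEMs into {n_windows} windows")
    bounds = np.linspace(0, n_vectors, n_windows + 1).round().astype(int)
    return tuple(
        tuple(range(bounds[w] + 1, bounds[w + 1] + 1)) for w in range(n_windows)
    )


def _window_names(n_windows: int) -> tuple[str, ...]:
    if n_windows == 2:
        return ("broad", "fine")
    return tuple(f"window_{k + 1}" for k in range(n_windows))


def _r2_profile(x: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    z = x - x.mean()
    ss = float(z @ z)
    if ss <= 0:
        raise ValidationError("scalogram undefined for a constant variable")
    proj = vectors.T @ z
    return proj**2 / ss


def scalogram(x: np.ndarray, basis: MEMBasis, name: str = "x") -> ScalogramResult:
    """Per-MEM R^2 of a focal variable: squared correlation with each eigenvector.

    The basis is orthonormal and spans the centred space, so the R^2 values
    sum to one for any non-constant variable.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (basis.n_sites,):
        raise ValidationError("focal variable not aligned to basis sites")
    r2 = _r2_profile(x, basis.vectors)
    windows = default_windows(basis.n_vectors, 2)
    sums = np.array([r2[[i - 1 for i in w]].sum() for w in windows])
    return ScalogramResult(
        focal_name=name,
        r2=r2,
        windows=windows,
        window_names=_window_names(2),
        window_sums=sums,
    )


def smoothed_scalogram_test(
    x: np.ndarray,
    basis: MEMBasis,
    windows: tuple[tuple[int, ...], ...] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    name: str = "x",
    permute: str = "sites",
) -> ScalogramResult:
    """Permutation test of the smoothed scalogram.

    Window sums S_g = sum of R^2 over the MEMs in each window are compared
    with a null distribution; per-window p = (1 + #{null S_g >= observed}) /
    (n_perm + 1). A max-statistic p (observed max_g S_g against the null
    distribution of the max) is reported for family-wise control.

    ``permute="sites"`` (default) permutes the focal values across sites and
    recomputes the whole profile. ``permute="mems"`` instead shuffles MEM
    identities within the full basis before windowing, testing whether the
    observed grouping of R^2 into windows is special given the profile.
    """
    if n_perm < 99:
        raise ValidationError(f"n_perm must be >= 99, got {n_perm}")
    if permute not in ("sites", "mems"):
        raise ValidationError(f"unknown permutation scheme {permute!r}")
    x = np.asarray(x, dtype=float)
    if windows is None:
        windows = default_windows(basis.n_vectors, 2)
    flat = sorted(i for w in windows for i in w)
    if flat != list(range(1, basis.n_vectors + 1)):
        raise ValidationError("windows must partition 1..n_vectors")
    idx = [np.array(w) - 1 for w in windows]
    r2 = _r2_profile(x, basis.vectors)
    sums = np.array([r2[i].sum() for i in idx])

    rng = np.random.default_rng(seed)
    n = basis.n_sites
    null_sums = np.empty((n_perm, len(windows)))
    if permute == "sites":
        z = x - x.mean()
        ss = float(z @ z)
        perms = np.empty((n_perm, n))
        for b in range(n_perm):
            perms[b] = z[rng.permutation(n)]
        prof = (perms @ basis.vectors) ** 2 / ss
        for g, i in enumerate(idx):
            null_sums[:, g] = prof[:, i].sum(axis=1)
    else:
        m = basis.n_vectors
        for b in range(n_perm):
            shuffled = r2[rng.permutation(m)]
            for g, i in enumerate(idx):
                null_sums[b, g] = shuffled[i].sum()
    p = (1 + (null_sums >= sums[None, :]).sum(axis=0)) / (n_perm + 1)
    p_max = float(
        (1 + int(np.sum(null_sums.max(axis=1) >= sums.max()))) / (n_perm + 1)
    )
    return ScalogramResult(
        focal_name=name,
        r2=r2,
        windows=tuple(tuple(w) for w in windows),
        window_names=_window_names(len(windows)),
        window_sums=sums,
        p_values=p,
        p_max_statistic=p_max,
        n_perm=n_perm,
        seed=seed,
        null_mean=null_sums.mean(axis=0),
        null_sd=null_sums.std(axis=0, ddof=1),
    )
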