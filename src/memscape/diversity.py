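"""Diversity estimation: Tsallis entropy, asymptotic Shannon diversity, rarefaction.

Two complementary estimators summarise each community sample. Tsallis
entropy S_q = (1 - sum p_s^q)/(q - 1) is a one-parameter family whose
sensitivity to rare species grows as q falls below 1 (q=0 gives richness
minus one, q->1 recovers Shannon entropy, q=2 relates to Simpson
concentration). The asymptotic Shannon estimator corrects the plug-in
Shannon entropy for unseen species using singleton/doubleton frequencies
and is reported on the effective-species (Hill number) scale as
D_AE = exp(H_hat), so it is comparable across samples of unequal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import AbundanceMatrix, SiteTable, ValidationError

__all__ = [
    "AbundanceVector",
    "tsallis_entropy",
    "asymptotic_shannon",
    "rarefaction_curve",
    "diversity_table",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Species counts of a single site or collection."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.size == 0:
            raise ValidationError("empty abundance vector")
        if np.any(c < 0) or np.any(c != np.round(c)):
            raise ValidationError("counts must be non-negative integers")
        c = c[c > 0]
        if c.size == 0 or c.sum() < 1:
            raise ValidationError("abundance vector has no individuals")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return int(self.counts.size)

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n

    def f(self, k: int) -> int:
        """Frequency count f_k: number of species observed exactly k times."""
        return int(np.sum(self.counts == k))


def tsallis_entropy(v: AbundanceVector | np.ndarray, q: float) -> float:
    """Tsallis entropy S_q of the relative abundances.

    S_q = (1 - sum_s p_s^q) / (q - 1) for q != 1; the q -> 1 limit is the
    Shannon entropy -sum p_s ln p_s, used when q == 1.
    """
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(np.asarray(v))
    if q < 0:
        raise ValidationError(f"q must be >= 0, got {q}")
    p = v.p
    if q == 1.0:
        return float(-(p * np.log(p)).sum())
    return float((1.0 - (p**q).sum()) / (q - 1.0))


def asymptotic_shannon(v: AbundanceVector | np.ndarray) -> float:
    """Asymptotic Shannon diversity D_AE = exp(H_hat), Chao–Jost estimator.

    H_hat sums the finite-sample-corrected terms
    sum_{x=1..n-1 species} (x/n) * sum_{k=x}^{n-1} 1/k
    plus the unseen-species tail
    (f_1/n) (1-A)^{1-n} [-ln A - sum_{r=1}^{n-1} (1-A)^r / r],
    with A = 2 f_2 / ((n-1) f_1 + 2 f_2) when doubletons exist,
    A = 2 / ((n-1)(f_1 - 1) + 2) when only singletons exist, and a zero tail
    when f_1 = 0 (the sample is treated as complete).
    """
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(np.asarray(v))
    n = v.n
    if n < 2:
        raise ValidationError("asymptotic Shannon needs a sample of size >= 2")
    counts = v.counts
    # first part: sum over species with 1 <= x <= n-1 of (x/n) * sum_{k=x}^{n-1} 1/k
    inv = 1.0 / np.arange(1, n)  # 1/1 .. 1/(n-1)
    tail_harmonic = np.concatenate([np.cumsum(inv[::-1])[::-1], [0.0]])  # H(n-1)-H(x-1) at x=1..n
    h = 0.0
    for x in counts:
        if x <= n - 1:
            h += (x / n) * tail_harmonic[x - 1]
    f1, f2 = v.f(1), v.f(2)
    if f1 > 0:
        if f2 > 0:
            a = 2.0 * f2 / ((n - 1.0) * f1 + 2.0 * f2)
        else:
            a = 2.0 / ((n - 1.0) * (f1 - 1.0) + 2.0)
        if a < 1.0:
            r = np.arange(1, n)
            series = float((((1.0 - a) ** r) / r).sum())
            h += (f1 / n) * (1.0 - a) ** (1.0 - n) * (-np.log(a) - series)
    return float(np.exp(h))


def rarefaction_curve(v: AbundanceVector | np.ndarray, depths) -> np.ndarray:
    """Expected species richness in subsamples of size m (hypergeometric).

    E[S_m] = sum_s [1 - C(n - x_s, m) / C(n, m)], evaluated in log space.
    """
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(np.asarray(v))
    n = v.n
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if np.any(depths < 1) or np.any(depths > n):
        raise ValidationError(f"depths must lie in 1..{n}")

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths))
    x = v.counts
    for t, m in enumerate(depths):
        rem = n - x
        with np.errstate(invalid="ignore"):
            ratio = np.where(
                rem >= m,
                np.exp(log_choose(rem.astype(float), int(m)) - log_choose(float(n), int(m))),
                0.0,
            )
        out[t] = float((1.0 - ratio).sum())
    return out


def _per_unit_rows(counts: np.ndarray, q: float) -> dict[str, float]:
    v = AbundanceVector(counts)
    return {
        "richness": v.richness,
        "n_individuals": v.n,
        "S_q": tsallis_entropy(v, q),
        "D_AE": asymptotic_shannon(v) if v.n >= 2 else 1.0,
    }


def diversity_table(
    A: AbundanceMatrix,
    q: float = 0.5,
    metadata: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-site diversity estimates and habitat(-by-season) summaries.

    Counts are aggregated per site (any temporal replication is summed away
    before estimation). Returns ``{"sites": ..., "groups": ...}``; when
    ``metadata`` supplies a ``season`` column per site, group summaries are
    computed per habitat-by-season cell as well as per habitat.
    """
    sites = A.sites
    rows = []
    for i, sid in enumerate(sites.site_ids):
        rec = {"site_id": sid, "habitat": sites.habitat[i]}
        rec.update(_per_unit_rows(A.values[i], q))
        rows.append(rec)
    per_site = pd.DataFrame(rows)
    if metadata is not None and "season" in metadata.columns:
        season = metadata.set_index("site_id")["season"]
        per_site["season"] = per_site["site_id"].map(season)
        group_cols = ["habitat", "season"]
    else:
        group_cols = ["habitat"]
    groups = (
        per_site.groupby(group_cols, observed=True)[["S_q", "D_AE", "richness"]]
        .agg(["mean", "std"])
    )
    groups.columns = ["_".join(c) for c in groups.columns]
    groups = groups.reset_index()
    return {"sites": per_site, "groups": groups}
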