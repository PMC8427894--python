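"""Habitat discrimination: Box-Cox preprocessing, MANOVA with Wilks lambda, LDA.

The comparison at stake is between two predictor sets for the habitat
categories: the two diversity estimates (S_q, D_AE), which are strongly
mutually correlated, and a handful of spatially optimised MEM site scores,
which are mutually orthogonal by construction. Wilks lambda
(det(E)/det(E+H), 0 = perfect separation) with Rao's F approximation gives
the multivariate test; a pooled-covariance Gaussian LDA with uniform or
class-frequency priors gives the classifier, optionally trained on a
stratified half of the sites and tested on the other half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datamodel import ValidationError

__all__ = [
    "PredictorSet",
    "WilksResult",
    "LDAResult",
    "boxcox_preprocess",
    "manova_wilks",
    "lda_fit_predict",
    "rao_wilks_f",
]

#: Box-Cox lambda search grid
BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class PredictorSet:
    """Site-indexed predictor columns with their preprocessing record."""

    data: pd.DataFrame  # index = site_id
    boxcox_lambda: dict = field(default_factory=dict)
    shift: dict = field(default_factory=dict)
    centre: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass(frozen=True)
class WilksResult:
    wilks_lambda: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    E: np.ndarray  # within-group (error) cross-products
    H: np.ndarray  # hypothesis (between-group) cross-products
    univariate: pd.DataFrame  # per-predictor ANOVA rows


@dataclass(frozen=True)
class LDAResult:
    priors_mode: str
    priors: np.ndarray
    classes: tuple[str, ...]
    scalings: np.ndarray  # discriminant directions (columns)
    scores: pd.DataFrame  # per-site discriminant scores
    predicted: pd.Series
    confusion: pd.DataFrame  # rows = true class, cols = predicted
    accuracy: float
    train_sites: tuple[str, ...] | None = None
    test_sites: tuple[str, ...] | None = None


def boxcox_preprocess(P: PredictorSet | pd.DataFrame) -> PredictorSet:
    """Box-Cox transform each column (grid MLE of lambda), then centre and scale.

    Non-positive columns are shifted to be strictly positive first; the
    shift, the selected lambda and the centring/scaling constants are all
    recorded so the transform is reportable.
    """
    df = P.data if isinstance(P, PredictorSet) else P
    out = {}
    lambdas: dict = {}
    shifts: dict = {}
    centres: dict = {}
    scales: dict = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        if np.std(x, ddof=1) <= 1e-12:
            raise ValidationError(f"zero-variance predictor column {name!r}")
        shift = 0.0
        if x.min() <= 0:
            span = x.max() - x.min()
            shift = -x.min() + 0.05 * (span if span > 0 else 1.0)
            x = x + shift
        llf = np.array([stats.boxcox_llf(lmb, x) for lmb in BOXCOX_GRID])
        lmb = float(BOXCOX_GRID[int(np.argmax(llf))])
        t = stats.boxcox(x, lmbda=lmb)
        c, s = float(t.mean()), float(t.std(ddof=1))
        out[name] = (t - c) / s
        lambdas[name], shifts[name], centres[name], scales[name] = lmb, shift, c, s
    return PredictorSet(
        data=pd.DataFrame(out, index=df.index),
        boxcox_lambda=lambdas,
        shift=shifts,
        centre=centres,
        scale=scales,
    )


def rao_wilks_f(lmb: float, p: int, g: int, n: int) -> tuple[float, float, float, float]:
    """Rao's F approximation to the Wilks lambda distribution.

    Returns (F, df1, df2, p_value). With p predictors, g groups and n
    observations: q = g - 1, df1 = p*q,
    t = sqrt((p^2 q^2 - 4)/(p^2 + q^2 - 5)) (1 if the denominator is <= 0),
    m = n - 1 - (p + q + 1)/2, df2 = m*t - df1/2 + 1, and
    F = ((1 - L^(1/t))/L^(1/t)) * (df2/df1). Exact for p <= 2 or q <= 2.
    """
    q = g - 1
    df1 = p * q
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + q + 1) / 2.0
    df2 = m * t - df1 / 2.0 + 1.0
    lam_t = lmb ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * (df2 / df1)
    p_value = float(stats.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), p_value


def manova_wilks(P: PredictorSet | pd.DataFrame, labels) -> WilksResult:
    """One-way MANOVA of the predictor set on class labels, with Wilks lambda.

    Also reports the per-predictor univariate ANOVA rows (sums of squares,
    mean squares, F and p) in the style of a sequential predictor table.
    """
    df = P.data if isinstance(P, PredictorSet) else P
    x = df.to_numpy(dtype=float)
    labels = np.asarray([str(lbl) for lbl in labels])
    classes, counts = np.unique(labels, return_counts=True)
    n, p = x.shape
    g = len(classes)
    if g < 2 or np.any(counts < 2):
        raise ValidationError("need >= 2 classes with >= 2 members each")
    if n <= p + g:
        raise ValidationError(f"too few observations ({n}) for {p} predictors and {g} classes")
    grand = x.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for cls, n_c in zip(classes, counts):
        xc = x[labels == cls]
        mu = xc.mean(axis=0)
        dev = xc - mu
        E += dev.T @ dev
        d = (mu - grand)[:, None]
        H += n_c * (d @ d.T)
    det_e = np.linalg.det(E)
    det_t = np.linalg.det(E + H)
    if det_t <= 0 or det_e < 0:
        raise ValidationError("singular cross-product matrix; reduce predictors")
    lmb = float(det_e / det_t)
    f, df1, df2, p_value = rao_wilks_f(lmb, p, g, n)

    uni_rows = []
    for j, name in enumerate(df.columns):
        ss_b, ss_w = float(H[j, j]), float(E[j, j])
        df_b, df_w = g - 1, n - g
        ms_b, ms_w = ss_b / df_b, ss_w / df_w
        f_j = ms_b / ms_w
        uni_rows.append(
            {
                "predictor": name,
                "df": df_b,
                "sum_sq": ss_b,
                "mean_sq": ms_b,
                "f_value": f_j,
                "p_value": float(stats.f.sf(f_j, df_b, df_w)),
                "resid_df": df_w,
                "resid_sum_sq": ss_w,
                "resid_mean_sq": ms_w,
            }
        )
    return WilksResult(
        wilks_lambda=lmb,
        f_value=f,
        df1=df1,
        df2=df2,
        p_value=p_value,
        E=E,
        H=H,
        univariate=pd.DataFrame(uni_rows),
    )


def _stratified_half(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Train indices by per-class split; falls back to simple random if any class < 2."""
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.all(counts >= 2):
        train: list[int] = []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            k = max(1, int(round(fraction * len(idx))))
            k = min(k, len(idx) - 1)  # keep at least one test member per class
            train.extend(idx[:k].tolist())
        return np.sort(np.array(train))
    k = max(1, int(round(fraction * n)))
    return np.sort(rng.permutation(n)[:k])


def lda_fit_predict(
    P: PredictorSet | pd.DataFrame,
    labels,
    priors: str = "uniform",
    split_fraction: float | None = None,
    seed: int = 0,
) -> LDAResult:
    """Pooled-covariance Gaussian LDA with configurable priors.

    ``priors="uniform"`` assigns equal prior probability to every class;
    ``"frequency"`` uses the observed class frequencies. With
    ``split_fraction`` the sites are divided (stratified by class when class
    sizes permit) into a training and a test half; the confusion matrix and
    accuracy then describe the held-out half. A class absent from the
    training half raises rather than silently resampling.
    """
    df = P.data if isinstance(P, PredictorSet) else P
    x = df.to_numpy(dtype=float)
    site_ids = [str(s) for s in df.index]
    labels = np.asarray([str(lbl) for lbl in labels])
    classes = np.unique(labels)
    if priors == "uniform":
        prior_vec = np.full(len(classes), 1.0 / len(classes))
    elif priors == "frequency":
        prior_vec = np.array([(labels == c).mean() for c in classes])
    else:
        raise ValidationError(f"unknown prior mode {priors!r}")

    if split_fraction is not None:
        if not 0.0 < split_fraction < 1.0:
            raise ValidationError("split_fraction must be in (0, 1)")
        rng = np.random.default_rng(seed)
        train_idx = _stratified_half(labels, split_fraction, rng)
        test_idx = np.setdiff1d(np.arange(len(labels)), train_idx)
        missing = set(classes) - set(labels[train_idx])
        if missing:
            raise ValidationError(f"class(es) absent from training half: {sorted(missing)}")
    else:
        train_idx = np.arange(len(labels))
        test_idx = train_idx

    model = LinearDiscriminantAnalysis(priors=prior_vec, solver="svd")
    model.fit(x[train_idx], labels[train_idx])
    predicted = model.predict(x[test_idx])
    scores_all = model.transform(x)
    n_axes = scores_all.shape[1]
    scores = pd.DataFrame(
        scores_all,
        index=site_ids,
        columns=[f"LD{j + 1}" for j in range(n_axes)],
    )
    truth = labels[test_idx]
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, pr in zip(truth, predicted):
        conf.loc[t, pr] += 1
    acc = float(np.mean(predicted == truth))
    return LDAResult(
        priors_mode=priors,
        priors=prior_vec,
        classes=tuple(classes),
        scalings=model.scalings_[:, :n_axes],
        scores=scores,
        predicted=pd.Series(predicted, index=[site_ids[i] for i in test_idx]),
        confusion=conf,
        accuracy=acc,
        train_sites=tuple(site_ids[i] for i in train_idx) if split_fraction else None,
        test_sites=tuple(site_ids[i] for i in test_idx) if split_fraction else None,
    )
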