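"""Statistical comparison and ordination of cell-shape feature tables.

Univariate: Welch's unequal-variance two-tailed t-test per descriptor, with
family-wise error control over the 29 descriptors by the Holm step-down
procedure, and percent differences reported relative to the low-metastatic
group mean.

Multivariate: PCA on z-scored descriptors via SVD; nonmetric
multidimensional scaling (NMDS) at k=3 on Bray-Curtis dissimilarities of
max-relativized descriptors, minimizing Kruskal stress-1 by alternating
isotonic regression with Guttman-transform updates (nonmetric SMACOF), from
a principal-coordinates start plus random restarts; PERMANOVA for the
proportion of distance variation explained by a grouping factor (R^2) with
a permutation p-value; and covariance-based 95% confidence ellipses for
plotting group clouds in ordination space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


# ---------------------------------------------------------------------------
# univariate testing


@dataclass
class PairwiseTestResult:
    descriptor: str
    t_statistic: float
    df: float
    p_value: float
    mean_low: float
    mean_high: float
    percent_difference: float  # high vs low, % of the low mean


@dataclass
class HolmDecision:
    p_values: np.ndarray             # original order
    thresholds: np.ndarray           # alpha/(m-i+1) aligned to the sorted order
    reject: np.ndarray               # flags, original order
    alpha: float


def welch_t_test(x, y, descriptor: str = "") -> PairwiseTestResult:
    """Two-tailed Welch t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            # identical constant samples: no evidence of difference
            return PairwiseTestResult(descriptor, 0.0, float(len(x) + len(y) - 2),
                                      1.0, float(y.mean()), float(x.mean()),
                                      _pct(float(x.mean()), float(y.mean())))
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return PairwiseTestResult(
        descriptor=descriptor,
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_low=float(y.mean()),
        mean_high=float(x.mean()),
        percent_difference=_pct(float(x.mean()), float(y.mean())),
    )


def percent_difference(mean_high: float, mean_low: float) -> float:
    """100 * (high - low) / low; sign follows the high-vs-low ordering."""
    if mean_low == 0:
        raise ValueError("zero baseline mean")
    return _pct(mean_high, mean_low)


def _pct(mean_high: float, mean_low: float) -> float:
    if mean_low == 0:
        raise ValueError("zero baseline mean")
    return 100.0 * (mean_high - mean_low) / mean_low


def holm_bonferroni(p_values, alpha: float = 0.05) -> HolmDecision:
    """Holm step-down: sort ascending, reject p(i) while
    p(i) <= alpha/(m - i + 1), stop at the first failure."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    reject_sorted = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    return HolmDecision(p_values=p, thresholds=thresholds, reject=reject, alpha=alpha)


def compare_groups(table: pd.DataFrame, descriptors, group_col: str,
                   high_label: str, low_label: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Welch tests on every descriptor plus Holm flags, as a tidy frame."""
    results = []
    for d in descriptors:
        x = table.loc[table[group_col] == high_label, d].to_numpy()
        y = table.loc[table[group_col] == low_label, d].to_numpy()
        results.append(welch_t_test(x, y, descriptor=d))
    decision = holm_bonferroni([r.p_value for r in results], alpha=alpha)
    return pd.DataFrame(
        {
            "descriptor": [r.descriptor for r in results],
            "t": [r.t_statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "mean_low": [r.mean_low for r in results],
            "mean_high": [r.mean_high for r in results],
            "percent_difference": [r.percent_difference for r in results],
            "significant_holm": decision.reject,
        }
    )


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    method: str
    coordinates: np.ndarray
    variance_fraction: np.ndarray | None = None      # PCA
    loadings: np.ndarray | None = None               # PCA
    stress: float | None = None                      # NMDS
    converged: bool | None = None
    n_starts: int | None = None
    r_squared: float | None = None                   # PERMANOVA
    pseudo_f: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    columns: list[str] = field(default_factory=list)


def _drop_constant(X: np.ndarray, names):
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=3)
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def pca_svd(table: pd.DataFrame | np.ndarray, columns=None) -> OrdinationResult:
    """PCA of z-scored columns via singular value decomposition."""
    if isinstance(table, pd.DataFrame):
        columns = list(columns) if columns is not None else list(table.columns)
        X = table[columns].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        columns = list(columns) if columns is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
    if X.shape[0] <= 3:
        raise ValueError("PCA needs more than 3 rows")
    X, columns = _drop_constant(X, columns)
    if X.shape[1] < 4:
        raise ValueError("fewer than 4 non-constant columns")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U * S
    var = S**2 / (X.shape[0] - 1)
    return OrdinationResult(
        method="pca",
        coordinates=scores,
        variance_fraction=var / var.sum(),
        loadings=Vt.T,
        columns=columns,
    )


def relativize_by_max(table: pd.DataFrame | np.ndarray, columns=None):
    """Divide every descriptor column by its own maximum (values in (0, 1])."""
    if isinstance(table, pd.DataFrame):
        cols = list(columns) if columns is not None else list(table.columns)
        out = table.copy()
        maxima = out[cols].max(axis=0)
        if (maxima <= 0).any():
            raise ValueError("non-positive column maximum")
        out[cols] = out[cols] / maxima
        return out
    X = np.asarray(table, dtype=float)
    maxima = X.max(axis=0)
    if (maxima <= 0).any():
        raise ValueError("non-positive column maximum")
    return X / maxima


def bray_curtis(table: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix: d = sum|x-y| / sum(x+y)."""
    X = np.asarray(table, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    sums = X.sum(axis=1)
    pair_sums = sums[:, None] + sums[None, :]
    np.fill_diagonal(pair_sums, 1.0)
    if (pair_sums == 0).any():
        raise ValueError("a pair of rows sums to zero; dissimilarity undefined")
    return squareform(pdist(X, metric="braycurtis"))


def _kruskal_stress(dissim_flat: np.ndarray, dist_flat: np.ndarray,
                    iso: IsotonicRegression) -> tuple[float, np.ndarray]:
    dhat = iso.fit_transform(dissim_flat, dist_flat)
    denom = float(np.sum(dist_flat**2))
    if denom == 0:
        return np.inf, dhat
    return float(np.sqrt(np.sum((dist_flat - dhat) ** 2) / denom)), dhat


def pcoa_coordinates(D: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) MDS / principal coordinates of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w_k)


def nmds(dissimilarity: np.ndarray, k: int = 3, n_starts: int = 20,
         max_iter: int = 500, tol: float = 1e-7,
         seed: int = 0, return_history: bool = False) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Each start alternates isotonic regression of configuration distances on
    the ranked dissimilarities with a Guttman-transform update of the
    configuration; the first start is the principal-coordinates (metric)
    embedding, the rest are random.  The best (lowest-stress) converged
    configuration is retained.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if k >= n:
        raise ValueError("k must be < number of objects")
    iu = np.triu_indices(n, 1)
    d_flat = D[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, bool] | None = None
    history: list[list[float]] = []
    for start in range(max(1, n_starts)):
        if start == 0:
            X = pcoa_coordinates(D, k)
        else:
            X = rng.normal(size=(n, k)) * d_flat.mean()
        stress_prev = np.inf
        converged = False
        trace: list[float] = []
        for _ in range(max_iter):
            dist = squareform(pdist(X))
            dist_flat = dist[iu]
            stress, dhat_flat = _kruskal_stress(d_flat, dist_flat, iso)
            trace.append(stress)
            if stress_prev - stress < tol:
                converged = True
                break
            stress_prev = stress
            # Guttman transform toward the isotonic fits
            dhat = np.zeros_like(dist)
            dhat[iu] = dhat_flat
            dhat += dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / np.where(dist > 0, dist, 1.0), 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
            X -= X.mean(axis=0)
        history.append(trace)
        if best is None or stress < best[0]:
            best = (stress, X.copy(), converged)

    stress, X, converged = best
    result = OrdinationResult(
        method="nmds", coordinates=X, stress=stress, converged=converged,
        n_starts=max(1, n_starts), seed=seed,
    )
    if return_history:
        result.history = history  # type: ignore[attr-defined]
    return result


def rotate_and_center(coordinates: np.ndarray) -> np.ndarray:
    """Center a configuration and rotate it onto its principal axes so the
    first dimension carries the most variance; rigid, distance-preserving."""
    X = np.asarray(coordinates, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need k >= 2 dimensions")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ Vt.T


def permanova(dissimilarity: np.ndarray, labels,
              n_permutations: int = 999, seed: int = 0) -> OrdinationResult:
    """One-factor PERMANOVA on a distance matrix.

    R^2 = (SS_total - SS_within) / SS_total with SS computed from squared
    distances; the p-value permutes group labels (with the +1 correction).
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    D2 = D**2
    iu = np.triu_indices(n, 1)
    ss_total = D2[iu].sum() / n

    def ss_within(lab: np.ndarray) -> float:
        ss = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = D2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss

    ssw = ss_within(labels)
    ssb = ss_total - ssw
    df_between = len(groups) - 1
    df_within = n - len(groups)
    with np.errstate(divide="ignore"):  # ssw = 0 on perfectly separated clusters
        f_obs = (ssb / df_between) / (ssw / df_within)
    r2 = ssb / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ssw_p = ss_within(perm)
        with np.errstate(divide="ignore"):
            f_p = ((ss_total - ssw_p) / df_between) / (ssw_p / df_within)
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return OrdinationResult(
        method="permanova", coordinates=np.empty((0, 0)),
        r_squared=float(r2), pseudo_f=float(f_obs), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
    )


@dataclass
class EllipseParams:
    center: np.ndarray
    width: float    # full axis along the first eigenvector
    height: float
    angle_deg: float
    level: float


def confidence_ellipse(coordinates: np.ndarray, labels=None,
                       level: float = 0.95) -> dict[str, EllipseParams]:
    """Per-group covariance ellipse at the chi-squared(2) quantile of
    ``level`` (a 95% region of the fitted Gaussian by default), using the
    first two ordination dimensions."""
    X = np.asarray(coordinates, dtype=float)[:, :2]
    if labels is None:
        labels = np.zeros(len(X), dtype=int)
    labels = np.asarray(labels)
    out: dict[str, EllipseParams] = {}
    q = sps.chi2.ppf(level, df=2) if level > 0 else 0.0
    for g in np.unique(labels):
        pts = X[labels == g]
        if len(pts) < 3:
            raise ValueError(f"group {g!r} has < 3 points")
        cov = np.cov(pts.T)
        w, v = np.linalg.eigh(cov)
        if w.min() <= 0:
            raise ValueError(f"degenerate covariance for group {g!r}")
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        out[str(g)] = EllipseParams(
            center=pts.mean(axis=0),
            width=2.0 * np.sqrt(w[0] * q),
            height=2.0 * np.sqrt(w[1] * q),
            angle_deg=float(np.degrees(np.arctan2(v[1, 0], v[0, 0]))),
            level=level,
        )
    return out


# ---------------------------------------------------------------------------
# power simulation


def welch_power_simulation(n_per_group: int = 100, effect_sd: float = 0.5,
                           alpha: float = 0.01, n_replicates: int = 20000,
                           seed: int = 0) -> float:
    """Monte-Carlo power of the Welch two-tailed test for a mean shift of
    ``effect_sd`` standard deviations; vectorized over replicates."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_replicates, n_per_group)) + effect_sd
    y = rng.standard_normal((n_replicates, n_per_group))
    res = sps.ttest_ind(x, y, axis=1, equal_var=False)
    return float(np.mean(res.pvalue < alpha))
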