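"""Profile normalization, ordination, correlation structure and statistics.

Compound profiles are compositional: each sample's terpene (or
cannabinoid) vector is divided by its row sum so values become shares of
the measured common panel.  Ordination is centered PCA on those shares.
Pairwise association is Spearman rank correlation with pairwise-complete
observations and Bonferroni control over the p(p-1)/2 comparisons; the
correlation matrix is ordered by average-linkage clustering for display
and thresholded into a co-occurrence network.

The group-comparison statistics used throughout the package live here:
Welch's unequal-variance t-test, the equal-weight-variance effect size

    d' = (mean1 - mean2) / sqrt((var1 + var2) / 2),

and the Pearson chi-squared goodness-of-fit test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import ChemovarError

# --- normalization ----------------------------------------------------------


@dataclass
class NormalizedProfileMatrix:
    """Row-normalized compound shares; all-zero rows flagged, not divided."""

    data: pd.DataFrame
    all_zero: pd.Series  # boolean flag per row

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def normalize_profiles(matrix: pd.DataFrame) -> NormalizedProfileMatrix:
    """Convert a nonnegative compound matrix to row shares.

    Nulls are filled with zeros (the convention for multivariate
    analysis of these panels), then each row is divided by its sum.
    All-zero rows are flagged and left as zeros.
    """
    df = pd.DataFrame(matrix).astype(float)
    if (df.fillna(0.0) < 0).any().any():
        raise ChemovarError("negative entries are not valid compound measurements")
    filled = df.fillna(0.0)
    sums = filled.sum(axis=1)
    all_zero = sums == 0
    safe = sums.where(~all_zero, 1.0)
    return NormalizedProfileMatrix(data=filled.div(safe, axis=0), all_zero=all_zero)


# --- PCA --------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_rows, n_components)
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance_ratio: np.ndarray
    feature_names: list[str] | None = None


def pca(matrix, n_components: int | None = None) -> PcaResult:
    """Centered (unscaled) PCA with a fixed sign convention.

    Components are ordered by decreasing variance; each component is
    flipped, if needed, so its largest-magnitude loading is positive.
    """
    if isinstance(matrix, NormalizedProfileMatrix):
        names = list(matrix.data.columns)
        X = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        names = None
        X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ChemovarError("PCA requires at least 2 rows")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # (features, components)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
        feature_names=names,
    )


# --- rank correlation -------------------------------------------------------


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 1.0
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = (xc * yc[list(perm)]).sum() / denom
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Pairs with a null in either variable are excluded; fewer than 3
    complete pairs raises.  Ties receive average ranks.  The p-value is
    exact (full permutation enumeration) for n <= 8 and the usual
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ChemovarError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ChemovarError("Spearman correlation requires >= 3 complete pairs")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= 8:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, rho)
    return rho, float(p)


@dataclass
class CorrelationMatrix:
    """All-pairs Spearman coefficients with Bonferroni-masked significance."""

    corr: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at alpha / m
    m: int  # number of pairwise comparisons, p(p-1)/2
    alpha: float
    failed_pairs: list[tuple[str, str]]


def correlation_matrix(matrix: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlations over the columns of ``matrix``.

    Pairs with too few complete observations are flagged (NaN
    coefficient, not significant) rather than fatal.
    """
    df = pd.DataFrame(matrix).astype(float)
    cols = list(df.columns)
    p = len(cols)
    if p < 2:
        raise ChemovarError("correlation matrix requires >= 2 compounds")
    m = p * (p - 1) // 2
    corr = pd.DataFrame(np.eye(p), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((p, p)), index=cols, columns=cols)
    sig = pd.DataFrame(np.zeros((p, p), dtype=bool), index=cols, columns=cols)
    threshold = bonferroni_alpha(alpha, m)
    failed: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            try:
                r, pv = spearman(df[cols[i]], df[cols[j]])
            except ChemovarError:
                failed.append((cols[i], cols[j]))
                r, pv = np.nan, np.nan
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = pv
            s = bool(pv < threshold) if not np.isnan(pv) else False
            sig.iloc[i, j] = sig.iloc[j, i] = s
    return CorrelationMatrix(corr, pvals, sig, m, alpha, failed)


def hierarchical_order(corr: CorrelationMatrix | pd.DataFrame) -> list:
    """Average-linkage dendrogram leaf order of a correlation matrix.

    Distances are Euclidean between rows of the correlation matrix
    (standard clustermap behavior).  Used for display ordering only.
    """
    mat = corr.corr if isinstance(corr, CorrelationMatrix) else pd.DataFrame(corr)
    names = list(mat.index)
    if len(names) == 1:
        return names
    Z = linkage(pdist(mat.to_numpy(dtype=float), metric="euclidean"), method="average")
    return [names[i] for i in leaves_list(Z)]


def threshold_network(
    corr: CorrelationMatrix | pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.DataFrame, list]:
    """Edges where the (signed) coefficient is >= ``threshold``.

    Returns ``(edges, nodes)``: an edge table with columns source,
    target, weight, and the full node list (isolated nodes retained).
    """
    if not 0 < threshold <= 1:
        raise ChemovarError("threshold must lie in (0, 1]")
    mat = corr.corr if isinstance(corr, CorrelationMatrix) else pd.DataFrame(corr)
    names = list(mat.index)
    rows = []
    vals = mat.to_numpy(dtype=float)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not np.isnan(vals[i, j]) and vals[i, j] >= threshold:
                rows.append((names[i], names[j], float(vals[i, j])))
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    return edges, names


def network_graph(edges: pd.DataFrame, nodes: list):
    """Build a networkx Graph from a thresholded edge list (display aid)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=row.weight)
    return g


# --- univariate statistics --------------------------------------------------


def mad_outlier_mask(x, threshold: float = 3.5) -> np.ndarray:
    """Outlier mask via the modified z-score 0.6745 (x - median) / MAD.

    True where |z| exceeds ``threshold``.  A zero MAD (at least half the
    values identical) flags nothing.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ChemovarError("MAD outlier detection requires >= 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(len(x), dtype=bool)
    z = 0.6745 * (x - med) / mad
    return np.abs(z) > threshold


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Two zero-variance samples with equal means return (0.0, 1.0) by
    convention rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ChemovarError("Welch's t-test requires >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (math.inf if x.mean() > y.mean() else -math.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def cohens_d_prime(x, y) -> float:
    """Signed effect size (mean1 - mean2) / sqrt((var1 + var2) / 2).

    Sample variances (ddof=1).  Raises when both variances are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ChemovarError("d' requires >= 2 values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ChemovarError("d' undefined when both variances are zero")
    return float((x.mean() - y.mean()) / math.sqrt((v1 + v2) / 2.0))


def chi_squared_gof(observed, expected_proportions) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit against expected proportions.

    Expected counts are N * proportions with df = k - 1.  A zero
    expected count is an error.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if np.any(obs < 0):
        raise ChemovarError("observed counts must be nonnegative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ChemovarError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if np.any(expected == 0):
        raise ChemovarError("zero expected count in a cell")
    x2, p = stats.chisquare(obs, expected)
    return float(x2), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison significance level alpha / m."""
    if m < 1:
        raise ChemovarError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ChemovarError("alpha must lie in (0, 1)")
    return alpha / m
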