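"""Label-consistency statistics against shuffled-name bootstrap nulls.

A "product" is the mean chemical profile of all samples sharing a
(producer, strain name) pair.  If strain names carry chemical meaning,
products with the same name should have more similar terpene profiles
than products paired at random.  The machinery here quantifies that:

* cosine similarity between normalized terpene profiles;
* per-chemotype product diversity (mean pairwise cosine distance);
* strain eligibility (>= 5 producers with >= 5 samples each);
* per-strain mean between-product similarity, tested against a
  shuffled-name bootstrap null (names permuted over products, the
  product-count-weighted mean strain similarity recomputed per
  replicate, 200 replicates by default);
* the share of a strain's products in its modal k-means cluster,
  against the analogous shuffled-cluster null;
* chi-squared enrichment of Indica/Hybrid/Sativa labels within clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _pairwise_cosine

from . import panels
from .chemometrics import bonferroni_alpha, chi_squared_gof, cohens_d_prime, welch_t
from .errors import ChemovarError


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (|u| |v|); zero-norm vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ChemovarError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def cosine_distance(u, v) -> float:
    return 1.0 - cosine_similarity(u, v)


def _profile_matrix(products: pd.DataFrame, profile_cols) -> np.ndarray:
    mat = products[list(profile_cols)].fillna(0.0).to_numpy(dtype=float)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ChemovarError("product with an all-zero profile; filter before use")
    return mat


def _mean_offdiag(sim_block: np.ndarray) -> np.ndarray:
    """Row means of a similarity block with the self-pair excluded."""
    n = sim_block.shape[0]
    return (sim_block.sum(axis=1) - np.diag(sim_block)) / (n - 1)


@dataclass
class NullDistribution:
    """Replicate statistics from a shuffled-label bootstrap."""

    values: np.ndarray
    reps: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.reps > 1 else 0.0


# --- product diversity ------------------------------------------------------


@dataclass
class DiversityResult:
    per_product: dict[str, pd.Series]  # chemotype -> per-product mean distance
    comparisons: pd.DataFrame
    bootstrap_means: dict[str, np.ndarray] | None = None


def product_diversity(
    products: pd.DataFrame,
    profile_cols=panels.TERPENES,
    chemotype_col: str = "chemotype",
    alpha: float = 0.05,
    subsample_size: int | None = None,
    reps: int = 0,
    seed: int = 0,
) -> DiversityResult:
    """Within-chemotype terpene diversity as mean pairwise cosine distance.

    Each product gets the mean cosine distance to every other product of
    its chemotype; chemotype distributions are compared pairwise with
    Welch's t and d' (Bonferroni over the number of pairs).  Optionally,
    an equal-n bootstrap (``subsample_size`` products per chemotype,
    ``reps`` replicates) checks robustness to unequal group sizes.
    """
    per_product: dict[str, pd.Series] = {}
    groups: dict[str, np.ndarray] = {}
    for chemotype, grp in products.groupby(chemotype_col):
        if len(grp) < 2:
            warnings.warn(f"chemotype {chemotype!r} has < 2 products; excluded")
            continue
        mat = _profile_matrix(grp, profile_cols)
        dist = 1.0 - _pairwise_cosine(mat)
        per_product[chemotype] = pd.Series(_mean_offdiag(dist), index=grp.index)
        groups[chemotype] = mat
    pairs = list(combinations(per_product, 2))
    threshold = bonferroni_alpha(alpha, max(len(pairs), 1))
    rows = []
    for a, b in pairs:
        t, p = welch_t(per_product[a], per_product[b])
        d = cohens_d_prime(per_product[a], per_product[b])
        rows.append((a, b, t, p, d, bool(p < threshold)))
    comparisons = pd.DataFrame(
        rows, columns=["chemotype_a", "chemotype_b", "t", "p", "d_prime", "significant"]
    )
    boot = None
    if reps > 0:
        rng = np.random.default_rng(seed)
        size = subsample_size or min(len(m) for m in groups.values())
        boot = {c: np.empty(reps) for c in groups}
        for c, mat in groups.items():
            n = mat.shape[0]
            for r in range(reps):
                idx = rng.choice(n, size=min(size, n), replace=False)
                sub = 1.0 - _pairwise_cosine(mat[idx])
                boot[c][r] = float(np.mean(_mean_offdiag(sub)))
    return DiversityResult(per_product, comparisons, boot)


# --- strain consistency -----------------------------------------------------


def eligible_strains(
    products: pd.DataFrame, min_producers: int = 5, min_samples: int = 5
) -> list[str]:
    """Strain names with >= ``min_producers`` products of >= ``min_samples``.

    Each product row must carry its sample count in ``n_samples``.
    """
    big = products[products["n_samples"] >= min_samples]
    counts = big.groupby("strain_name").size()
    return sorted(counts[counts >= min_producers].index)


def strain_consistency(
    products: pd.DataFrame,
    strains: list[str],
    profile_cols=panels.TERPENES,
    null: NullDistribution | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean between-product cosine similarity per strain name.

    Each product's score is its mean similarity to the *other* products
    of the same strain (self-pairs excluded).  When a shuffled-name
    ``null`` is supplied, each strain's product scores are compared to
    the null replicate vector with Welch's t and d', Bonferroni over the
    number of strains.
    """
    rows = []
    threshold = bonferroni_alpha(alpha, max(len(strains), 1)) if strains else alpha
    for strain in strains:
        grp = products[products["strain_name"] == strain]
        if len(grp) < 2:
            raise ChemovarError(f"strain {strain!r} has < 2 products")
        sims = _mean_offdiag(_pairwise_cosine(_profile_matrix(grp, profile_cols)))
        row = {
            "strain_name": strain,
            "n_products": len(grp),
            "mean_similarity": float(np.mean(sims)),
        }
        if null is not None:
            t, p = welch_t(sims, null.values)
            try:
                d = cohens_d_prime(sims, null.values)
            except ChemovarError:
                d = np.nan
            row.update(t=t, p=p, d_prime=d, significant=bool(p < threshold))
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        "mean_similarity", ascending=False, ignore_index=True
    )


def shuffled_name_null(
    products: pd.DataFrame,
    reps: int = 200,
    seed: int = 0,
    profile_cols=panels.TERPENES,
) -> NullDistribution:
    """Shuffled-name bootstrap null for strain consistency.

    Per replicate: strain names are permuted (without replacement) over
    product rows; for every randomized name with >= 2 products, each
    product's mean similarity to its new name-mates is computed and
    averaged into a name-level score; the replicate statistic is the
    mean of those scores weighted by each name's product count.
    """
    if reps < 1:
        raise ChemovarError("reps must be >= 1")
    mat = _profile_matrix(products, profile_cols)
    sim = _pairwise_cosine(mat)
    names = products["strain_name"].to_numpy()
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(names)
        scores, weights = [], []
        for name in pd.unique(perm):
            idx = np.flatnonzero(perm == name)
            if len(idx) < 2:
                continue
            block = sim[np.ix_(idx, idx)]
            scores.append(float(np.mean(_mean_offdiag(block))))
            weights.append(len(idx))
        values[r] = float(np.average(scores, weights=weights))
    return NullDistribution(values=values, reps=reps, seed=seed)


# --- cluster membership of strains -----------------------------------------


def _modal_share(cluster_labels: np.ndarray) -> tuple[object, float]:
    """Modal cluster and its percentage; ties -> lowest cluster label."""
    vals, counts = np.unique(cluster_labels, return_counts=True)
    order = np.lexsort((vals.astype(str), -counts))  # max count, then lowest label
    top = vals[order[0]]
    return top, 100.0 * counts[order[0]] / len(cluster_labels)


def top_cluster_share(
    products: pd.DataFrame, strains: list[str], cluster_col: str = "cluster"
) -> pd.DataFrame:
    """Per-strain modal cluster and the percent of products in it."""
    rows = []
    for strain in strains:
        labels = products.loc[products["strain_name"] == strain, cluster_col].to_numpy()
        if len(labels) == 0:
            warnings.warn(f"strain {strain!r} has no products; skipped")
            continue
        top, share = _modal_share(labels)
        rows.append({"strain_name": strain, "top_cluster": top, "share_pct": share})
    return pd.DataFrame(rows)


def shuffled_cluster_null(
    products: pd.DataFrame,
    strains: list[str],
    reps: int = 200,
    seed: int = 0,
    cluster_col: str = "cluster",
) -> NullDistribution:
    """Shuffled-name null for the top-cluster share.

    Per replicate: names permuted over products, then the mean (over the
    given strains) of each randomized strain's modal-cluster percentage.
    """
    if reps < 1:
        raise ChemovarError("reps must be >= 1")
    names = products["strain_name"].to_numpy()
    clusters = products[cluster_col].to_numpy()
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    strains_set = list(strains)
    for r in range(reps):
        perm = rng.permutation(names)
        shares = []
        for strain in strains_set:
            labels = clusters[perm == strain]
            if len(labels) == 0:
                continue
            shares.append(_modal_share(labels)[1])
        values[r] = float(np.mean(shares))
    return NullDistribution(values=values, reps=reps, seed=seed)


def cluster_share_vs_null(
    products: pd.DataFrame,
    strains: list[str],
    null: NullDistribution,
    cluster_col: str = "cluster",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each strain's top-cluster membership against the shuffled null.

    The strain-side sample is the per-product indicator (x100) of
    falling in the strain's modal cluster, compared to the null
    replicate vector with Welch's t and d'; Bonferroni over strains.
    """
    threshold = bonferroni_alpha(alpha, max(len(strains), 1))
    rows = []
    for strain in strains:
        labels = products.loc[products["strain_name"] == strain, cluster_col].to_numpy()
        top, share = _modal_share(labels)
        indicators = 100.0 * (labels == top).astype(float)
        t, p = welch_t(indicators, null.values)
        try:
            d = cohens_d_prime(indicators, null.values)
        except ChemovarError:
            d = np.nan
        rows.append(
            {
                "strain_name": strain,
                "top_cluster": top,
                "share_pct": share,
                "t": t,
                "p": p,
                "d_prime": d,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)


def category_cluster_enrichment(
    products: pd.DataFrame,
    cluster_col: str = "cluster",
    label_col: str = "category_label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster Indica/Hybrid/Sativa enrichment vs the overall mix.

    Products without an Indica/Hybrid/Sativa label are excluded.  Each
    cluster's label counts are tested with a chi-squared goodness-of-fit
    against the overall labeled-population proportions, Bonferroni over
    the number of clusters.
    """
    labeled = products[products[label_col].isin(panels.CATEGORY_LABELS)]
    if labeled.empty:
        raise ChemovarError("no products carry an Indica/Hybrid/Sativa label")
    # restrict to categories actually present in the labeled population;
    # absent categories would give zero expected counts
    categories = [
        lab for lab in panels.CATEGORY_LABELS
        if (labeled[label_col] == lab).any()
    ]
    overall = (
        labeled[label_col].value_counts(normalize=True)
        .reindex(categories)
        .fillna(0.0)
    )
    clusters = sorted(labeled[cluster_col].unique(), key=str)
    threshold = bonferroni_alpha(alpha, max(len(clusters), 1))
    rows = []
    for cl in clusters:
        grp = labeled[labeled[cluster_col] == cl]
        if grp.empty:
            warnings.warn(f"cluster {cl!r} has no labeled products; excluded")
            continue
        counts = (
            grp[label_col].value_counts().reindex(categories).fillna(0.0)
        )
        if len(categories) < 2:
            x2, p = 0.0, 1.0  # one category: no composition to test
        else:
            x2, p = chi_squared_gof(counts.to_numpy(), overall.to_numpy())
        row = {"cluster": cl, "n": int(len(grp)), "x2": x2, "p": p,
               "significant": bool(p < threshold)}
        for lab in panels.CATEGORY_LABELS:
            row[f"prop_{lab.lower()}"] = float(
                counts.get(lab, 0.0) / len(grp)
            )
        rows.append(row)
    return pd.DataFrame(rows)
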