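"""K-means terpene clustering, silhouette label validity, UMAP embedding.

Samples are segmented on their normalized 14-terpene shares with
k-means (elbow-selected k, default 3 in the pipeline).  How well any
labeling system — commercial Indica/Hybrid/Sativa categories, simple
dominant-terpene labels, or the k-means partition itself — aligns with
chemistry is scored by the silhouette coefficient

    s = (b - a) / max(a, b)

where a is a sample's mean intra-label Euclidean distance and b its
mean distance to the nearest other label; singleton labels score 0.
Label systems are compared pairwise with Welch's t and the d' effect
size under Bonferroni control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from . import panels
from .chemometrics import bonferroni_alpha, cohens_d_prime, welch_t
from .errors import ChemovarError

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def _as_array(X) -> np.ndarray:
    from .chemometrics import NormalizedProfileMatrix

    if isinstance(X, NormalizedProfileMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray  # per-row cluster index, relabeled by size
    wcss: float
    seed: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def kmeans_fit(X, k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd k-means with k-means++ seeding and ``n_init`` restarts.

    Deterministic for a fixed seed.  Cluster indices are relabeled by
    descending cluster size (0 largest), giving reproducible identities
    for reporting.
    """
    arr = _as_array(X)
    if k < 1:
        raise ChemovarError("k must be >= 1")
    if k > arr.shape[0]:
        raise ChemovarError(f"k={k} exceeds the number of rows ({arr.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    raw = km.fit_predict(arr)
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_[order],
        assignments=relabel[raw],
        wcss=float(km.inertia_),
        seed=seed,
    )


def cluster_names(model: ClusterModel) -> list[str]:
    """Roman-numeral cluster names (I = largest)."""
    return [_ROMAN[i] if i < len(_ROMAN) else str(i + 1) for i in range(model.k)]


@dataclass
class ElbowResult:
    ks: list[int]
    wcss: list[float]
    suggested_k: int


def elbow_scan(X, k_range=range(1, 11), seed: int = 0) -> ElbowResult:
    """WCSS curve over ``k_range`` with a maximum-curvature suggestion.

    The suggested k is advisory (largest discrete second difference of
    the WCSS curve); choosing k remains the analyst's decision.
    """
    arr = _as_array(X)
    ks = [int(k) for k in k_range]
    if not ks:
        raise ChemovarError("empty k range")
    wcss = [kmeans_fit(arr, k, seed=seed).wcss for k in ks]
    if len(ks) < 3:
        return ElbowResult(ks, wcss, ks[0])
    curvature = [wcss[i - 1] - 2 * wcss[i] + wcss[i + 1] for i in range(1, len(ks) - 1)]
    suggested = ks[1 + int(np.argmax(curvature))]
    return ElbowResult(ks, wcss, suggested)


def silhouette_scores(X, labels) -> np.ndarray:
    """Per-row silhouette coefficients (Euclidean distance).

    Singleton labels and coincident points with different labels score 0
    by convention.  Requires at least two distinct labels.
    """
    arr = _as_array(X)
    labels = np.asarray(labels)
    if len(labels) != arr.shape[0]:
        raise ChemovarError("labels must match the number of rows")
    n_labels = len(np.unique(labels))
    if n_labels < 2:
        raise ChemovarError("silhouette requires >= 2 distinct labels")
    if n_labels == len(labels):
        return np.zeros(len(labels))  # every label a singleton
    return silhouette_samples(arr, labels, metric="euclidean")


@dataclass
class SilhouetteReport:
    """Per-system silhouette distributions and their pairwise comparisons."""

    coefficients: dict[str, np.ndarray]
    means: dict[str, float]
    comparisons: pd.DataFrame  # system_a, system_b, t, p, d_prime, significant
    alpha: float
    m: int

    def ranking(self) -> list[str]:
        return sorted(self.means, key=self.means.get, reverse=True)


def compare_label_systems(
    X,
    systems: dict[str, np.ndarray],
    alpha: float = 0.05,
    exclude_labels=(panels.UNKNOWN_LABEL, None),
) -> SilhouetteReport:
    """Silhouette comparison of labeling systems over the same rows.

    For each system, rows whose label is in ``exclude_labels`` (or null)
    are dropped from that system's scoring only.  Means come from the
    full (non-excluded) data; all system pairs are compared with Welch's
    t and d' under Bonferroni correction over the number of pairs.
    """
    arr = _as_array(X)
    if len(systems) < 2:
        raise ChemovarError("need >= 2 label systems to compare")
    coeffs: dict[str, np.ndarray] = {}
    for name, labels in systems.items():
        labels = np.asarray(labels, dtype=object)
        if len(labels) != arr.shape[0]:
            raise ChemovarError(f"label system {name!r} does not match row count")
        keep = np.array(
            [lab not in exclude_labels and not pd.isna(lab) for lab in labels]
        )
        coeffs[name] = silhouette_scores(arr[keep], labels[keep])
    means = {name: float(np.mean(c)) for name, c in coeffs.items()}
    pairs = list(combinations(coeffs, 2))
    m = len(pairs)
    threshold = bonferroni_alpha(alpha, m)
    rows = []
    for a, b in pairs:
        if np.array_equal(coeffs[a], coeffs[b]):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = welch_t(coeffs[a], coeffs[b])
            d = cohens_d_prime(coeffs[a], coeffs[b])
        rows.append((a, b, t, p, d, bool(p < threshold)))
    comparisons = pd.DataFrame(
        rows, columns=["system_a", "system_b", "t", "p", "d_prime", "significant"]
    )
    return SilhouetteReport(coeffs, means, comparisons, alpha, m)


def polar_profile(mean_profile: pd.Series) -> dict[str, float]:
    """Eight-terpene polar-plot summary with alpha/beta-pinene summed."""
    s = pd.Series(mean_profile, dtype=float)
    out = {}
    for t in panels.POLAR_TERPENES:
        if t == "pinene":
            out[t] = float(s.get("alpha_pinene", 0.0) + s.get("beta_pinene", 0.0))
        else:
            out[t] = float(s.get(t, 0.0))
    return out


def cluster_summary(model: ClusterModel, profiles: pd.DataFrame) -> list[dict]:
    """Characterize each cluster: size, top-2 mean terpenes, polar profile."""
    names = cluster_names(model)
    out = []
    for i in range(model.k):
        mask = model.assignments == i
        mean_profile = profiles.loc[mask].mean()
        polar = polar_profile(mean_profile)
        top2 = sorted(polar, key=polar.get, reverse=True)[:2]
        out.append(
            {
                "cluster": names[i],
                "size": int(mask.sum()),
                "top_terpenes": top2,
                "character": f"high {top2[0]}-{top2[1]}",
                "polar_profile": polar,
            }
        )
    return out


def umap_embed(
    X, n_neighbors: int = 15, n_components: int = 2, seed: int = 0
) -> np.ndarray:
    """Nonlinear 2-D embedding for qualitative display (delegates to UMAP)."""
    arr = _as_array(X)
    if arr.shape[0] < n_neighbors:
        raise ChemovarError(
            f"UMAP requires at least n_neighbors={n_neighbors} rows, got {arr.shape[0]}"
        )
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, n_components=n_components, random_state=seed
    )
    return np.asarray(reducer.fit_transform(arr))
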