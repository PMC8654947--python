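"""Unbiased classification of insertion-fitness profiles.

Motifs are hierarchically clustered on their positional fitness profiles
(cosine distance, Ward linkage); insertion positions are classified by a
2-D UMAP embedding of their motif-response profiles followed by k-means,
with the cluster number chosen by majority vote over five cluster-validity
indices. Per-position property-fitness correlation profiles, class
enrichment for annotated site sets (two-sided Fisher's exact test), class
agreement (chi-squared / Cramer's V), and the terminal-vs-middle
productive-insertion analysis complete the layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, hypergeom, spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

__all__ = [
    "masked_cosine_distance", "MotifClusterer", "PositionClassifier",
    "cluster_motifs", "position_classes", "correlation_profile",
    "cluster_correlation_profiles", "fisher_exact_twosided",
    "class_enrichment", "class_agreement", "terminal_enrichment",
    "linkage_to_newick",
]


def masked_cosine_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance over jointly observed entries.

    Rows are profiles; NaN cells are excluded pairwise. Pairs with no
    informative overlap get distance 1.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(x[i]) & np.isfinite(x[j])
            a, b = x[i, mask], x[j, mask]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if mask.sum() < 2 or na == 0 or nb == 0:
                d = 1.0
            else:
                d = 1.0 - float(np.dot(a, b) / (na * nb))
            dist[i, j] = dist[j, i] = max(d, 0.0)
    return dist


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    labels = list(labels)
    n = len(labels)

    def node(idx):
        if idx < n:
            return labels[idx], 0.0
        row = link[idx - n]
        left, lh = node(int(row[0]))
        right, rh = node(int(row[1]))
        h = row[2]
        return (f"({left}:{h - lh:.6g},{right}:{h - rh:.6g})", h)

    tree, _ = node(2 * n - 2)
    return tree + ";"


class MotifClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical clustering of motif fitness profiles.

    Cosine distance on the positional profiles (missing cells pairwise
    excluded), Ward linkage, cut to ``n_clusters`` groups. Motifs with
    fewer than ``min_observed`` observed positions are excluded and
    reported in ``excluded_``.
    """

    def __init__(self, n_clusters: int = 3, min_observed: int = 2):
        self.n_clusters = n_clusters
        self.min_observed = min_observed

    def fit(self, fitness: pd.DataFrame, y=None):
        observed = fitness.notna().sum(axis=0)
        keep = observed >= self.min_observed
        self.excluded_ = list(fitness.columns[~keep])
        profiles = fitness.loc[:, keep]
        if profiles.shape[1] < 3:
            raise ValueError("need >= 3 motifs with enough observations")
        dist = masked_cosine_distance(profiles.T.to_numpy())
        self.distance_matrix_ = dist
        self.linkage_ = linkage(squareform(dist, checks=False),
                                method="ward")
        flat = fcluster(self.linkage_, t=self.n_clusters,
                        criterion="maxclust")
        self.labels_ = pd.Series(flat, index=profiles.columns,
                                 name="motif_cluster")
        self.newick_ = linkage_to_newick(self.linkage_, profiles.columns)
        return self


def cluster_motifs(fitness: pd.DataFrame, n_clusters: int = 3):
    """Functional wrapper around :class:`MotifClusterer`."""
    mc = MotifClusterer(n_clusters=n_clusters).fit(fitness)
    return mc.labels_, mc.linkage_


# --------------------------------------------------------------------------
# cluster-validity indices (implemented, not delegated)


def _dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    clusters = [points[labels == k] for k in np.unique(labels)]
    diam = max(
        (np.max(np.linalg.norm(c[:, None] - c[None], axis=-1))
         for c in clusters if len(c) > 1), default=0.0)
    if diam == 0:
        return np.inf
    sep = np.inf
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            d = np.min(np.linalg.norm(clusters[i][:, None]
                                      - clusters[j][None], axis=-1))
            sep = min(sep, d)
    return sep / diam


def _within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for k in np.unique(labels):
        c = points[labels == k]
        w += ((c - c.mean(axis=0)) ** 2).sum()
    return w


def _gap_statistic(points: np.ndarray, k_values, kmeans_factory,
                   rng: np.random.Generator, n_ref: int = 10):
    """Tibshirani gap statistic over a uniform bounding-box reference."""
    lo, hi = points.min(axis=0), points.max(axis=0)
    log_w = {}
    gap, sk = {}, {}
    for k in k_values:
        km = kmeans_factory(k).fit(points)
        log_w[k] = np.log(_within_dispersion(points, km.labels_) + 1e-300)
        ref = []
        for _ in range(n_ref):
            sample = rng.uniform(lo, hi, size=points.shape)
            km_ref = kmeans_factory(k).fit(sample)
            ref.append(np.log(_within_dispersion(sample, km_ref.labels_)
                              + 1e-300))
        ref = np.asarray(ref)
        gap[k] = float(ref.mean() - log_w[k])
        sk[k] = float(ref.std(ddof=0) * np.sqrt(1 + 1 / n_ref))
    ks = sorted(k_values)
    for a, b in zip(ks, ks[1:]):
        if gap[a] >= gap[b] - sk[b]:
            return a, gap
    return ks[int(np.argmax([gap[k] for k in ks]))], gap


@dataclass
class ClassAssignment:
    labels: pd.Series
    method: dict = field(default_factory=dict)
    k: int = 0


class PositionClassifier(BaseEstimator, ClusterMixin):
    """UMAP + k-means positional classification with consensus cluster
    number.

    Positions (rows) are embedded in 2-D with UMAP (local neighborhood
    ``n_neighbors``, metric ``metric``); k-means labels the embedding for
    each k in ``k_range``; the consensus k is the majority vote over five
    validity indices (silhouette, Calinski-Harabasz, Davies-Bouldin, Dunn,
    gap statistic), ties broken toward smaller k. Missing fitness cells
    are imputed with the per-motif mean (the z-score anchor point).
    """

    def __init__(self, n_neighbors: int = 10, metric: str = "cosine",
                 k_range: tuple = (2, 8), n_init: int = 20,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, fitness: pd.DataFrame, y=None):
        import umap

        if fitness.shape[0] < self.n_neighbors + 1:
            raise ValueError("fewer positions than n_neighbors + 1")
        x = fitness.to_numpy(dtype=float)
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        filled = np.where(np.isfinite(x), x, col_mean[None, :])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2,
                                n_neighbors=self.n_neighbors,
                                metric=self.metric,
                                random_state=self.random_state,
                                n_jobs=1)
            emb = reducer.fit_transform(filled)
        self.embedding_ = np.asarray(emb, dtype=float)

        rng = np.random.default_rng(self.random_state)
        ks = list(range(self.k_range[0], self.k_range[1] + 1))

        def factory(k):
            return KMeans(n_clusters=k, n_init=self.n_init,
                          random_state=self.random_state)

        labels_by_k, scores = {}, {}
        for k in ks:
            labels_by_k[k] = factory(k).fit_predict(self.embedding_)
            scores[k] = {
                "silhouette": silhouette_score(self.embedding_,
                                               labels_by_k[k]),
                "calinski_harabasz": calinski_harabasz_score(
                    self.embedding_, labels_by_k[k]),
                "davies_bouldin": davies_bouldin_score(self.embedding_,
                                                       labels_by_k[k]),
                "dunn": _dunn_index(self.embedding_, labels_by_k[k]),
            }
        gap_best, gap_values = _gap_statistic(self.embedding_, ks, factory,
                                              rng)
        votes = {
            "silhouette": max(ks, key=lambda k: scores[k]["silhouette"]),
            "calinski_harabasz": max(
                ks, key=lambda k: scores[k]["calinski_harabasz"]),
            "davies_bouldin": min(
                ks, key=lambda k: scores[k]["davies_bouldin"]),
            "dunn": max(ks, key=lambda k: scores[k]["dunn"]),
            "gap": gap_best,
        }
        tally = pd.Series(votes).value_counts()
        best = tally[tally == tally.max()].index.min()  # ties -> smaller k
        self.votes_ = votes
        self.index_scores_ = {k: dict(scores[k], gap=gap_values[k])
                              for k in ks}
        self.consensus_k_ = int(best)
        self.labels_ = pd.Series(labels_by_k[self.consensus_k_],
                                 index=fitness.index,
                                 name="position_class")
        return self


def position_classes(fitness: pd.DataFrame, **params) -> ClassAssignment:
    """Functional wrapper around :class:`PositionClassifier`."""
    pc = PositionClassifier(**params).fit(fitness)
    return ClassAssignment(labels=pc.labels_, k=pc.consensus_k_,
                           method={"votes": pc.votes_,
                                   "params": pc.get_params()})


# --------------------------------------------------------------------------
# correlation profiles


def correlation_profile(fitness: pd.DataFrame, motif_props: pd.DataFrame,
                        min_pairs: int = 30):
    """Per-position Spearman correlation of fitness with motif properties.

    For each position (row of ``fitness``) and each property (column of
    ``motif_props``), the Spearman rho across motifs on pairwise-complete
    cells; cells with fewer than ``min_pairs`` pairs are missing. Returns
    ``(rho_df, n_df)``.
    """
    shared = fitness.columns.intersection(motif_props.index)
    if shared.empty:
        raise ValueError("no shared motif keys between fitness and "
                         "property table")
    fit = fitness.loc[:, shared]
    props = motif_props.loc[shared]
    rho = pd.DataFrame(index=fit.index, columns=props.columns, dtype=float)
    npairs = pd.DataFrame(0, index=fit.index, columns=props.columns)
    for pos in fit.index:
        y = fit.loc[pos].to_numpy(dtype=float)
        for prop in props.columns:
            x = props[prop].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            npairs.loc[pos, prop] = int(mask.sum())
            if mask.sum() >= min_pairs and np.std(x[mask]) > 0 \
                    and np.std(y[mask]) > 0:
                rho.loc[pos, prop] = spearmanr(x[mask], y[mask]).statistic
    return rho, npairs


def cluster_correlation_profiles(rho: pd.DataFrame, n_clusters: int = 3):
    """Cluster positions on their correlation-profile vectors
    (cosine + Ward), cut to ``n_clusters`` classes."""
    dist = masked_cosine_distance(rho.to_numpy(dtype=float))
    link = linkage(squareform(dist, checks=False), method="ward")
    flat = fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(flat, index=rho.index, name="correlation_class"), link


# --------------------------------------------------------------------------
# categorical statistics


def fisher_exact_twosided(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's. The odds ratio uses the Haldane-Anscombe 0.5 correction when
    any cell is zero.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b, c, d = t.ravel()
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    if (t == 0).any():
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    return float(odds), min(p, 1.0)


def class_enrichment(labels: pd.Series, annotated_sites) -> pd.DataFrame:
    """Per-class enrichment of an annotated site set.

    Builds the 2x2 (in-class x in-set) table for each class and returns
    odds ratios and two-sided Fisher's exact p-values.
    """
    labels = pd.Series(labels)
    sites = set(annotated_sites)
    if not sites:
        raise ValueError("annotated site set is empty")
    unknown = sites - set(labels.index)
    if unknown:
        raise ValueError(f"sites outside the position universe: "
                         f"{sorted(unknown)[:10]}")
    in_set = labels.index.isin(sites)
    rows = []
    for cls in sorted(labels.unique()):
        in_cls = (labels == cls).to_numpy()
        a = int((in_cls & in_set).sum())
        b = int((in_cls & ~in_set).sum())
        c = int((~in_cls & in_set).sum())
        d = int((~in_cls & ~in_set).sum())
        odds, p = fisher_exact_twosided([[a, b], [c, d]])
        rows.append({"class": cls, "n_class": a + b, "n_overlap": a,
                     "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(rows).set_index("class")


def class_agreement(labels_a, labels_b) -> dict:
    """Chi-squared association and Cramer's V between two labelings."""
    a, b = pd.Series(labels_a), pd.Series(labels_b)
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("each labeling needs at least 2 classes")
    table = pd.crosstab(a, b)
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    n = int(table.to_numpy().sum())
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return {"chi2": float(chi2), "p_value": float(p), "dof": int(dof),
            "cramers_v": v, "n": n}


def terminal_enrichment(fitness: pd.DataFrame, motif_subset=None,
                        productive_threshold: float = 0.0,
                        terminal_window: int = 45) -> dict:
    """Fraction of productive insertions at the termini vs the middle.

    Among (position, motif) cells with score above the threshold within
    ``motif_subset``, the fraction in the first/last ``terminal_window``
    positions; the random expectation is the corresponding window-size
    fraction of all positions.
    """
    L = fitness.shape[0]
    if L <= 2 * terminal_window:
        raise ValueError("recipient shorter than twice the terminal window")
    sub = fitness if motif_subset is None else fitness.loc[:, motif_subset]
    positions = np.asarray(sub.index)
    order = np.argsort(positions)
    nterm = set(positions[order[:terminal_window]])
    cterm = set(positions[order[-terminal_window:]])
    productive = sub > productive_threshold
    total = int(productive.to_numpy().sum())
    if total == 0:
        raise ValueError("no productive cells above the threshold")
    per_pos = productive.sum(axis=1)
    n_frac = float(per_pos[per_pos.index.isin(nterm)].sum() / total)
    c_frac = float(per_pos[per_pos.index.isin(cterm)].sum() / total)
    return {
        "n_terminal": n_frac, "c_terminal": c_frac,
        "middle": 1.0 - n_frac - c_frac,
        "expected_terminal": 2 * terminal_window / L,
        "expected_middle": (L - 2 * terminal_window) / L,
        "n_productive": total,
    }
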