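"""Donor/recipient compatibility model and its interpretation statistics.

A regression random forest predicts insertion fitness from recipient and
motif features. Around it:

- correlation-based redundancy reduction (``|rho| >= cutoff`` groups,
  keeping the feature with the largest summed absolute response
  correlation);
- drop-and-refit feature importance (increase in held-out mean absolute
  error when a feature is removed and the forest refit on the same split);
- first- and second-order accumulated local effects (ALE, the Apley-Zhu
  quantile-bin estimators);
- pairwise interaction strength (Friedman's H statistic from centered
  partial dependences).

The ALE and H estimators are implemented here directly and validated
against closed-form oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureSet", "reduce_redundancy", "CompatibilityForest", "fit_model",
    "drop_importance", "ALEProfile", "ale_first_order", "ale_second_order",
    "interaction_strength",
]


# --------------------------------------------------------------------------
# redundancy reduction


@dataclass
class FeatureSet:
    """Result of redundancy reduction."""
    retained: list[str]
    groups: list[dict] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)


def _abs_response_score(x: np.ndarray, y: np.ndarray,
                        groups: np.ndarray | None) -> float:
    """Summed |Pearson correlation with the response|, per group of rows."""
    if groups is None:
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
            return 0.0
        return float(abs(np.corrcoef(x[mask], y[mask])[0, 1]))
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        total += _abs_response_score(x[sel], y[sel], None)
    return total


def reduce_redundancy(features: pd.DataFrame, response, cutoff: float = 0.8,
                      row_groups=None) -> FeatureSet:
    """Group mutually correlated features and keep one representative each.

    Features whose pairwise |Pearson correlation| reaches ``cutoff`` are
    grouped by transitive closure; within a group the representative
    maximizes the summed absolute correlation with the response
    (``row_groups`` sums that correlation within each group of rows, e.g.
    per position for motif features). Constant features are removed first.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(response, dtype=float)
    if len(y) != len(features):
        raise ValueError("response length must match the feature rows")
    complete = features.notna().all(axis=1) & np.isfinite(y)
    if complete.sum() < 10:
        raise ValueError("need >= 10 complete cases")
    groups_arr = None if row_groups is None else np.asarray(row_groups)

    constant = [c for c in features.columns
                if features[c].nunique(dropna=True) <= 1]
    work = features.drop(columns=constant)
    cols = list(work.columns)
    corr = work.corr().abs().to_numpy()

    # union-find over the |rho| >= cutoff relation
    parent = list(range(len(cols)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if corr[i, j] >= cutoff - 1e-12:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(len(cols)):
        clusters.setdefault(find(i), []).append(i)

    retained, group_reports = [], []
    for members in clusters.values():
        scores = {
            cols[i]: _abs_response_score(work[cols[i]].to_numpy(float), y,
                                         groups_arr)
            for i in members}
        rep = max(sorted(scores), key=lambda c: scores[c])
        retained.append(rep)
        if len(members) > 1:
            group_reports.append({
                "members": [cols[i] for i in members],
                "representative": rep,
                "scores": scores,
            })
    retained = [c for c in cols if c in set(retained)]  # stable order
    return FeatureSet(retained=retained, groups=group_reports,
                      dropped_constant=constant)


# --------------------------------------------------------------------------
# the forest


class CompatibilityForest(BaseEstimator, RegressorMixin):
    """Regression random forest with a seeded held-out split.

    Parameters mirror the conventions of regression forests in this
    setting: 500 trees, mtry = p/3, unlimited depth, an 85/15 train/test
    split, and out-of-bag scoring. After :meth:`fit`:

    - ``forest_``: the fitted sklearn ensemble
    - ``train_idx_`` / ``test_idx_``: the split (disjoint, exhaustive)
    - ``heldout_variance_explained_``: 1 - MSE/Var(y) on the held-out 15%
    - ``oob_variance_explained_``: out-of-bag R^2
    - ``heldout_mae_``: held-out mean absolute error
    """

    def __init__(self, n_trees: int = 500, test_size: float = 0.15,
                 min_rows: int = 50, random_state: int = 0):
        self.n_trees = n_trees
        self.test_size = test_size
        self.min_rows = min_rows
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        complete = X.notna().all(axis=1).to_numpy() & np.isfinite(y)
        if complete.sum() < self.min_rows:
            raise ValueError(
                f"need >= {self.min_rows} complete-case rows, "
                f"got {int(complete.sum())}")
        X, y = X.loc[complete], y[complete]
        if np.std(y) == 0:
            raise ValueError("response is constant")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        idx = np.arange(len(y))
        train, test = train_test_split(idx, test_size=self.test_size,
                                       random_state=self.random_state)
        self.train_idx_, self.test_idx_ = np.sort(train), np.sort(test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.forest_ = RandomForestRegressor(
                n_estimators=self.n_trees, max_features=1.0 / 3.0,
                oob_score=True, random_state=self.random_state, n_jobs=1)
            self.forest_.fit(X.iloc[self.train_idx_], y[self.train_idx_])
        pred = self.forest_.predict(X.iloc[self.test_idx_])
        y_test = y[self.test_idx_]
        self.heldout_variance_explained_ = float(
            1.0 - np.mean((pred - y_test) ** 2) / np.var(y_test))
        self.heldout_mae_ = float(mean_absolute_error(y_test, pred))
        self.oob_variance_explained_ = float(self.forest_.oob_score_)
        return self

    def predict(self, X):
        return self.forest_.predict(pd.DataFrame(X)[
            list(self.feature_names_in_)])


def fit_model(features: pd.DataFrame, response, n_trees: int = 500,
              split: float = 0.85, seed: int = 0) -> CompatibilityForest:
    """Functional wrapper: fit a compatibility forest (train fraction
    ``split``, the rest held out)."""
    return CompatibilityForest(n_trees=n_trees, test_size=1.0 - split,
                               random_state=seed).fit(features, response)


def drop_importance(features: pd.DataFrame, response,
                    n_trees: int = 500, test_size: float = 0.15,
                    random_state: int = 0) -> pd.DataFrame:
    """Drop-and-refit importance: held-out MAE increase per removed feature.

    Each feature is removed in turn, the forest refit with the same seed
    and split, and the increase in held-out mean absolute error over the
    full-feature baseline recorded. Negative increases are clipped at 0 in
    the ranked column; raw values are retained.
    """
    features = pd.DataFrame(features)
    if features.shape[1] < 2:
        raise ValueError("drop importance needs at least 2 features")
    base = CompatibilityForest(n_trees=n_trees, test_size=test_size,
                               random_state=random_state)
    base.fit(features, response)
    rows = []
    for col in features.columns:
        reduced = CompatibilityForest(n_trees=n_trees, test_size=test_size,
                                      random_state=random_state)
        reduced.fit(features.drop(columns=[col]), response)
        raw = reduced.heldout_mae_ - base.heldout_mae_
        rows.append({"feature": col, "mae_increase_raw": raw,
                     "mae_increase": max(raw, 0.0)})
    out = pd.DataFrame(rows).set_index("feature")
    out["rank"] = out["mae_increase_raw"].rank(ascending=False,
                                               method="first").astype(int)
    out.attrs["baseline_mae"] = base.heldout_mae_
    return out.sort_values("rank")


# --------------------------------------------------------------------------
# accumulated local effects


def _predict(model, X: pd.DataFrame) -> np.ndarray:
    f = model.predict if hasattr(model, "predict") else model
    return np.asarray(f(X), dtype=float)


@dataclass
class ALEProfile:
    """A first- or second-order accumulated-local-effects profile."""
    features: tuple
    edges: tuple            # one (first order) or two arrays of bin edges
    effects: np.ndarray     # values at bin edges / grid nodes (centered)
    centering: float
    filled_cells: list = field(default_factory=list)


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    return edges


def ale_first_order(model, X: pd.DataFrame, feature: str,
                    n_bins: int = 20) -> ALEProfile:
    """First-order ALE of one feature (Apley-Zhu quantile estimator).

    Local prediction differences across each quantile bin (the feature
    moved from the lower to the upper edge, all other features at their
    observed values) are averaged per bin, accumulated, and centered to a
    data-weighted mean of zero.
    """
    X = pd.DataFrame(X)
    x = X[feature].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        warnings.warn(f"feature {feature!r} is constant; ALE is flat zero")
        return ALEProfile(features=(feature,), edges=(np.array([x[0]]),),
                          effects=np.zeros(1), centering=0.0)
    edges = _quantile_edges(x, n_bins)
    k = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, k - 1)
    deltas = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    for b in range(k):
        rows = X.iloc[idx == b]
        counts[b] = len(rows)
        if counts[b] == 0:
            continue
        hi = rows.copy()
        hi[feature] = edges[b + 1]
        lo = rows.copy()
        lo[feature] = edges[b]
        deltas[b] = float(np.mean(_predict(model, hi) - _predict(model, lo)))
    fe = np.concatenate([[0.0], np.cumsum(deltas)])
    center = float(np.sum(counts * (fe[:-1] + fe[1:]) / 2.0) / counts.sum())
    return ALEProfile(features=(feature,), edges=(edges,),
                      effects=fe - center, centering=center)


def _nearest_fill(delta: np.ndarray, empty: np.ndarray):
    """Fill empty cells with the nearest non-empty cell's value
    (bin-index Manhattan distance)."""
    filled = []
    if not empty.any():
        return delta, filled
    occ = np.argwhere(~empty)
    for i, j in np.argwhere(empty):
        dists = np.abs(occ[:, 0] - i) + np.abs(occ[:, 1] - j)
        src = occ[np.argmin(dists)]
        delta[i, j] = delta[src[0], src[1]]
        filled.append((int(i), int(j)))
    return delta, filled


def ale_second_order(model, X: pd.DataFrame, feature_i: str,
                     feature_j: str, n_bins: int = 10) -> ALEProfile:
    """Second-order ALE of a feature pair (Apley-Zhu quantile estimator).

    Per-cell cross-differences of predictions over the 2-D quantile grid
    are accumulated along both axes; the first-order components and the
    constant are subtracted so the surface isolates the pure interaction.
    Empty grid cells are filled from the nearest non-empty cell and
    reported in ``filled_cells``.
    """
    X = pd.DataFrame(X)
    xi = X[feature_i].to_numpy(dtype=float)
    xj = X[feature_j].to_numpy(dtype=float)
    e1 = _quantile_edges(xi, n_bins)
    e2 = _quantile_edges(xj, n_bins)
    k1, k2 = len(e1) - 1, len(e2) - 1
    b1 = np.clip(np.searchsorted(e1, xi, side="left") - 1, 0, k1 - 1)
    b2 = np.clip(np.searchsorted(e2, xj, side="left") - 1, 0, k2 - 1)

    delta = np.zeros((k1, k2))
    counts = np.zeros((k1, k2), dtype=int)
    for a in range(k1):
        sel_a = b1 == a
        for b in range(k2):
            rows = X.iloc[sel_a & (b2 == b)]
            counts[a, b] = len(rows)
            if counts[a, b] == 0:
                continue
            preds = []
            for vi, vj in ((e1[a + 1], e2[b + 1]), (e1[a], e2[b + 1]),
                           (e1[a + 1], e2[b]), (e1[a], e2[b])):
                z = rows.copy()
                z[feature_i] = vi
                z[feature_j] = vj
                preds.append(_predict(model, z).mean())
            delta[a, b] = preds[0] - preds[1] - preds[2] + preds[3]
    delta, filled = _nearest_fill(delta, counts == 0)

    fe = np.zeros((k1 + 1, k2 + 1))
    fe[1:, 1:] = np.cumsum(np.cumsum(delta, axis=0), axis=1)

    # subtract the first-order components (row/column effects)
    diff1 = fe[1:, :] - fe[:-1, :]              # k1 x (k2+1)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_eff = np.where(
            row_tot > 0,
            (counts * (diff1[:, :-1] + diff1[:, 1:]) / 2.0).sum(axis=1)
            / np.maximum(row_tot, 1), 0.0)
    fe1 = np.concatenate([[0.0], np.cumsum(row_eff)])
    diff2 = fe[:, 1:] - fe[:, :-1]              # (k1+1) x k2
    col_tot = counts.sum(axis=0)
    col_eff = np.where(
        col_tot > 0,
        (counts * (diff2[:-1, :] + diff2[1:, :]) / 2.0).sum(axis=0)
        / np.maximum(col_tot, 1), 0.0)
    fe2 = np.concatenate([[0.0], np.cumsum(col_eff)])
    fe = fe - fe1[:, None] - fe2[None, :]

    center = float(
        (counts * (fe[:-1, :-1] + fe[:-1, 1:] + fe[1:, :-1] + fe[1:, 1:])
         / 4.0).sum() / counts.sum())
    return ALEProfile(features=(feature_i, feature_j), edges=(e1, e2),
                      effects=fe - center, centering=center,
                      filled_cells=filled)


# --------------------------------------------------------------------------
# interaction strength


def _partial_dependence(model, X: pd.DataFrame, cols: list[str],
                        grid: pd.DataFrame) -> np.ndarray:
    """Brute-force partial dependence of ``cols`` on ``grid`` values,
    averaged over the background rows of ``X``."""
    n_bg, n_grid = len(X), len(grid)
    tiled = pd.concat([X] * n_grid, ignore_index=True)
    for c in cols:
        tiled[c] = np.repeat(grid[c].to_numpy(), n_bg)
    preds = _predict(model, tiled).reshape(n_grid, n_bg)
    return preds.mean(axis=1)


def interaction_strength(model, X: pd.DataFrame, pairs=None,
                         n_sample: int = 500,
                         random_state: int = 0) -> pd.DataFrame:
    """Friedman's H statistic for feature pairs.

    H^2 = sum[PD_ij - PD_i - PD_j]^2 / sum[PD_ij^2] over a sample of
    observed points, with all partial dependences centered; reported as
    H in [0, 1] (numerical excursions clipped and flagged in
    ``attrs['clipped']``). Pairs with zero-variance joint partial
    dependence are undefined (NaN).
    """
    X = pd.DataFrame(X)
    cols = list(X.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rng = np.random.default_rng(random_state)
    n = min(n_sample, len(X))
    sample = X.iloc[np.sort(rng.choice(len(X), size=n, replace=False))]
    sample = sample.reset_index(drop=True)

    pd1 = {}
    for col in sorted({c for p in pairs for c in p}):
        vals = _partial_dependence(model, sample, [col], sample)
        pd1[col] = vals - vals.mean()

    rows, clipped = [], []
    for a, b in pairs:
        pdij = _partial_dependence(model, sample, [a, b], sample)
        pdij = pdij - pdij.mean()
        denom = float(np.sum(pdij ** 2))
        if denom == 0:
            rows.append({"feature_a": a, "feature_b": b, "h": np.nan})
            continue
        h2 = float(np.sum((pdij - pd1[a] - pd1[b]) ** 2) / denom)
        h = np.sqrt(max(h2, 0.0))
        if h > 1.0:
            clipped.append((a, b))
            h = 1.0
        rows.append({"feature_a": a, "feature_b": b, "h": h})
    out = pd.DataFrame(rows)
    out.attrs["clipped"] = clipped
    out.attrs["n_sample"] = n
    return out
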