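"""Sort-seq surface-expression fitness statistics.

Implements the enrichment statistic used in two-gate (surface-labeled
high/low) FACS-seq domain-insertion screens:

1. *Raw enrichment* — per insertion position, the natural log ratio of the
   pseudocounted read fraction in the label-high gate to the label-low gate,
   computed within one (motif, replicate, subpool) group.
2. *z-scoring* — raw scores are standardized to the raw enrichment of an
   internal flexible-linker control motif within the same sequencing
   subpool / collection batch, so that 0 means "traffics like a flexible
   linker insertion".
3. *Poisson standard errors* — per-variant count-based SEs.
4. *Replicate combination* — a weighted average across replicates, with a
   between-replicate variance component M estimated per variant by REML
   Fisher scoring.

The replicate weight is sqrt(M + SE_r^2) / sum_r sqrt(M + SE_r^2), kept in
that form deliberately (see ``weighting='inverse-variance'`` for the
conventional alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "raw_enrichment", "poisson_se", "control_stats", "zscore",
    "reml_combine", "filter_dataset", "ControlStats", "CombinedScore",
    "SortSeqScorer", "score_counts",
]


@dataclass(frozen=True)
class ControlStats:
    """Location/scale of the control motif's raw enrichment in one scope."""
    mu: float
    sigma: float
    scope: tuple
    n_control_scores: int


@dataclass
class CombinedScore:
    position: int
    motif_id: str
    score: float
    weights: np.ndarray
    reml_var: float
    n_replicates: int


def raw_enrichment(counts_high, counts_low, require_both_gates: bool = True):
    """Per-position log-ratio enrichment within one (motif, replicate) group.

    score_i = ln[(0.5 + h_i) / sum_i(0.5 + h_i)]
            - ln[(0.5 + l_i) / sum_i(0.5 + l_i)]

    Positions lacking reads in either gate are returned as NaN when
    ``require_both_gates`` (the exclusion rule used for all downstream
    analysis); the relaxed form is available for formula checks.
    """
    h = np.asarray(counts_high, dtype=float)
    l = np.asarray(counts_low, dtype=float)
    if h.shape != l.shape:
        raise ValueError("gate count vectors must share positions")
    if np.any(h < 0) or np.any(l < 0):
        raise ValueError("counts must be non-negative")
    th = np.sum(0.5 + h)
    tl = np.sum(0.5 + l)
    score = np.log((0.5 + h) / th) - np.log((0.5 + l) / tl)
    if require_both_gates:
        score = np.where((h > 0) & (l > 0), score, np.nan)
    if h.sum() == 0 or l.sum() == 0:
        # an all-zero gate carries no enrichment information
        score = np.full_like(score, np.nan)
    return score


def poisson_se(c_high, c_low, total_high, total_low):
    """Count-based standard error of a raw enrichment score.

    SE = sqrt(1/(c_high+0.5) + 1/(c_low+0.5)
              + 1/(total_high+0.5) + 1/(total_low+0.5))

    Pseudocounts make the SE finite for zero counts.
    """
    c_high = np.asarray(c_high, dtype=float)
    c_low = np.asarray(c_low, dtype=float)
    return np.sqrt(
        1.0 / (c_high + 0.5)
        + 1.0 / (c_low + 0.5)
        + 1.0 / (np.asarray(total_high, dtype=float) + 0.5)
        + 1.0 / (np.asarray(total_low, dtype=float) + 0.5)
    )


def control_stats(control_scores, scope=("global",)) -> ControlStats:
    """Mean and sample sd (ddof=1) of the control motif's raw scores."""
    x = np.asarray(control_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(
            f"scope {scope!r}: need >= 2 control scores, got {x.size}")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        raise ValueError(f"scope {scope!r}: control scores are constant")
    return ControlStats(mu=float(np.mean(x)), sigma=sigma, scope=tuple(scope),
                        n_control_scores=int(x.size))


def zscore(raw, stats: ControlStats):
    """Standardize raw scores to the control motif's location and scale."""
    return (np.asarray(raw, dtype=float) - stats.mu) / stats.sigma


def _reml_variance(y: np.ndarray, s2: np.ndarray, n_iter: int = 50) -> float:
    """REML estimate of the between-replicate variance M by Fisher scoring.

    Random-effects model: y_r ~ Normal(theta, M + s2_r). The REML score and
    expected information are iterated ``n_iter`` times with M floored at 0.
    """
    m = max(0.0, float(np.var(y, ddof=1) - np.mean(s2))) if y.size > 1 else 0.0
    for _ in range(n_iter):
        v = s2 + m
        w = 1.0 / v
        sw = w.sum()
        theta = (w * y).sum() / sw
        resid = y - theta
        w2 = w * w
        score = 0.5 * ((w2 * resid**2).sum() - w.sum() + w2.sum() / sw)
        info = 0.5 * (w2.sum() - 2.0 * (w**3).sum() / sw
                      + (w2.sum() / sw) ** 2)
        if info <= 0:
            break
        m = max(0.0, m + score / info)
    return m


def reml_combine(z_scores, ses, n_iter: int = 50,
                 weighting: str = "as-printed"):
    """Combine replicate z-scores into one variant score.

    Weights are sqrt(M + SE_r^2) normalized over the replicates present
    (``weighting='as-printed'``), or 1/(M + SE_r^2) normalized
    (``'inverse-variance'``). Returns ``(combined, weights, M)``.
    """
    z = np.asarray(z_scores, dtype=float)
    se = np.asarray(ses, dtype=float)
    keep = np.isfinite(z) & np.isfinite(se)
    z, se = z[keep], se[keep]
    if z.size == 0:
        return np.nan, np.array([]), np.nan
    if z.size == 1:
        return float(z[0]), np.array([1.0]), 0.0
    m = _reml_variance(z, se**2, n_iter=n_iter)
    if weighting == "as-printed":
        w = np.sqrt(m + se**2)
    elif weighting == "inverse-variance":
        w = 1.0 / (m + se**2)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return float(np.dot(z, w)), w, m


def filter_dataset(fitness: pd.DataFrame, min_fraction: float = 0.8):
    """Drop motifs observed at too few positions.

    A motif (column) is retained iff its observed-position fraction is
    strictly greater than ``min_fraction``. Returns the filtered matrix and
    the list of dropped motif ids.
    """
    frac = fitness.notna().mean(axis=0)
    keep = frac > min_fraction
    dropped = list(fitness.columns[~keep])
    return fitness.loc[:, keep], dropped


REQUIRED_COUNT_COLUMNS = ("position", "motif_id", "gate", "replicate",
                          "subpool", "batch", "count")


class SortSeqScorer(BaseEstimator):
    """Estimator turning a gated count table into a fitness matrix.

    Parameters
    ----------
    control_motif : str
        Motif id of the internal flexible-linker control used as the
        z-score anchor.
    scope : {'subpool', 'global'}
        Scope within which control statistics are computed: per
        (subpool, batch), or once globally.
    weighting : {'as-printed', 'inverse-variance'}
        Replicate weighting scheme (see :func:`reml_combine`).
    min_fraction : float
        Strict lower bound on the observed-position fraction a motif needs
        to survive filtering.
    n_iter : int
        Fisher scoring iterations for the REML variance component.

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : long-form per-replicate DataFrame (raw, z, se per variant)
    fitness_matrix_ : positions x motifs DataFrame after motif filtering
    fitness_matrix_all_ : unfiltered matrix
    combined_ : long-form combined scores with weights and REML variance
    control_stats_ : dict mapping scope key -> ControlStats
    dropped_motifs_ : motifs removed by the coverage filter
    """

    def __init__(self, control_motif: str = "flex_linker",
                 scope: str = "subpool", weighting: str = "as-printed",
                 min_fraction: float = 0.8, n_iter: int = 50):
        self.control_motif = control_motif
        self.scope = scope
        self.weighting = weighting
        self.min_fraction = min_fraction
        self.n_iter = n_iter

    # -- internals ---------------------------------------------------------

    def _scope_key(self, subpool, batch):
        return (subpool, batch) if self.scope == "subpool" else ("global",)

    def fit(self, counts: pd.DataFrame, y=None):
        missing = set(REQUIRED_COUNT_COLUMNS) - set(counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if self.scope not in ("subpool", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")

        wide = (counts.pivot_table(index=["motif_id", "replicate", "subpool",
                                          "batch", "position"],
                                   columns="gate", values="count",
                                   aggfunc="sum", fill_value=0)
                .reindex(columns=["high", "low"], fill_value=0)
                .reset_index())

        rows = []
        for (motif, rep, subpool, batch), grp in wide.groupby(
                ["motif_id", "replicate", "subpool", "batch"], sort=True):
            h = grp["high"].to_numpy(float)
            l = grp["low"].to_numpy(float)
            raw = raw_enrichment(h, l)
            se = poisson_se(h, l, h.sum(), l.sum())
            rows.append(pd.DataFrame({
                "position": grp["position"].to_numpy(),
                "motif_id": motif, "replicate": rep,
                "subpool": subpool, "batch": batch,
                "count_high": h.astype(int), "count_low": l.astype(int),
                "raw": raw, "se": se,
            }))
        scores = pd.concat(rows, ignore_index=True)

        # control statistics per scope, from the control motif's raw scores
        self.control_stats_ = {}
        ctrl = scores[scores["motif_id"] == self.control_motif]
        if ctrl.empty:
            raise ValueError(
                f"control motif {self.control_motif!r} absent from counts")
        for key, grp in ctrl.groupby(
                ctrl.apply(lambda r: self._scope_key(r["subpool"], r["batch"]),
                           axis=1)):
            try:
                self.control_stats_[key] = control_stats(
                    grp["raw"].to_numpy(), scope=key)
            except ValueError as exc:
                warnings.warn(str(exc), stacklevel=2)

        def _z(row):
            st = self.control_stats_.get(
                self._scope_key(row["subpool"], row["batch"]))
            if st is None or not np.isfinite(row["raw"]):
                return np.nan
            return (row["raw"] - st.mu) / st.sigma

        scores["z"] = scores.apply(_z, axis=1)
        self.scores_ = scores

        combined_rows = []
        for (pos, motif), grp in scores.groupby(["position", "motif_id"],
                                                sort=True):
            c, w, m = reml_combine(grp["z"].to_numpy(), grp["se"].to_numpy(),
                                   n_iter=self.n_iter,
                                   weighting=self.weighting)
            combined_rows.append({
                "position": pos, "motif_id": motif, "score": c,
                "reml_var": m, "n_replicates": int(len(w)),
            })
        combined = pd.DataFrame(combined_rows)
        self.combined_ = combined

        matrix = combined.pivot(index="position", columns="motif_id",
                                values="score").sort_index()
        self.fitness_matrix_all_ = matrix
        self.fitness_matrix_, self.dropped_motifs_ = filter_dataset(
            matrix, self.min_fraction)
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Score a count table and return the filtered fitness matrix."""
        return self.fit(counts).fitness_matrix_


def score_counts(counts: pd.DataFrame, **params) -> pd.DataFrame:
    """Functional wrapper: count table -> filtered fitness matrix."""
    return SortSeqScorer(**params).fit(counts).fitness_matrix_
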