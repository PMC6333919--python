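"""Grouping features by silencing kinetics and mutant sensitivity.

Early/intermediate/late silencing classes come from a 3-cluster k-means
on IC35 values; HDAC3-sensitivity classes from a 3-cluster k-means on
the normalised WT-vs-mutant difference at 24 h.  Cluster labels are
assigned by centroid order, so they are invariant to input order and
k-means label permutation.  Feature association compares early vs late
groups with two-sided rank-sum tests under Benjamini-Hochberg
correction across the feature panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrderedKMeans1D",
    "kinetic_clusters",
    "sensitivity_classes",
    "replicate_stability_filter",
    "escapee_filter",
    "sensitivity_score",
    "associate_features",
]

KINETIC_LABELS = ("early", "intermediate", "late")
SENSITIVITY_LABELS = ("resistant", "intermediate", "sensitive")


class OrderedKMeans1D(BaseEstimator, ClusterMixin):
    """1-D k-means whose labels follow centroid order, not fit order.

    ``labels`` names the clusters by ascending centroid (e.g. lowest
    IC35 centroid = "early").  Degenerate input (all values equal, or
    fewer distinct values than clusters) collapses to the first label
    with a warning.  Ties in centroid order are broken by cluster size
    (larger first).

    Fitted attributes: ``centers_`` (ascending), ``labels_``.
    """

    def __init__(self, n_clusters: int = 3, labels: tuple = KINETIC_LABELS,
                 random_state: int = 0, n_init: int = 10):
        self.n_clusters = n_clusters
        self.labels = labels
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if not np.isfinite(x).all():
            raise ValueError("cluster values must be finite")
        if len(x) < self.n_clusters:
            raise ValueError(
                f"need >= {self.n_clusters} values, got {len(x)}"
            )
        if len(self.labels) != self.n_clusters:
            raise ValueError("one label per cluster required")
        if np.unique(x).size < self.n_clusters:
            warnings.warn(
                "fewer distinct values than clusters; assigning one class",
                UserWarning,
            )
            self.centers_ = np.repeat(float(np.mean(x)), self.n_clusters)
            self.labels_ = np.array([self.labels[0]] * len(x), dtype=object)
            return self
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(x.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        sizes = np.bincount(km.labels_, minlength=self.n_clusters)
        order = sorted(range(self.n_clusters), key=lambda i: (centers[i], -sizes[i]))
        rank_of = {ci: r for r, ci in enumerate(order)}
        self.centers_ = centers[order]
        self.labels_ = np.array(
            [self.labels[rank_of[ci]] for ci in km.labels_], dtype=object
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kinetic_clusters(ic35_values, k: int = 3, seed: int = 0) -> np.ndarray:
    """Early/intermediate/late (ascending IC35 centroid) cluster labels.

    With k != 3 clusters the labels are "cluster_0" (earliest) upward.
    """
    labels = KINETIC_LABELS if k == 3 else tuple(f"cluster_{i}" for i in range(k))
    return OrderedKMeans1D(n_clusters=k, labels=labels, random_state=seed).fit_predict(
        ic35_values
    )


def sensitivity_classes(scores, k: int = 3, seed: int = 0) -> np.ndarray:
    """Resistant/intermediate/sensitive labels (highest score = sensitive)."""
    labels = (
        SENSITIVITY_LABELS if k == 3 else tuple(f"cluster_{i}" for i in range(k))
    )
    return OrderedKMeans1D(n_clusters=k, labels=labels, random_state=seed).fit_predict(
        scores
    )


def replicate_stability_filter(
    dscores: pd.DataFrame, n_sd: float = 2.0
) -> pd.Series:
    """Features with stable d-scores between replicates (True = pass).

    ``dscores`` is a long frame with feature_id, time_h, replicate,
    dscore and optionally clone.  The absolute replicate difference is
    computed per feature/time(/clone); the cutoff is median + n_sd * sd
    of all differences pooled globally.  A feature passes only if every
    one of its differences is below the cutoff.  With a single
    replicate the filter is inapplicable: all pass with a warning.
    """
    if dscores["replicate"].nunique() < 2:
        warnings.warn("single replicate; stability filter inapplicable", UserWarning)
        return pd.Series(
            True, index=pd.Index(dscores["feature_id"].unique(), name="feature_id")
        )
    keys = ["feature_id", "time_h"]
    if "clone" in dscores.columns:
        keys.append("clone")
    wide = dscores.pivot_table(
        index=keys, columns="replicate", values="dscore", aggfunc="first"
    )
    reps = wide.columns.tolist()
    diffs = (wide[reps[0]] - wide[reps[1]]).abs()
    pooled = diffs.dropna()
    # epsilon keeps the degenerate all-equal-differences case passing
    cutoff = float(pooled.median()) + n_sd * float(pooled.std(ddof=1)) + 1e-12
    bad = diffs >= cutoff
    fail = bad.groupby(level="feature_id").any()
    return ~fail.reindex(dscores["feature_id"].unique(), fill_value=False)


def escapee_filter(normalized_d_at_24, cutoff: float = 0.8) -> np.ndarray:
    """Non-escaping features: normalised d-score at 24 h strictly < cutoff.

    True = retained (silenced); a feature at exactly the cutoff is
    flagged escaping.
    """
    d = np.asarray(normalized_d_at_24, dtype=float)
    return d < cutoff


def sensitivity_score(wt_norm_d0, wt_norm_d24, mut_norm_d24):
    """Normalised mutant-vs-WT silencing defect at 24 h.

    score = (mut(24) - WT(24)) / (WT(0) - WT(24)):
    0 = mutant silences like WT (resistant to the mutation),
    1 = mutant stays at the WT starting level (fully blocked).
    nan where the WT dynamic range is zero (flagged upstream).
    """
    d0 = np.asarray(wt_norm_d0, dtype=float)
    d24 = np.asarray(wt_norm_d24, dtype=float)
    m24 = np.asarray(mut_norm_d24, dtype=float)
    denom = d0 - d24
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (m24 - d24) / denom, np.nan)
    return out if out.ndim else float(out)


def associate_features(
    groups,
    feature_table: pd.DataFrame,
    early_label: str = "early",
    late_label: str = "late",
    entry_site_distance_col: str | None = "dist_entry_site",
    proximity_kb: float = 100.0,
) -> pd.DataFrame:
    """Rank-sum association of genomic features with kinetic groups.

    For each numeric column of ``feature_table`` (distance to Xist,
    TAD-boundary and LAD distances, LINE/gene density, expression, ...)
    the early and late groups are compared with a two-sided Wilcoxon
    rank-sum test; p-values are Benjamini-Hochberg adjusted across the
    panel.  If ``entry_site_distance_col`` is present, a proximity flag
    (< ``proximity_kb`` kb) is tested the same way on the flag values.
    Returns one row per feature column with statistic, p and adjusted p.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(feature_table):
        raise ValueError("groups and feature_table lengths differ")
    early = groups == early_label
    late = groups == late_label
    if early.sum() == 0 or late.sum() == 0:
        raise ValueError("both early and late groups must be non-empty")

    tbl = feature_table.copy()
    if entry_site_distance_col and entry_site_distance_col in tbl.columns:
        tbl["near_entry_site"] = (
            tbl[entry_site_distance_col] < proximity_kb * 1000
        ).astype(float)

    rows = []
    for col in tbl.columns:
        vals = pd.to_numeric(tbl[col], errors="coerce")
        a = vals[early].dropna()
        b = vals[late].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        stat, p = ranksums(a, b)
        rows.append({"feature": col, "statistic": float(stat), "pvalue": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
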