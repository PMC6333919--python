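"""From allelic counts to filtered d-score and accumulation series.

The d-score of a feature in a sample is the allelic ratio

    d = reads_B6 / (reads_B6 + reads_Cast)

with B6 the allele of the (induced) inactive X and Cast the active X:
0.5 is biallelic and the score moves towards 0 as the B6 allele loses an
active mark or expression.  Repressive marks gain signal on the Xi
instead, so they are analysed as TMM-normalised B6 counts relative to
the t=0 baseline (accumulation) rather than as ratios.

Features failing a filter are flagged, never dropped, so downstream
feature counts remain auditable.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "read_count_table",
    "write_table",
    "compute_dscores",
    "filter_biallelic",
    "normalize_dscores",
    "TMMNormalizer",
    "tmm_factors",
    "input_outlier_windows",
    "accumulation_series",
]

REQUIRED_COLUMNS = [
    "feature_id",
    "sample_id",
    "time_h",
    "replicate",
    "count_B6",
    "count_Cast",
    "count_total",
]


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a TSV allelic count table.

    Required columns: feature_id, sample_id, time_h, replicate,
    count_B6, count_Cast, count_total (chrom/start/end/clone/condition
    optional).  Counts must be non-negative with
    count_B6 + count_Cast <= count_total, and (feature_id, sample_id)
    must be unique; violations raise with the offending row number
    (1-based, excluding the header).
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing required columns: {missing}")
    counts = table[["count_B6", "count_Cast", "count_total"]]
    neg = (counts < 0).any(axis=1)
    if neg.any():
        row = int(neg.idxmax()) + 1
        raise ValueError(f"negative count at row {row}")
    over = table["count_B6"] + table["count_Cast"] > table["count_total"]
    if over.any():
        row = int(over.idxmax()) + 1
        raise ValueError(f"allelic counts exceed total at row {row}")
    dup = table.duplicated(subset=["feature_id", "sample_id"])
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(f"duplicated (feature_id, sample_id) at row {row}")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def compute_dscores(table: pd.DataFrame, min_allelic_reads: int = 50) -> pd.DataFrame:
    """Per-sample d-scores with the minimum-allelic-reads filter.

    ``min_allelic_reads`` defaults to 50 (ChIP peaks); use 10 for genes
    and 20 for FLAG peaks.  A sample passes only with strictly more than
    the threshold of allelic reads.  A feature failing in any sample is
    flagged (``min_reads_pass`` False on all its rows), not dropped.
    d is nan where the allelic total is 0.
    """
    out = table.copy()
    allelic = out["count_B6"] + out["count_Cast"]
    out["allelic_total"] = allelic
    with np.errstate(invalid="ignore", divide="ignore"):
        out["dscore"] = np.where(allelic > 0, out["count_B6"] / allelic, np.nan)
    sample_pass = allelic > min_allelic_reads
    feature_pass = sample_pass.groupby(out["feature_id"]).transform("all")
    out["min_reads_pass"] = feature_pass & out["dscore"].notna()
    return out


def filter_biallelic(
    dscores: pd.DataFrame, low: float = 0.3, high: float = 0.7
) -> pd.DataFrame:
    """Flag features whose mean t=0 d-score is outside [low, high].

    The interval is closed: a feature at exactly 0.3 or 0.7 is retained.
    """
    out = dscores.copy()
    d0 = (
        out.loc[out["time_h"] == 0]
        .groupby("feature_id")["dscore"]
        .mean()
    )
    ok = (d0 >= low) & (d0 <= high) & d0.notna()
    out["biallelic_pass"] = out["feature_id"].map(ok).fillna(False).astype(bool)
    return out


def normalize_dscores(dscores: pd.DataFrame, per_replicate: bool = False) -> pd.DataFrame:
    """Normalise so every retained feature starts at 0.5.

    norm_d(t) = d(t) / d(0) / 2.  By default the t=0 denominator is the
    pooled mean over replicates; ``per_replicate=True`` divides each
    replicate by its own t=0 value instead.  Features with d(0) = 0 (or
    undefined) are flagged ``norm_defined`` False and left un-divided.
    """
    out = dscores.copy()
    t0 = out[out["time_h"] == 0]
    if per_replicate:
        d0 = t0.set_index(["feature_id", "replicate"])["dscore"]
        keys = pd.MultiIndex.from_frame(out[["feature_id", "replicate"]])
        denom = pd.Series(d0.reindex(keys).to_numpy(), index=out.index)
    else:
        d0 = t0.groupby("feature_id")["dscore"].mean()
        denom = out["feature_id"].map(d0)
    defined = denom.notna() & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["norm_dscore"] = np.where(defined, out["dscore"] / denom / 2.0, np.nan)
    out["norm_defined"] = defined.to_numpy()
    return out


def _quantile_ref(counts: np.ndarray, lib: np.ndarray) -> int:
    """edgeR reference choice: upper quartile closest to the mean one."""
    uq = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Doubly trimmed, weighted mean of M-values for one sample pair."""
    mask = (obs > 0) & (ref > 0)
    if mask.sum() == 0:
        return 1.0
    o, r = obs[mask], ref[mask]
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.abs(M).max() < 1e-6:
        return 1.0
    n = len(M)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(M), rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed-mean-of-M-values scale factors over reference features.

    Follows the published TMM defaults: 30% two-sided trim on M-values,
    5% on A-values, inverse-asymptotic-variance weights, reference
    sample chosen by upper-quartile proximity to the mean, and factors
    renormalised to geometric mean 1.  For allelic accumulation the
    reference features are B6 counts over autosomal consensus peaks.

    ``fit`` accepts a features x samples count matrix (DataFrame);
    ``transform`` divides a count matrix by the fitted factors.

    Fitted attributes: ``composition_factors_`` (the TMM factor proper,
    geometric mean 1 — what edgeR's calcNormFactors returns),
    ``scale_factors_`` (library size x composition factor, renormalised
    to geometric mean 1 — the factor counts are divided by, so a
    uniformly doubled sample gets a doubled factor), ``ref_sample_``.
    """

    def __init__(self, logratio_trim: float = 0.3, sum_trim: float = 0.05):
        self.logratio_trim = logratio_trim
        self.sum_trim = sum_trim

    def fit(self, counts: pd.DataFrame, y=None):
        X = counts.to_numpy(dtype=float)
        if X.shape[1] < 2:
            raise ValueError("TMM needs at least two samples")
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        lib = X.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("every sample needs positive library size")
        ref = _quantile_ref(X, lib)
        factors = np.array(
            [
                _tmm_pair(
                    X[:, j], X[:, ref], lib[j], lib[ref],
                    self.logratio_trim, self.sum_trim,
                )
                for j in range(X.shape[1])
            ]
        )
        factors /= np.exp(np.mean(np.log(factors)))
        # effective scale = library size x composition factor, anchored to
        # the reference sample: normalised counts stay on the reference
        # count scale and rescaling one sample never moves the others
        effective = factors * lib
        effective /= effective[ref]
        self.ref_sample_ = counts.columns[ref]
        self.composition_factors_ = pd.Series(
            factors, index=counts.columns, name="tmm_composition"
        )
        self.scale_factors_ = pd.Series(
            effective, index=counts.columns, name="tmm_factor"
        )
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts / self.scale_factors_[counts.columns]


def tmm_factors(
    table: pd.DataFrame, reference_features, value_col: str = "count_B6"
) -> pd.Series:
    """Per-sample TMM factors from a long count table.

    ``reference_features`` restricts the computation (autosomal
    consensus peaks in the accumulation analysis).
    """
    sub = table[table["feature_id"].isin(reference_features)]
    if sub.empty:
        raise ValueError("no reference features found in table")
    mat = sub.pivot(index="feature_id", columns="sample_id", values=value_col)
    return TMMNormalizer().fit(mat).scale_factors_


def input_outlier_windows(
    input_counts: pd.DataFrame, k: float = 1.5, log_scale: bool = False
) -> pd.Series:
    """Mask windows with outlier input counts (accessibility/mappability bias).

    ``input_counts`` is windows x input-samples.  A window is flagged if
    its count in any input sample lies above mean + k*sd or below
    mean - k*sd of that sample; statistics on the raw-count scale by
    default (``log_scale`` uses log1p counts).  Returns a boolean Series
    (True = outlier, to be discarded).
    """
    X = input_counts.astype(float)
    if log_scale:
        X = np.log1p(X)
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1).fillna(0.0)
    flagged = (X > mean + k * sd) | (X < mean - k * sd)
    return flagged.any(axis=1)


def accumulation_series(
    table: pd.DataFrame,
    factors: pd.Series,
    mask: pd.Series | None = None,
) -> pd.DataFrame:
    """TMM-normalised, t=0-subtracted B6 accumulation per feature/sample.

    normalised = count_B6 / factor; the feature's baseline (mean
    normalised signal over replicates at t=0) is subtracted from every
    time point, so accumulation at t=0 is exactly 0 up to replicate
    scatter (exactly 0 for a single replicate).  Windows in ``mask`` are
    flagged ``masked`` True.
    """
    out = table.copy()
    missing = set(out["sample_id"]) - set(factors.index)
    if missing:
        raise ValueError(f"no TMM factor for samples: {sorted(missing)}")
    out["normalized_B6"] = out["count_B6"] / out["sample_id"].map(factors)
    baseline = (
        out.loc[out["time_h"] == 0]
        .groupby("feature_id")["normalized_B6"]
        .mean()
    )
    if baseline.isna().any() or set(out["feature_id"]) - set(baseline.index):
        warnings.warn("features without a t=0 baseline get nan accumulation", UserWarning)
    out["accumulation"] = out["normalized_B6"] - out["feature_id"].map(baseline)
    if mask is not None:
        flagged = mask[mask].index if mask.dtype == bool else pd.Index(mask)
        out["masked"] = out["feature_id"].isin(flagged)
    else:
        out["masked"] = False
    return out
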