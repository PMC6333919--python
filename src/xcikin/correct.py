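"""Corrections for confounded allelic signal.

Two procedures:

* XO-contamination adjustment — cultures that accumulate XO cells (loss
  of one X) bias the allelic composition of the input.  The input's B6
  fraction p defines a normalisation factor nf = p / (1 - p), and each
  observed d-score is remapped so that a feature observed at the input
  fraction becomes biallelic (0.5):

      d_adj = d / (d + nf - nf * d)

* Induction-corrected log fold change — when only a fraction of cells
  induce Xist (measured by FISH cloud counts), the apparent dox/no-dox
  logFC is diluted.  A no-intercept linear model with one baseline per
  clone and a per-clone induction slope (~ 0 + clones + clones:induction)
  extrapolates to the logFC a fully induced population would show.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "xo_norm_factor",
    "adjust_dscore",
    "InductionEffectEstimator",
    "induction_corrected_logfc",
]


def xo_norm_factor(input_b6: float, input_cast: float) -> float:
    """Odds of the B6 allele in the input: p/(1-p) with p the B6 fraction.

    Raises on a Cast-free input (p = 1), where the factor is undefined.
    """
    if input_b6 < 0 or input_cast < 0:
        raise ValueError("input read counts must be non-negative")
    if input_b6 + input_cast <= 0:
        raise ValueError("input has no allelic reads")
    if input_cast == 0:
        raise ValueError("input B6 fraction is 1; normalisation factor undefined")
    p = input_b6 / (input_b6 + input_cast)
    return p / (1.0 - p)


def adjust_dscore(d, norm_factor: float):
    """Remap d-scores through the XO normalisation factor.

    d_adj = d / (d + nf - nf*d).  Identity at nf = 1; a d-score equal to
    the input B6 fraction maps to 0.5.  Strictly increasing bijection of
    [0, 1] onto itself for any nf > 0; the inverse is adjustment by 1/nf.
    """
    if norm_factor <= 0:
        raise ValueError("norm_factor must be positive")
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("d-scores must lie in [0, 1]")
    out = d / (d + norm_factor - norm_factor * d)
    return out if out.ndim else float(out)


class InductionEffectEstimator(BaseEstimator):
    """OLS fit of ~ 0 + clones + clones:induction per feature.

    Parameters
    ----------
    aggregate : bool
        Also report the unweighted mean of per-clone slopes.

    Fitted attributes
    -----------------
    clones_ : list of clone labels
    logfc_ : DataFrame (features x clones) of corrected logFC slopes
    se_ : DataFrame of slope standard errors (nan with 0 residual dof)
    mean_logfc_ : Series, unweighted mean slope across clones
    """

    def __init__(self, aggregate: bool = True):
        self.aggregate = aggregate

    def fit(self, signal: pd.DataFrame, design: pd.DataFrame):
        design = design.copy()
        frac = design["induction_fraction"].astype(float)
        if (frac > 1.0).any():
            warnings.warn(
                "induction_fraction values > 1 interpreted as percentages",
                UserWarning,
                stacklevel=2,
            )
            frac = frac / 100.0
        if ((frac < 0) | (frac > 1)).any() or not np.isfinite(frac).all():
            raise ValueError("induction fractions must be finite and in [0, 1]")
        design["induction_fraction"] = frac

        missing = set(design["sample_id"]) - set(signal.columns)
        if missing:
            raise ValueError(f"signal lacks design samples: {sorted(missing)}")
        clones = list(dict.fromkeys(design["clone"]))

        # design matrix: per-clone intercept, per-clone induction slope
        X = np.zeros((len(design), 2 * len(clones)))
        for i, row in enumerate(design.itertuples(index=False)):
            ci = clones.index(row.clone)
            X[i, ci] = 1.0
            X[i, len(clones) + ci] = row.induction_fraction
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = [
                c
                for c in clones
                if design.loc[design["clone"] == c, "induction_fraction"].nunique() < 2
            ]
            raise ValueError(
                "rank-deficient induction design; clones with a constant "
                f"induction covariate: {bad}"
            )

        Y = signal[list(design["sample_id"])].to_numpy(dtype=float).T  # samples x feats
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        dof = X.shape[0] - X.shape[1]
        XtX_inv = np.linalg.inv(X.T @ X)
        if dof > 0:
            sigma2 = (resid**2).sum(axis=0) / dof
            se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        else:
            se = np.full_like(beta, np.nan)

        k = len(clones)
        self.clones_ = clones
        self.logfc_ = pd.DataFrame(beta[k:].T, index=signal.index, columns=clones)
        self.se_ = pd.DataFrame(se[k:].T, index=signal.index, columns=clones)
        self.mean_logfc_ = self.logfc_.mean(axis=1)
        return self


def induction_corrected_logfc(
    signal: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature corrected logFC table (per-clone slopes, SEs, mean)."""
    est = InductionEffectEstimator().fit(signal, design)
    out = est.logfc_.add_prefix("logfc_")
    out = out.join(est.se_.add_prefix("se_"))
    out["mean_logfc"] = est.mean_logfc_
    return out
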