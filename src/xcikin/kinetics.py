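"""Per-feature sigmoid kinetics: LL.4 fits and derived time statistics.

Each feature's normalised d-score (or B6 accumulation) over the time
course is fitted with the four-parameter log-logistic curve

    f(t) = c + (d - c) / (1 + exp(b (ln t - ln e)))

pooling all samples into one fit (e.g. 10 points for 5 time points x
2 replicates).  Three statistics summarise the kinetics:

* IC threshold — the time the fitted curve crosses a normalised d-score
  level (default 0.35, i.e. half of the 0.5 -> 0.2 dynamic range),
  inverted in closed form;
* ED50 — the half-maximal time, the ``e`` parameter (the maximum-slope
  time of the sigmoid on the log axis);
* onset — the extremum of the analytic second derivative on (0, ED50),
  a proxy for when the curve starts to move.

Statistics beyond the experimental horizon (24 h) or undefined are
censored: set to the horizon and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .ll4 import invert_ll4, ll4, ll4_deriv2

__all__ = [
    "SigmoidFit",
    "LL4Regressor",
    "fit_ll4",
    "ic_threshold",
    "ed50",
    "onset_time",
    "residual_filter",
    "summarize_kinetics",
]

HORIZON = 24.0
#: fits with a dynamic range below this are classed flat and censored
FLAT_RANGE = 0.02
#: lower edge of the onset search interval (h); avoids the ln t singularity
ONSET_EPS = 1e-3


@dataclass
class SigmoidFit:
    """Fitted LL.4 parameters with fit quality."""

    b: float
    c: float
    d: float
    e: float
    residual_metric: float
    converged: bool

    @property
    def flat(self) -> bool:
        return abs(self.d - self.c) < FLAT_RANGE

    def predict(self, t):
        return ll4(t, self.b, self.c, self.d, self.e)


class LL4Regressor(BaseEstimator, RegressorMixin):
    """Least-squares LL.4 fit of a single response-vs-time series.

    Parameters
    ----------
    bounded : bool
        Constrain asymptotes to [0, 1] (d-score fits).  Accumulation
        fits use ``bounded=False``.
    increasing : bool
        Fit an increasing curve (b < 0), for accumulation series.
    residual_mode : {"ssr", "rms"}
        Residual metric: sum of squared residuals (default) or its
        root mean square.

    Fitted attributes: ``b_``, ``c_``, ``d_``, ``e_``,
    ``residual_metric_``, ``converged_``, ``fit_`` (a SigmoidFit).
    """

    def __init__(
        self,
        bounded: bool = True,
        increasing: bool = False,
        residual_mode: str = "ssr",
    ):
        self.bounded = bounded
        self.increasing = increasing
        self.residual_mode = residual_mode

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        keep = np.isfinite(t) & np.isfinite(y)
        t, y = t[keep], y[keep]
        if len(np.unique(t)) < 4:
            raise ValueError("LL.4 fit needs >= 4 distinct time points")

        sign = -1.0 if self.increasing else 1.0
        c0, d0 = float(np.min(y)), float(np.max(y))
        span = max(d0 - c0, 1e-6)
        tpos = t[t > 0]

        if self.bounded:
            lo = np.array([1e-3, 0.0, 0.0, np.log(1e-3)])
            hi = np.array([50.0, 1.0, 1.0, np.log(1e4)])
        else:
            # loose data-driven asymptote bounds keep the optimiser off
            # the degenerate straight-line ridge (d, e jointly divergent)
            lo = np.array([1e-3, c0 - 2 * span, c0 - 2 * span, np.log(1e-3)])
            hi = np.array([50.0, d0 + 5 * span, d0 + 5 * span, np.log(1e3)])

        def resid(x):
            b, c, d, loge = x
            return ll4(t, sign * b, c, d, float(np.exp(loge))) - y

        # multi-start over shape and half-way time; keep the best SSR
        e_starts = (
            np.quantile(tpos, [0.25, 0.5, 0.75]) if len(tpos) else np.array([1.0])
        )
        best, best_ssr, converged = None, np.inf, False
        for b_start in (0.5, 1.0, 2.0, 4.0):
            for e_start in np.unique(e_starts):
                x0 = np.clip(
                    np.array([b_start, c0, d0, np.log(max(e_start, 1e-3))]), lo, hi
                )
                try:
                    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
                except Exception:
                    continue
                ssr = float(np.sum(sol.fun**2))
                if ssr < best_ssr:
                    best, best_ssr, converged = sol.x, ssr, bool(sol.success)
        if best is None:
            b, c, d, loge = 1.0, c0, d0, np.log(np.median(tpos) if len(tpos) else 1.0)
        else:
            b, c, d, loge = best
        b = sign * b
        e = float(np.exp(loge))
        if c > d:
            c, d, b = d, c, -b
        r = ll4(t, b, c, d, e) - y
        ssr = float(np.sum(r * r))
        metric = float(np.sqrt(ssr / len(r))) if self.residual_mode == "rms" else ssr

        self.b_, self.c_, self.d_, self.e_ = float(b), float(c), float(d), e
        self.residual_metric_ = metric
        self.converged_ = converged
        self.fit_ = SigmoidFit(self.b_, self.c_, self.d_, self.e_, metric, converged)
        return self

    def predict(self, t):
        return ll4(t, self.b_, self.c_, self.d_, self.e_)


def fit_ll4(times, values, bounded: bool = True, increasing: bool = False,
            residual_mode: str = "ssr") -> SigmoidFit:
    """Fit one LL.4 curve; thin wrapper over LL4Regressor."""
    reg = LL4Regressor(bounded=bounded, increasing=increasing,
                       residual_mode=residual_mode)
    return reg.fit(times, values).fit_


def ic_threshold(
    fit: SigmoidFit, threshold: float = 0.35, horizon: float = HORIZON
) -> tuple[float, bool]:
    """Time at which the fitted curve reaches ``threshold``.

    Closed-form inversion of the LL.4 curve.  Returns (time, censored):
    crossings beyond the horizon, thresholds outside the fitted
    asymptote range, flat or unconverged fits all yield
    (horizon, True).
    """
    if not fit.converged or fit.flat:
        return horizon, True
    t = invert_ll4(threshold, fit.b, fit.c, fit.d, fit.e)
    if not np.isfinite(t) or t > horizon:
        return horizon, True
    return float(t), False


def ed50(fit: SigmoidFit, horizon: float = HORIZON) -> tuple[float, bool]:
    """Half-maximal time (the ``e`` parameter), censored at the horizon."""
    if not fit.converged or fit.flat or not np.isfinite(fit.e):
        return horizon, True
    if fit.e > horizon:
        return horizon, True
    return float(fit.e), False


def onset_time(
    fit: SigmoidFit, mode: str = "min", horizon: float = HORIZON
) -> tuple[float, bool]:
    """Extremum of the second derivative on (0, ED50).

    ``mode="min"`` for decreasing d-score curves (the curve starts to
    fall), ``mode="max"`` for increasing accumulation curves.  The
    search is restricted below ED50 so the symmetric extremum beyond
    the inflection is never picked.  Censored when ED50 is censored or
    the optimum is degenerate.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    ed, censored = ed50(fit, horizon=horizon)
    if censored:
        return horizon, True
    sign = 1.0 if mode == "min" else -1.0

    def objective(t):
        return sign * ll4_deriv2(t, fit.b, fit.c, fit.d, fit.e)

    res = minimize_scalar(objective, bounds=(ONSET_EPS, ed), method="bounded")
    t = float(res.x)
    if not res.success or not np.isfinite(t) or t > horizon:
        return horizon, True
    return t, False


def residual_filter(
    residuals, mode: str = "fixed", cutoff: float = 0.2, k: float = 1.5
) -> np.ndarray:
    """QC mask over fit residual metrics (True = pass).

    fixed: pass when residual < cutoff (the active-mark rule);
    adaptive: pass when residual < mean + k*sd over all supplied fits
    (the repressive-mark rule).
    """
    r = np.asarray(
        [f.residual_metric if isinstance(f, SigmoidFit) else f for f in residuals],
        dtype=float,
    )
    if mode == "fixed":
        return r < cutoff
    if mode == "adaptive":
        if len(r) == 0:
            return np.zeros(0, dtype=bool)
        sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
        return r < float(np.mean(r)) + k * sd + 1e-12
    raise ValueError("mode must be 'fixed' or 'adaptive'")


def summarize_kinetics(
    series: pd.DataFrame,
    value_col: str = "norm_dscore",
    thresholds: tuple = (0.35,),
    horizon: float = HORIZON,
    increasing: bool = False,
    residual_mode: str = "fixed",
    residual_cutoff: float = 0.2,
    residual_k: float = 1.5,
) -> pd.DataFrame:
    """Fit every feature and tabulate its kinetic statistics.

    ``series`` is a long frame with feature_id, time_h and ``value_col``
    (replicates pooled into one fit per feature).  Returns one row per
    feature: LL.4 parameters, residual metric, convergence, IC times
    per requested threshold, ED50, onset, censoring flags and the
    residual-filter ``qc_pass``.  Empty input yields an empty frame.
    """
    rows = []
    onset_mode = "max" if increasing else "min"
    for fid, grp in series.groupby("feature_id", sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        t = grp["time_h"].to_numpy(dtype=float)
        try:
            fit = fit_ll4(t, vals, bounded=not increasing, increasing=increasing)
        except ValueError:
            fit = SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)
        row = {
            "feature_id": fid,
            "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
            "residual_metric": fit.residual_metric,
            "converged": fit.converged,
        }
        for thr in thresholds:
            ic, cen = ic_threshold(fit, threshold=thr, horizon=horizon)
            label = f"ic{round(thr * 100):d}"
            row[label] = ic
            row[f"{label}_censored"] = cen
        row["ed50"], row["ed50_censored"] = ed50(fit, horizon=horizon)
        row["onset"], row["onset_censored"] = onset_time(
            fit, mode=onset_mode, horizon=horizon
        )
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["feature_id", "b", "c", "d", "e", "residual_metric", "converged"]
        )
    out = pd.DataFrame(rows)
    qc = residual_filter(
        out["residual_metric"].to_numpy(), mode=residual_mode,
        cutoff=residual_cutoff, k=residual_k,
    )
    out["qc_pass"] = qc & out["converged"]
    n_pass = int(out["qc_pass"].sum())
    if n_pass < len(out):
        warnings.warn(
            f"{len(out) - n_pass} of {len(out)} features fail the residual filter",
            UserWarning,
        )
    return out
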