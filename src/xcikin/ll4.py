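"""Four-parameter log-logistic (LL.4) curve in the drc parameterisation.

The response is

    f(t) = c + (d - c) / (1 + exp(b * (ln t - ln e)))
         = c + (d - c) / (1 + (t / e)**b)

with shape ``b``, lower asymptote ``c``, upper asymptote ``d`` and
half-way time ``e`` (hours).  For ``b > 0`` the curve decreases from
``d`` at t=0 to ``c`` as t grows; for ``b < 0`` it increases from ``c``.
The value at t = 0 is defined by the analytic limit rather than by a
pseudo-time offset.

All evaluations go through the logistic sigmoid of
z = b (ln t - ln e), which is overflow-free for any shape parameter.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["ll4", "ll4_deriv1", "ll4_deriv2", "invert_ll4"]


def _qw(t: np.ndarray, b: float, e: float) -> tuple[np.ndarray, np.ndarray]:
    """q = 1/(1+u) and w = u/(1+u) with u = (t/e)**b, via the sigmoid."""
    z = b * (np.log(t) - np.log(e))
    q = expit(-z)
    return q, 1.0 - q


def ll4(t, b: float, c: float, d: float, e: float):
    """Evaluate the LL.4 curve; t may be scalar or array, t >= 0.

    f(0) is the limit: d when b > 0, c when b < 0, midpoint when b == 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape, dtype=float)
    pos = t > 0
    q, _ = _qw(t[pos], b, e)
    out[pos] = c + (d - c) * q
    if b > 0:
        lim = d
    elif b < 0:
        lim = c
    else:
        lim = (c + d) / 2.0
    out[~pos] = lim
    return out if out.ndim else float(out)


def ll4_deriv1(t, b: float, c: float, d: float, e: float):
    """Analytic first derivative df/dt for t > 0 (0 at t=0 by the limit).

    f'(t) = -(d - c) * b * w * q / t   with q = 1/(1+u), w = 1-q.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    tp = t[pos]
    q, w = _qw(tp, b, e)
    out[pos] = -(d - c) * b * w * q / tp
    return out if out.ndim else float(out)


def ll4_deriv2(t, b: float, c: float, d: float, e: float):
    """Analytic second derivative d2f/dt2 for t > 0.

    f''(t) = -(d - c) * b * w * q * (b - 1 - 2*b*w) / t**2.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    tp = t[pos]
    q, w = _qw(tp, b, e)
    out[pos] = -(d - c) * b * w * q * (b - 1.0 - 2.0 * b * w) / (tp * tp)
    return out if out.ndim else float(out)


def invert_ll4(y: float, b: float, c: float, d: float, e: float) -> float:
    """Time at which the curve passes through response level ``y``.

    Closed-form inversion t* = e * ((d - c)/(y - c) - 1)**(1/b).
    Returns nan when the level is outside the open interval (c, d)
    (the curve never attains its asymptotes at finite positive time).
    """
    lo, hi = min(c, d), max(c, d)
    if not (lo < y < hi) or c == d:
        return float("nan")
    x = (d - c) / (y - c) - 1.0
    if x <= 0:
        return float("nan")
    return float(e * x ** (1.0 / b))
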