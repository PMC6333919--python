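"""Quantification of 1-D IF/RNA-FISH intensity profiles.

Each cell contributes intensity traces recorded along a line drawn from
inside the Xist RNA cloud out into the nucleoplasm, one trace per
channel (Xist plus one or more immunofluorescence channels).  The
pipeline: (1) detect the Xist-cloud boundary as the point of minimum
slope of the smoothed Xist signal; (2) re-centre the pixel axis on the
boundary and normalise each channel to a reference window (the Xist
peak just inside the boundary, or the IF plateau well outside it);
(3) average the aligned profiles over cells with an interquartile band;
(4) summarise per-cell within-cloud enrichment of the IF signal and
compare groups with a rank-sum test.

Profiles are consumed as long-format tables (cell_id, channel, pixel,
intensity); drawing the measurement axis on the image stack is a manual
upstream step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ranksums

__all__ = [
    "find_boundary",
    "align_and_normalize",
    "average_profiles",
    "cloud_enrichment",
]

#: reference window for the Xist channel, in pixels from the boundary
XIST_REF = (-4, -2)
#: reference window for IF channels (nucleoplasm plateau)
IF_REF = (15, 35)
#: within-cloud window for enrichment
CLOUD_WINDOW = (-10, 0)


def find_boundary(
    xist_profile, smooth: int = 3, flat_tol: float = 1e-9
) -> int:
    """Index of the Xist-cloud boundary: the point of minimum slope.

    The profile is smoothed with a ``smooth``-px moving average before
    the discrete first derivative is taken; the boundary is the pixel
    where the derivative is most negative (the signal drops fastest
    leaving the cloud).  A profile whose derivative range is below
    ``flat_tol`` has no boundary and raises.
    """
    y = np.asarray(xist_profile, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("profile must be 1-D with length >= 5")
    if smooth > 1:
        # edge-padded moving average: no spurious slope at the profile ends
        pad = smooth // 2
        padded = np.pad(y, pad, mode="edge")
        kernel = np.ones(smooth) / smooth
        y = np.convolve(padded, kernel, mode="valid")[: len(y)]
    # centred differences give a unique extremum at a symmetric step
    dy = np.gradient(y)
    if np.ptp(dy) < flat_tol:
        raise ValueError("flat profile: no boundary detectable")
    return int(np.argmin(dy))


def align_and_normalize(
    stack: pd.DataFrame,
    xist_channel: str = "xist",
    xist_ref: tuple = XIST_REF,
    if_ref: tuple = IF_REF,
    smooth: int = 3,
) -> pd.DataFrame:
    """Boundary-align and reference-normalise every cell's profiles.

    Per cell, the boundary is detected on the Xist channel and all
    channels are re-indexed to boundary-relative positions.  The Xist
    channel is divided by its mean over ``xist_ref``; every other
    channel by its mean over ``if_ref``.  Cells whose profiles do not
    cover the needed reference window (or have no boundary) are dropped
    with a warning.  Returns a long frame (cell_id, channel, position,
    intensity).
    """
    rows = []
    dropped = []
    for cell, grp in stack.groupby("cell_id", sort=False):
        pivot = grp.pivot_table(index="pixel", columns="channel", values="intensity")
        if xist_channel not in pivot.columns:
            dropped.append((cell, "no Xist channel"))
            continue
        xist = pivot[xist_channel].to_numpy(dtype=float)
        try:
            b = find_boundary(xist, smooth=smooth)
        except ValueError:
            dropped.append((cell, "no boundary"))
            continue
        pos = pivot.index.to_numpy() - pivot.index.to_numpy()[b]
        ok = True
        for channel in pivot.columns:
            ref = xist_ref if channel == xist_channel else if_ref
            win = (pos >= ref[0]) & (pos <= ref[1])
            vals = pivot[channel].to_numpy(dtype=float)
            if not win.any() or not np.isfinite(vals[win]).any():
                dropped.append((cell, f"reference window empty for {channel}"))
                ok = False
                break
            denom = float(np.nanmean(vals[win]))
            if denom <= 0:
                dropped.append((cell, f"non-positive reference mean for {channel}"))
                ok = False
                break
            for p, v in zip(pos, vals / denom):
                rows.append(
                    {"cell_id": cell, "channel": channel, "position": int(p),
                     "intensity": float(v)}
                )
        if not ok:
            rows = [r for r in rows if r["cell_id"] != cell]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} cell(s): {dropped[:5]}", UserWarning
        )
    return pd.DataFrame(rows, columns=["cell_id", "channel", "position", "intensity"])


def average_profiles(
    aligned: pd.DataFrame, min_coverage: float = 0.25
) -> pd.DataFrame:
    """Mean and interquartile band per channel and position.

    Positions contributed by fewer than ``min_coverage`` of the cells
    in a channel are excluded (profile edges covered by few cells).
    Returns a frame (channel, position, mean, q25, q75, n_cells).
    """
    out = []
    for channel, grp in aligned.groupby("channel", sort=False):
        n_total = grp["cell_id"].nunique()
        agg = grp.groupby("position")["intensity"].agg(
            mean="mean",
            q25=lambda v: v.quantile(0.25),
            q75=lambda v: v.quantile(0.75),
            n_cells="count",
        )
        agg = agg[agg["n_cells"] >= min_coverage * n_total]
        agg = agg.reset_index()
        agg.insert(0, "channel", channel)
        out.append(agg)
    if not out:
        return pd.DataFrame(columns=["channel", "position", "mean", "q25", "q75", "n_cells"])
    return pd.concat(out, ignore_index=True)


def cloud_enrichment(
    aligned: pd.DataFrame,
    channel: str = "if",
    window: tuple = CLOUD_WINDOW,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.Series, float | None]:
    """Per-cell within-cloud enrichment of an IF channel.

    The enrichment is the cell's mean normalised intensity over the
    within-cloud window (positions ``window[0]`` to ``window[1]``
    relative to the boundary); because the channel is normalised to its
    outside plateau, 1 means no difference from the nucleoplasm.  If
    ``groups`` maps cell_id to a group label (two groups), a two-sided
    rank-sum p-value comparing the groups is returned, else None.
    """
    ch = aligned[aligned["channel"] == channel]
    win = ch[(ch["position"] >= window[0]) & (ch["position"] <= window[1])]
    enrich = win.groupby("cell_id")["intensity"].mean()
    pvalue = None
    if groups is not None:
        g = pd.Series(groups)
        labels = g.reindex(enrich.index).dropna()
        uniq = labels.unique()
        if len(uniq) != 2:
            raise ValueError("rank-sum comparison needs exactly two groups")
        a = enrich[labels[labels == uniq[0]].index]
        b = enrich[labels[labels == uniq[1]].index]
        pvalue = float(ranksums(a, b).pvalue)
    return enrich, pvalue
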