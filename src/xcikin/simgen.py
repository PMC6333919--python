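"""Synthetic allele-specific count data with known ground truth.

Emulates a doxycycline induction time course in a hybrid (B6 x Cast)
cell line: per feature (ChIP peak, gene, or 10-kb window) and per sample,
allele-resolved read counts whose B6 fraction follows a four-parameter
log-logistic decay (active marks, transcription) or whose B6 counts
follow a sigmoidal accumulation (repressive marks).  Totals are
negative-binomial, the allelic split is binomial, and the generator can
plant escapees (constant biallelic ratio), XO-contaminated samples
(allele-biased input) and clones with incomplete induction.

Every generator returns the simulated table together with a truth table,
so estimator recovery can be measured against known parameters.  A
noiseless mode returns real-valued expected counts for exact oracle
tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correct import adjust_dscore, xo_norm_factor
from .ll4 import invert_ll4, ll4

__all__ = [
    "SimConfig",
    "simulate_timecourse",
    "simulate_accumulation",
    "simulate_mixture",
    "simulate_profiles",
]

#: Xist-cloud induction fractions measured by FISH for the four clones
#: of the non-hybrid (TXY) experiment, used as mixture defaults.
DEFAULT_INDUCTION_FRACTIONS = (0.4664, 0.5944, 0.5061, 0.4824)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic time course.

    Defaults mirror the experimental design: five time points
    {0, 4, 8, 12, 24} h in biological duplicates, ~300 allele-assignable
    reads per feature and sample (total depth 500 with 60% of reads
    carrying an informative SNP), mild negative-binomial overdispersion.
    """

    n_features: int = 200
    time_points: tuple = (0.0, 4.0, 8.0, 12.0, 24.0)
    n_replicates: int = 2
    total_count_mean: float = 500.0
    # NB dispersion = squared biological CV; 0.02 ~ BCV 0.14, typical of
    # biological duplicates of an isogenic cell line
    total_count_dispersion: float = 0.02
    allelic_fraction_of_total: float = 0.6
    truth_params: pd.DataFrame | None = None  # columns b, c, d, e
    escapee_fraction: float = 0.0
    xo_input_fraction: float | None = None
    induction_fractions: tuple | None = None
    noiseless: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        tp = tuple(float(t) for t in self.time_points)
        if list(tp) != sorted(tp) or 0.0 not in tp:
            raise ValueError("time_points must be sorted ascending and include 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.total_count_mean <= 0:
            raise ValueError("total_count_mean must be positive")
        if self.total_count_dispersion < 0:
            raise ValueError("total_count_dispersion must be >= 0")
        for name in ("allelic_fraction_of_total", "escapee_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.xo_input_fraction is not None and not 0.0 < self.xo_input_fraction < 1.0:
            raise ValueError("xo_input_fraction must lie in (0, 1)")
        if self.induction_fractions is not None:
            for f in self.induction_fractions:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"induction_fractions must lie in [0, 1], got {f}")
        if self.truth_params is not None:
            tr = self.truth_params
            ok = (tr["c"] >= 0) & (tr["c"] < tr["d"]) & (tr["d"] <= 1) & (tr["e"] > 0)
            if not bool(ok.all()):
                raise ValueError("truth_params must satisfy 0 <= c < d <= 1 and e > 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-feature LL.4 truth; sampled if not supplied in the config."""
    n = config.n_features
    if config.truth_params is not None:
        tr = config.truth_params.iloc[:n].reset_index(drop=True).copy()
        if len(tr) < n:
            raise ValueError("truth_params has fewer rows than n_features")
    else:
        tr = pd.DataFrame(
            {
                "b": rng.uniform(1.0, 3.0, n),
                "c": rng.uniform(0.05, 0.30, n),
                "d": rng.uniform(0.40, 0.60, n),
                "e": np.exp(rng.uniform(np.log(2.0), np.log(20.0), n)),
            }
        )
    n_esc = int(round(config.escapee_fraction * n))
    esc = np.zeros(n, dtype=bool)
    if n_esc:
        esc[rng.choice(n, size=n_esc, replace=False)] = True
    tr["escapee"] = esc
    return tr


def _truth_table(truth: pd.DataFrame, feature_ids: pd.Index) -> pd.DataFrame:
    """Attach true IC35/ED50 (on the normalized scale starting at 0.5)."""
    rows = []
    for fid, row in zip(feature_ids, truth.itertuples(index=False)):
        if row.escapee:
            ic35 = ed50 = np.nan
        else:
            # normalization divides by d(0)=d and by 2, so the normalized
            # curve is LL.4 with asymptotes d->0.5 and c->c/(2d)
            ic35 = invert_ll4(0.35, row.b, row.c / (2 * row.d), 0.5, row.e)
            ed50 = row.e
        rows.append(
            {
                "feature_id": fid,
                "b": row.b,
                "c": row.c,
                "d": row.d,
                "e": row.e,
                "escapee": row.escapee,
                "true_ic35": ic35,
                "true_ed50": ed50,
            }
        )
    return pd.DataFrame(rows)


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial with mean/dispersion parameterisation (Poisson at 0)."""
    mean = np.broadcast_to(np.asarray(mean, float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_timecourse(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate d-score-style allelic counts over the time course.

    Returns (counts, truth).  ``counts`` has one row per feature x sample
    with columns feature_id, chrom, start, end, sample_id, time_h,
    replicate, clone, condition, count_B6, count_Cast, count_total.
    The B6 fraction of feature f at time t is LL.4(t; truth_f); escapees
    sit at 0.5 throughout.  If ``config.xo_input_fraction`` is set, every
    sample's observed B6 fraction is distorted by the XO-contamination
    map (a biallelic feature then presents at the input fraction).
    """
    config.validate()
    rng = _rng(config)
    truth = _draw_truth(config, rng)
    fids = pd.Index([f"feat_{i:04d}" for i in range(config.n_features)])

    mean_allelic = config.total_count_mean * config.allelic_fraction_of_total
    nf = None
    if config.xo_input_fraction is not None:
        nf = xo_norm_factor(config.xo_input_fraction, 1.0 - config.xo_input_fraction)

    rows = []
    for i, fid in enumerate(fids):
        tr = truth.iloc[i]
        start = 1_000_000 + 10_000 * i
        for rep in range(1, config.n_replicates + 1):
            for t in config.time_points:
                p = 0.5 if tr["escapee"] else float(
                    ll4(t, tr["b"], tr["c"], tr["d"], tr["e"])
                )
                if nf is not None:
                    p = adjust_dscore(p, 1.0 / nf)  # forward contamination
                if config.noiseless:
                    allelic = mean_allelic
                    b6 = allelic * p
                    total = config.total_count_mean
                else:
                    allelic = int(
                        _nb_draw(rng, mean_allelic, config.total_count_dispersion, (1,))[0]
                    )
                    b6 = int(rng.binomial(allelic, p))
                    extra_mean = config.total_count_mean - mean_allelic
                    total = allelic + (
                        int(_nb_draw(rng, extra_mean, config.total_count_dispersion, (1,))[0])
                        if extra_mean > 0
                        else 0
                    )
                rows.append(
                    {
                        "feature_id": fid,
                        "chrom": "chrX",
                        "start": start,
                        "end": start + 1000,
                        "sample_id": f"t{t:g}_r{rep}",
                        "time_h": float(t),
                        "replicate": rep,
                        "clone": "WT",
                        "condition": "dox",
                        "count_B6": b6,
                        "count_Cast": (allelic - b6),
                        "count_total": total,
                    }
                )
    counts = pd.DataFrame(rows)
    return counts, _truth_table(truth, fids)


def simulate_accumulation(
    config: SimConfig, n_autosomal: int = 50, autosomal_mean: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate B6-read accumulation (repressive-mark gain) counts.

    X-linked features gain B6 reads along an increasing log-logistic:
    expected B6 count = total_count_mean * allelic_fraction * LL.4, with
    the truth table's (c, d) read as baseline and plateau fractions.
    Autosomal control features keep a constant expectation, providing
    the reference set for TMM normalization.
    """
    config.validate()
    rng = _rng(config)
    truth = _draw_truth(config, rng)
    fids = [f"feat_{i:04d}" for i in range(config.n_features)]
    scale = config.total_count_mean * config.allelic_fraction_of_total

    rows = []
    for i, fid in enumerate(fids):
        tr = truth.iloc[i]
        start = 1_000_000 + 10_000 * i
        for rep in range(1, config.n_replicates + 1):
            for t in config.time_points:
                if tr["escapee"]:
                    frac = tr["c"]
                else:
                    # increasing curve: b < 0 in the drc convention
                    frac = float(ll4(t, -tr["b"], tr["c"], tr["d"], tr["e"]))
                mean_b6 = scale * frac
                if config.noiseless:
                    b6 = mean_b6
                else:
                    b6 = int(_nb_draw(rng, mean_b6, config.total_count_dispersion, (1,))[0])
                rows.append(
                    {
                        "feature_id": fid,
                        "chrom": "chrX",
                        "start": start,
                        "end": start + 10_000,
                        "sample_id": f"t{t:g}_r{rep}",
                        "time_h": float(t),
                        "replicate": rep,
                        "clone": "WT",
                        "condition": "dox",
                        "count_B6": b6,
                        "count_Cast": 0,
                        "count_total": b6,
                    }
                )
    for j in range(n_autosomal):
        fid = f"auto_{j:04d}"
        mean_b6 = autosomal_mean if autosomal_mean is not None else scale
        start = 5_000_000 + 10_000 * j
        for rep in range(1, config.n_replicates + 1):
            for t in config.time_points:
                b6 = (
                    mean_b6
                    if config.noiseless
                    else int(_nb_draw(rng, mean_b6, config.total_count_dispersion, (1,))[0])
                )
                rows.append(
                    {
                        "feature_id": fid,
                        "chrom": "chr1",
                        "start": start,
                        "end": start + 10_000,
                        "sample_id": f"t{t:g}_r{rep}",
                        "time_h": float(t),
                        "replicate": rep,
                        "clone": "WT",
                        "condition": "dox",
                        "count_B6": b6,
                        "count_Cast": 0,
                        "count_total": b6,
                    }
                )
    counts = pd.DataFrame(rows)
    tt = _truth_table(truth, pd.Index(fids))
    tt["true_ed50"] = tt["e"].where(~tt["escapee"])
    return counts, tt


def simulate_mixture(
    config: SimConfig,
    n_clones: int = 4,
    true_logfc: float | np.ndarray = -2.0,
    baseline: float = 8.0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate log2 signal under incomplete Xist induction.

    Each clone contributes a no-dox and a dox sample.  The dox sample's
    expected log2 signal is baseline + induction_fraction * true_logfc:
    only the induced cells respond, so the apparent fold change shrinks
    with the induction fraction.  Returns (signal, design, truth) where
    ``signal`` is features x samples, ``design`` carries sample_id,
    clone, dox, induction_fraction.
    """
    config.validate()
    rng = _rng(config)
    fracs = config.induction_fractions
    if fracs is None:
        fracs = DEFAULT_INDUCTION_FRACTIONS[:n_clones] if n_clones <= 4 else tuple(
            rng.uniform(0.4, 0.6, n_clones)
        )
    if len(fracs) != n_clones:
        raise ValueError("need one induction fraction per clone")
    for f in fracs:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"induction fraction outside [0, 1]: {f}")

    n = config.n_features
    logfc = np.broadcast_to(np.asarray(true_logfc, float), (n,))
    fids = [f"feat_{i:04d}" for i in range(n)]

    design_rows, cols = [], {}
    for ci, frac in enumerate(fracs):
        clone = f"clone{ci + 1}"
        for dox, ind in (("no", 0.0), ("yes", float(frac))):
            sid = f"{clone}_{'dox' if dox == 'yes' else 'nodox'}"
            design_rows.append(
                {"sample_id": sid, "clone": clone, "dox": dox, "induction_fraction": ind}
            )
            mu = baseline + ind * logfc
            eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
            cols[sid] = mu + eps
    signal = pd.DataFrame(cols, index=pd.Index(fids, name="feature_id"))
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame({"feature_id": fids, "true_logfc": logfc})
    return signal, design, truth


def simulate_profiles(
    n_cells: int = 50,
    boundary_position: int = 40,
    enrichment_ratio: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pixels: int = 80,
    boundary_jitter: int = 2,
    step_width: float = 1.5,
) -> pd.DataFrame:
    """Simulate per-cell 1-D IF/RNA-FISH intensity traces.

    The Xist channel is a smooth sigmoidal step, high inside the cloud
    (low pixel coordinates) and dropping across the programmed boundary;
    the IF channel sits at ``enrichment_ratio`` inside the cloud and at
    1 outside.  Returns a long-format frame (cell_id, channel, pixel,
    intensity) with a ``true_boundary`` column per cell.
    """
    if n_pixels < 5:
        raise ValueError("n_pixels must be >= 5")
    if not 0 < boundary_position < n_pixels - 1:
        raise ValueError("boundary_position must lie inside the pixel range")
    rng = np.random.default_rng(seed)
    px = np.arange(n_pixels, dtype=float)
    rows = []
    for ci in range(n_cells):
        jitter = int(rng.integers(-boundary_jitter, boundary_jitter + 1)) if boundary_jitter else 0
        b0 = boundary_position + jitter
        xist = 0.05 + 0.95 / (1.0 + np.exp((px - b0) / step_width))
        # hard step for the IF channel: the programmed within-cloud /
        # outside ratio holds exactly over the whole cloud window
        if_ch = np.where(px <= b0, enrichment_ratio, 1.0).astype(float)
        if noise_sd > 0:
            xist = np.clip(xist + rng.normal(0, noise_sd, n_pixels), 0, None)
            if_ch = np.clip(if_ch + rng.normal(0, noise_sd, n_pixels), 0, None)
        for channel, vals in (("xist", xist), ("if", if_ch)):
            for p, v in zip(px.astype(int), vals):
                rows.append(
                    {
                        "cell_id": f"cell_{ci:03d}",
                        "channel": channel,
                        "pixel": p,
                        "intensity": float(v),
                        "true_boundary": b0,
                    }
                )
    return pd.DataFrame(rows)
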