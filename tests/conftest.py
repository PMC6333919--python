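import numpy as np
import pandas as pd
import pytest

import xcikin as xk


@pytest.fixture(scope="session")
def timecourse_500():
    """200-feature time course at ~500 allelic reads/sample, fixed seed."""
    cfg = xk.SimConfig(
        n_features=200, total_count_mean=500, allelic_fraction_of_total=1.0, seed=11
    )
    counts, truth = xk.simulate_timecourse(cfg)
    return counts, truth


@pytest.fixture(scope="session")
def fitted_summary(timecourse_500):
    """Filtered, normalised and fitted kinetics for the shared time course."""
    counts, truth = timecourse_500
    s = xk.compute_dscores(counts, min_allelic_reads=50)
    s = xk.filter_biallelic(s)
    s = xk.normalize_dscores(s)
    keep = s["min_reads_pass"] & s["biallelic_pass"] & s["norm_defined"]
    summary = xk.summarize_kinetics(s[keep])
    return summary.merge(truth, on="feature_id")


@pytest.fixture()
def tiny_counts():
    """Hand-written 2-feature, 2-sample count table."""
    return pd.DataFrame(
        {
            "feature_id": ["a", "a", "b", "b"],
            "sample_id": ["t0_r1", "t24_r1", "t0_r1", "t24_r1"],
            "time_h": [0.0, 24.0, 0.0, 24.0],
            "replicate": [1, 1, 1, 1],
            "count_B6": [50, 30, 20, 10],
            "count_Cast": [50, 70, 20, 80],
            "count_total": [120, 110, 50, 100],
        }
    )


def grid_ic(b, c, d, e, threshold, horizon=24.0, n=10_000):
    """Brute-force IC-threshold time: densest grid point where the curve
    first crosses the threshold (independent of the closed form)."""
    from xcikin.ll4 import ll4

    t = np.linspace(1e-6, horizon, n)
    y = ll4(t, b, c, d, e)
    below = np.nonzero(y <= threshold)[0] if d > c else np.nonzero(y >= threshold)[0]
    if len(below) == 0:
        return None
    return float(t[below[0]])
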