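"""Constructed activity maps with known correlation structure, shared by the
connectivity and acceptance tests."""

import numpy as np

from meafield.activity import ActivityMap
from meafield.connectivity import (
    activity_autocovariance_spatial,
    activity_autocovariance_temporal,
)
from meafield.simulate import paper_like_layout


def make_activity_map(values, window_s=0.5):
    n_el, n_win = values.shape
    layout = paper_like_layout()
    return ActivityMap(
        electrodes=layout.active_indices[:n_el],
        window_times=window_s * 1000.0 * (np.arange(n_win) + 0.5),
        values=values,
        window=window_s * 1000.0,
    )


def ou_series(rng, n, dt_s, rate_s, sd=1.0):
    a = np.exp(-rate_s * dt_s)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for t in range(1, n):
        x[t] = a * x[t - 1] + rng.normal(0, sd * np.sqrt(1 - a * a))
    return x


def known_temporal_activity(beta_true=0.1, n_seeds=10):
    """Activity maps whose spatial mean is an OU process with rate β."""
    dt_s = 0.5
    fits = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(5000 + seed)
        common = ou_series(rng, 4000, dt_s, beta_true)
        values = 0.035 * (1.0 + 0.3 * common)[None, :] + 0.002 * rng.standard_normal(
            (8, 4000)
        )
        fit = activity_autocovariance_temporal(
            make_activity_map(values, dt_s), max_lag=30.0, fit_range=(2.0, 20.0)
        )
        fits.append(fit.decay_constant)
    return beta_true, fits


def known_spatial_activity(kappa_true=1.4, n_seeds=10, n_win=400):
    """Activity maps drawn with equal-time covariance exp(−κ|Δr|)."""
    layout = paper_like_layout()
    pos = layout.positions[layout.active_indices]
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    cov = np.exp(-kappa_true * d)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(d)))
    fits = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(6000 + seed)
        g = L @ rng.standard_normal((len(d), n_win))
        values = 0.035 * (1.0 + 0.3 * g)
        fit = activity_autocovariance_spatial(
            make_activity_map(values), layout, fit_range=(0.2, 1.2)
        )
        fits.append(fit.decay_constant)
    return kappa_true, fits
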