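"""Space-time activity estimation from the short-lag logarithmic law.

The short-lag covariance of the field at one electrode obeys
⟨p(r, t)·p(r, t+δt)⟩ = σ²(r, t)/(8πα) · (−log(γδt) + O(1)), so with the
diffusion constant α already known from the global fit, the local activity
σ²(r, t) is 8πα times the slope of windowed lagged products against
−log δt — the constant inside the log, the O(1) term and any slowly varying
covariance contribution (equilibrium potential, periodic artifact) are all
absorbed by the regression intercept.  Expectations are approximated by
averaging over windows of at least ~100 ms, which bounds the temporal
resolution of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import ElectrodeLayout, Recording

__all__ = [
    "ActivityEstimationParams",
    "ActivityMap",
    "estimate_activity",
    "activity_summary",
    "quadrant_regions",
]


def default_activity_lags(sampling_interval: float) -> np.ndarray:
    """Eight log-uniform lags in 0.2–10 ms, snapped to the sample grid.

    The band sits above the measurement-error artifact support (0.2 ms) and
    well below the slow regime; at coarse sampling rates snapping and
    deduplication can return fewer points.
    """
    raw = np.geomspace(0.2, 10.0, 8)
    snapped = np.unique(np.maximum(np.round(raw / sampling_interval), 1)) * sampling_interval
    return snapped[snapped <= 10.0 + 1e-9]


@dataclass(frozen=True)
class ActivityEstimationParams:
    """Controls of the windowed log-slope estimator.

    ``alpha`` must come from a field-model fit.  ``window`` ≥ 100 ms; the
    default 1000 ms with 50% overlap matches the 1 s resolution at which
    region time courses are typically displayed.
    """

    alpha: float  # mm²·ms⁻¹, from the fitted field model
    lag_grid: Optional[np.ndarray] = None  # ms; default log-uniform in 0.2–10
    window: float = 1000.0  # ms
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.window < 100.0:
            raise ValueError("window must be at least 100 ms")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class ActivityMap:
    """Windowed activity estimates σ²(r, t) per active electrode.

    ``values[i, w]`` is the estimate (μV²·mm²·ms⁻¹, clipped at 0) for
    electrode ``electrodes[i]`` in the window centered at
    ``window_times[w]`` (ms); ``n_clipped`` counts negative slopes set to 0.
    """

    electrodes: np.ndarray  # layout indices of the rows
    window_times: np.ndarray  # ms, window centers
    values: np.ndarray  # (n_el, n_win) μV² mm² ms⁻¹
    window: float  # ms
    n_clipped: int = 0

    @property
    def temporal_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def spatial_mean_series(self) -> np.ndarray:
        """σ²_mean(t): mean over the electrode domain, per window."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (int(e), float(t - self.window / 2), float(self.values[i, w]))
            for i, e in enumerate(self.electrodes)
            for w, t in enumerate(self.window_times)
        ]
        return pd.DataFrame(rows, columns=["electrode", "window_start_ms", "sigma2"])


def estimate_activity(rec: Recording, params: ActivityEstimationParams) -> ActivityMap:
    """Estimate σ²(r, t) on overlapping windows of a despiked recording.

    Per electrode and window, lagged products of the mean-removed trace are
    regressed on −log δt; the slope s maps to activity as σ² = 8πα·s, with
    negative slopes (possible in quiet windows) clipped to zero and counted.
    """
    si = rec.sampling_interval
    lags = params.lag_grid if params.lag_grid is not None else default_activity_lags(si)
    lags = np.asarray(lags, dtype=float)
    ells = np.round(lags / si).astype(int)
    if not np.allclose(ells * si, lags, atol=1e-9):
        raise ValueError("lag grid must be multiples of the sampling interval")
    if len(np.unique(ells)) < 2:
        raise ValueError("need at least two distinct lags for the slope")
    if np.any(ells < 1):
        raise ValueError("lags must be at least one sampling interval")
    wlen = int(round(params.window / si))
    if wlen < 10 * ells.max():
        raise ValueError("window must be at least 10 × the largest lag")
    step = max(1, int(round(wlen * (1.0 - params.overlap))))
    active = rec.layout.active_indices
    p = rec.potentials[active]
    n = p.shape[1]
    starts = np.arange(0, n - wlen + 1, step)
    x = -np.log(ells * si)
    xc = x - x.mean()
    slope_w = xc / np.sum(xc**2)  # regression weights: slope = Σ w_l · c_l

    values = np.empty((len(active), len(starts)))
    for wi, s0 in enumerate(starts):
        seg = p[:, s0 : s0 + wlen]
        seg = seg - seg.mean(axis=1, keepdims=True)
        cov = np.empty((len(active), len(ells)))
        for li, ell in enumerate(ells):
            cov[:, li] = np.mean(seg[:, : wlen - ell] * seg[:, ell:], axis=1)
        values[:, wi] = cov @ slope_w
    values *= 8.0 * np.pi * params.alpha
    n_clipped = int(np.sum(values < 0))
    np.clip(values, 0.0, None, out=values)
    return ActivityMap(
        electrodes=active,
        window_times=(starts + wlen / 2.0) * si,
        values=values,
        window=params.window,
        n_clipped=n_clipped,
    )


def quadrant_regions(layout: ElectrodeLayout) -> dict:
    """Partition active electrodes into the four quadrants of the array."""
    active = layout.active_indices
    pos = layout.positions[active]
    xm, ym = np.median(pos[:, 0]), np.median(pos[:, 1])
    out: dict = {}
    for e, (px, py) in zip(active, pos):
        name = ("upper" if py > ym else "lower") + "_" + ("right" if px > xm else "left")
        out.setdefault(name, []).append(int(e))
    return {k: np.array(v) for k, v in sorted(out.items())}


def activity_summary(
    amap: ActivityMap,
    region_map: Optional[Mapping[int, str]] = None,
    coarse_window: float = 1.0,
) -> dict:
    """Temporal means per electrode and per-region coarse time courses.

    ``coarse_window`` is in seconds (default 1 s).  Returns a dict with
    ``per_electrode`` (DataFrame: electrode, mean sigma2) and ``regions``
    (DataFrame: time_s, one column per region).
    """
    per_el = pd.DataFrame(
        {"electrode": amap.electrodes, "sigma2_mean": amap.temporal_mean}
    )
    t_s = amap.window_times / 1000.0
    edges = np.arange(0.0, t_s.max() + coarse_window, coarse_window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(t_s, edges) - 1, 0, len(centers) - 1)
    regions_df = pd.DataFrame({"time_s": centers})
    region_map = region_map or {int(e): "all" for e in amap.electrodes}
    for reg in sorted(set(region_map.values())):
        rows = [i for i, e in enumerate(amap.electrodes) if region_map.get(int(e)) == reg]
        series = amap.values[rows].mean(axis=0)
        coarse = np.full(len(centers), np.nan)
        for b in range(len(centers)):
            sel = idx == b
            if sel.any():
                coarse[b] = series[sel].mean()
        regions_df[reg] = coarse
    return {"per_electrode": per_el, "regions": regions_df}
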