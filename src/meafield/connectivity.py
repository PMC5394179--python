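"""Correlation structure of the activity field.

The activity σ²(r, t) estimated per electrode and window is treated as a
given space-time function and characterized descriptively: exponential-decay
fits to its temporal autocovariance (spatial mean series, decay constant β
in s⁻¹) and its spatial autocovariance (pooled by electrode separation,
decay constant κ in mm⁻¹), plus Pearson correlations between adjacent
electrode pairs rendered as a connectivity graph whose edge weights are the
fourth power of the correlation coefficient.  Correlation is symmetric under
electrode exchange, so no direction of information flow is implied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import logging

import networkx as nx
import numpy as np
import pandas as pd

from .activity import ActivityMap
from .io import ElectrodeLayout

__all__ = [
    "DecayFit",
    "activity_autocovariance_temporal",
    "activity_autocovariance_spatial",
    "adjacent_pair_correlations",
    "export_graph",
]


@dataclass
class DecayFit:
    """Exponential-decay fit to a normalized autocorrelation.

    ``decay_constant`` is β (s⁻¹) for kind='temporal' or κ (mm⁻¹) for
    kind='spatial'; ``abscissa``/``autocorrelation`` tabulate the normalized
    curve (1 at the origin).
    """

    kind: str
    decay_constant: float
    fit_range: tuple
    r_squared: float
    abscissa: np.ndarray  # s (temporal) or mm (spatial)
    autocorrelation: np.ndarray


def _log_linear_decay(x, ac, fit_range, kind) -> DecayFit:
    """Fit log(autocorrelation) = c − k·x inside the range; if non-positive
    values intrude, the range is shrunk to end before the first one (with a
    warning)."""
    sel = (x >= fit_range[0]) & (x <= fit_range[1])
    bad = sel & (ac <= 0)
    if bad.any():
        cutoff = x[bad].min()
        sel &= x < cutoff
        logging.getLogger(__name__).warning(
            "%s autocorrelation non-positive at %g; fit range shrunk", kind, cutoff
        )
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 usable points in the {kind} fit range {fit_range}")
    coef = np.polyfit(x[sel], np.log(ac[sel]), 1)
    pred = np.polyval(coef, x[sel])
    r = np.log(ac[sel])
    sst = np.sum((r - r.mean()) ** 2)
    r2 = 1.0 - np.sum((r - pred) ** 2) / sst if sst > 0 else np.nan
    k = -coef[0]
    if k <= 0:
        raise ValueError(f"{kind} autocorrelation does not decay over {fit_range}")
    return DecayFit(
        kind=kind,
        decay_constant=float(k),
        fit_range=(float(x[sel].min()), float(x[sel].max())),
        r_squared=float(r2),
        abscissa=x,
        autocorrelation=ac,
    )


def activity_autocovariance_temporal(
    amap: ActivityMap,
    max_lag: float = 30.0,
    fit_range: tuple = (2.0, 20.0),
) -> DecayFit:
    """Temporal autocovariance of the spatial-mean activity, with β fit.

    Lags and the fit range are in seconds; the default range starts at 2 s
    because windowing smears the smallest lags.  The autocorrelation is
    normalized to 1 at zero lag.
    """
    series = amap.spatial_mean_series
    dt_s = (amap.window_times[1] - amap.window_times[0]) / 1000.0 if len(
        amap.window_times
    ) > 1 else amap.window / 1000.0
    n = len(series)
    max_k = min(int(round(max_lag / dt_s)), n - 2)
    if max_k < 2:
        raise ValueError("activity series too short for the requested max lag")
    x = series - series.mean()
    ac = np.array([np.mean(x[: n - k] * x[k:]) for k in range(max_k + 1)])
    if ac[0] <= 0:
        raise ValueError("activity series has zero variance")
    ac /= ac[0]
    lags_s = np.arange(max_k + 1) * dt_s
    return _log_linear_decay(lags_s, ac, fit_range, "temporal")


def activity_autocovariance_spatial(
    amap: ActivityMap,
    layout: ElectrodeLayout,
    fit_range: tuple = (0.4, 1.2),
    separation_tolerance: float = 1e-6,
) -> DecayFit:
    """Equal-time activity covariance pooled by separation, with κ fit.

    Separations and the fit range are in mm; the default range starts at
    0.4 mm because estimation noise inflates the smallest separations.
    Normalized by the Δr = 0 bin (the pooled variance).
    """
    rows = {int(e): i for i, e in enumerate(amap.electrodes)}
    x = amap.values - amap.values.mean(axis=1, keepdims=True)
    els = [int(e) for e in amap.electrodes if int(e) in rows]
    pos = {int(e): layout.positions[int(e)] for e in els}
    pair_cov: dict = {}
    for a in range(len(els)):
        for b in range(a, len(els)):
            ea, eb = els[a], els[b]
            d = float(np.hypot(*(pos[ea] - pos[eb])))
            key = round(d / separation_tolerance) * separation_tolerance
            c = float(np.mean(x[rows[ea]] * x[rows[eb]]))
            pair_cov.setdefault(key, []).append(c)
    if len(pair_cov) < 3:
        raise ValueError("need at least 3 distinct separations")
    seps = np.array(sorted(pair_cov))
    cov = np.array([np.mean(pair_cov[s]) for s in seps])
    if cov[0] <= 0:
        raise ValueError("pooled activity variance is zero")
    ac = cov / cov[0]
    return _log_linear_decay(seps, ac, fit_range, "spatial")


def adjacent_pair_correlations(
    amap: ActivityMap,
    layout: ElectrodeLayout,
    adjacency_distance: float = 0.2,
    tolerance: float = 1e-6,
) -> nx.Graph:
    """Pearson correlation of activity time series on adjacent electrodes.

    One edge per pair at exactly ``adjacency_distance`` (grid neighbours, not
    diagonals), with attributes ``pearson_r`` and ``weight`` = r⁴; pairs with
    a constant series are flagged on the graph (``excluded_pairs``) and get
    no edge.
    """
    if amap.values.shape[1] < 2:
        raise ValueError("need at least 2 activity windows for correlations")
    g = nx.Graph(adjacency_distance=adjacency_distance, excluded_pairs=[])
    rows = {int(e): i for i, e in enumerate(amap.electrodes)}
    for e in amap.electrodes:
        e = int(e)
        g.add_node(e, x_mm=float(layout.positions[e, 0]), y_mm=float(layout.positions[e, 1]))
    els = sorted(rows)
    for i, ea in enumerate(els):
        for eb in els[i + 1 :]:
            d = float(np.hypot(*(layout.positions[ea] - layout.positions[eb])))
            if abs(d - adjacency_distance) > tolerance:
                continue
            sa, sb = amap.values[rows[ea]], amap.values[rows[eb]]
            if np.ptp(sa) == 0 or np.ptp(sb) == 0:  # constant series: r undefined
                g.graph["excluded_pairs"].append((ea, eb))
                continue
            r = float(np.corrcoef(sa, sb)[0, 1])
            g.add_edge(ea, eb, pearson_r=r, weight=r**4)
    return g


def export_graph(graph: nx.Graph, path) -> Path:
    """Write the connectivity graph as an edge-list TSV.

    Columns: node1, node2, x1_mm, y1_mm, x2_mm, y2_mm, pearson_r, weight.
    """
    path = Path(path)
    rows = []
    for a, b, data in graph.edges(data=True):
        rows.append(
            (
                a,
                b,
                graph.nodes[a]["x_mm"],
                graph.nodes[a]["y_mm"],
                graph.nodes[b]["x_mm"],
                graph.nodes[b]["y_mm"],
                data["pearson_r"],
                data["weight"],
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["node1", "node2", "x1_mm", "y1_mm", "x2_mm", "y2_mm", "pearson_r", "weight"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path
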