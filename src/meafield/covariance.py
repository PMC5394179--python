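"""Empirical spatio-temporal covariance S(ρ, τ), artifact subtraction and the
slow/fast decomposition.

The estimator assumes stationarity in time and homogeneity/isotropy in space:
all active-electrode pairs whose separation falls in a bin are pooled, and
lags are symmetrized over ±τ.  Two instrumental artifact components are
estimated from the ρ = 0 row and subtracted: an almost perfectly periodic
common-mode component (145 ms period) visible at lags beyond ~1 s, and a
rapidly decaying component (support ≲ 0.2 ms) due to independent errors in
the individual voltage measurements.  The cleaned table is then decomposed as
S(ρ, τ) = S_slow(τ) + S_fast(ρ, τ) with S_slow taken to be the row at the
largest available separation, where the fast (activity-driven) part is
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Recording

__all__ = [
    "CovarianceTable",
    "ArtifactProfiles",
    "CovarianceDecomposition",
    "estimate_covariance",
    "estimate_periodic_artifact",
    "estimate_short_lag_artifact",
    "remove_artifacts",
    "decompose_slow_fast",
    "default_lag_grid",
]


@dataclass(frozen=True)
class CovarianceTable:
    """Empirical S(ρ, τ) over separation bins and non-negative lags.

    ``values[i, j]`` is the mean of p(r1, t)·p(r2, t+τ_j) over all (ordered)
    active-electrode pairs in separation bin ρ_i and all valid t, after
    per-trace global mean subtraction; the ρ = 0 bin pools self-pairs only.
    """

    separations: np.ndarray  # (ns,) mm, sorted
    lags: np.ndarray  # (nl,) ms, sorted, >= 0
    values: np.ndarray  # (ns, nl) μV²
    pair_counts: np.ndarray  # (ns,) contributing unordered pairs (self for ρ=0)
    sample_counts: np.ndarray  # (nl,) contributing time samples

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariance values must be finite")
        if np.any(self.pair_counts < 1):
            raise ValueError("every separation bin must have at least one pair")

    def row(self, rho: float, tol: float = 1e-6) -> np.ndarray:
        i = self._bin_index(rho, tol)
        return self.values[i]

    def _bin_index(self, rho: float, tol: float = 1e-6) -> int:
        hits = np.nonzero(np.abs(self.separations - rho) <= tol)[0]
        if hits.size == 0:
            raise ValueError(f"no separation bin at {rho} mm (have {self.separations})")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format (rho_mm, tau_ms, value_uV2, n_pairs)."""
        rows = [
            (rho, tau, self.values[i, j], int(self.pair_counts[i]))
            for i, rho in enumerate(self.separations)
            for j, tau in enumerate(self.lags)
        ]
        return pd.DataFrame(rows, columns=["rho_mm", "tau_ms", "value_uV2", "n_pairs"])


@dataclass(frozen=True)
class ArtifactProfiles:
    """Temporal covariance offsets of the two artifact classes.

    ``periodic_profile`` is one period of the common-mode component (zero
    mean over the period, defined on ``periodic_phase``); ``short_lag_profile``
    is the measurement-error component on ``short_lag_lags`` (zero beyond its
    support).  Either part may be absent (None).
    """

    period: Optional[float] = None  # ms
    periodic_phase: Optional[np.ndarray] = None  # ms in [0, period)
    periodic_profile: Optional[np.ndarray] = None  # μV²
    short_lag_support: Optional[float] = None  # ms
    short_lag_lags: Optional[np.ndarray] = None  # ms
    short_lag_profile: Optional[np.ndarray] = None  # μV²

    def periodic_at(self, lags) -> np.ndarray:
        """Periodic profile extended to arbitrary lags (wrap-around linear
        interpolation), including down to τ = 0."""
        if self.periodic_profile is None:
            return np.zeros_like(np.asarray(lags, dtype=float))
        phase = np.mod(np.asarray(lags, dtype=float), self.period)
        xp = np.concatenate([self.periodic_phase, [self.period]])
        fp = np.concatenate([self.periodic_profile, [self.periodic_profile[0]]])
        return np.interp(phase, xp, fp)


@dataclass(frozen=True)
class CovarianceDecomposition:
    """S(ρ, τ) = S_slow(τ) + S_fast(ρ, τ) with S_slow := S(ρ_large, τ)."""

    slow: np.ndarray  # (nl,) μV²
    fast: CovarianceTable
    rho_large: float  # mm


def default_lag_grid(sampling_interval: float, max_lag: float = 100.0) -> np.ndarray:
    """Log-spaced lags from one sampling interval to ``max_lag`` ms, snapped
    to the sample grid (deduplicated)."""
    raw = np.geomspace(sampling_interval, max_lag, 40)
    snapped = np.unique(np.round(raw / sampling_interval)) * sampling_interval
    return np.concatenate([[0.0], snapped])


def _lag_samples(lags, sampling_interval: float) -> np.ndarray:
    lags = np.asarray(lags, dtype=float)
    ells = np.round(lags / sampling_interval).astype(int)
    if not np.allclose(ells * sampling_interval, lags, atol=1e-9):
        raise ValueError("lags must be multiples of the sampling interval")
    return np.unique(ells)


def estimate_covariance(
    rec: Recording,
    lags: Sequence[float],
    separation_tolerance: float = 1e-6,
    max_separation: Optional[float] = None,
    auto_only: bool = False,
) -> CovarianceTable:
    """Estimate S(ρ, τ) from a (despiked) recording.

    Parameters
    ----------
    lags : sequence of float
        Non-negative lags in ms; must be multiples of the sampling interval.
    separation_tolerance : float
        Pair separations within this tolerance share a bin (grid distances
        are exact, so the default is tight).
    max_separation : float, optional
        Drop bins beyond this separation.
    auto_only : bool
        Estimate only the ρ = 0 row (per-electrode autocovariances, computed
        by FFT — much faster for dense lag grids).
    """
    ells = _lag_samples(lags, rec.sampling_interval)
    if ells[-1] >= rec.n_samples:
        raise ValueError("largest lag exceeds the recording duration")
    active = rec.layout.active_indices
    p = rec.potentials[active].astype(float)
    p = p - p.mean(axis=1, keepdims=True)
    n = p.shape[1]
    lag_ms = ells * rec.sampling_interval
    sample_counts = n - ells

    if auto_only:
        nfft = 1
        while nfft < 2 * n:
            nfft *= 2
        f = np.fft.rfft(p, nfft, axis=1)
        acf = np.fft.irfft((f * np.conj(f)).real, nfft, axis=1)[:, : ells[-1] + 1]
        acf /= (n - np.arange(ells[-1] + 1))[None, :]
        values = acf[:, ells].mean(axis=0)[None, :]
        return CovarianceTable(
            separations=np.array([0.0]),
            lags=lag_ms,
            values=values,
            pair_counts=np.array([p.shape[0]]),
            sample_counts=sample_counts,
        )

    pos = rec.layout.positions[active]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(len(active), k=1)
    pair_d = dist[iu, ju]
    # group separations within tolerance
    order = np.argsort(pair_d)
    seps = [0.0]
    groups = {0.0: (np.arange(len(active)), np.arange(len(active)))}
    cur: list = []
    cur_ref = None
    for idx in order:
        d = pair_d[idx]
        if max_separation is not None and d > max_separation + separation_tolerance:
            break
        if cur_ref is None or d - cur_ref > separation_tolerance:
            if cur:
                seps.append(cur_ref)
                groups[cur_ref] = (iu[cur], ju[cur])
            cur = [idx]
            cur_ref = d
        else:
            cur.append(idx)
    if cur:
        seps.append(cur_ref)
        groups[cur_ref] = (iu[cur], ju[cur])

    values = np.zeros((len(seps), len(ells)))
    for j, ell in enumerate(ells):
        m = n - ell
        c = p[:, :m] @ p[:, ell:].T / m
        c = 0.5 * (c + c.T)  # symmetrize over ±τ
        for i, s in enumerate(seps):
            gi, gj = groups[s]
            values[i, j] = c[gi, gj].mean()
    pair_counts = np.array(
        [len(active) if s == 0.0 else len(groups[s][0]) for s in seps]
    )
    return CovarianceTable(
        separations=np.array(seps),
        lags=lag_ms,
        values=values,
        pair_counts=pair_counts,
        sample_counts=sample_counts,
    )


def estimate_periodic_artifact(
    cov: CovarianceTable,
    period: float = 145.0,
    long_lag_start: float = 1000.0,
) -> ArtifactProfiles:
    """Estimate the periodic common-mode artifact from S(0, τ).

    A centered moving average of width one period is subtracted from the
    ρ = 0 row; the residual at lags ≥ ``long_lag_start`` — where the
    subthreshold covariance itself is smooth — is folded over the period and
    averaged into a single zero-mean profile, which downstream removal
    extends periodically to all lags (including down to τ = 0).

    The table's lag grid must be uniform and extend at least two periods
    beyond ``long_lag_start``.
    """
    s0 = cov.row(0.0)
    lags = cov.lags
    dlag = np.diff(lags)
    if len(lags) < 3 or not np.allclose(dlag, dlag[0], atol=1e-9):
        raise ValueError("periodic-artifact estimation needs a uniform lag grid")
    step = dlag[0]
    w = int(round(period / step))
    if w < 3:
        raise ValueError("lag grid too coarse to resolve the period")
    if lags[-1] < long_lag_start + 2 * period:
        raise ValueError("lag grid must extend two periods beyond long_lag_start")
    kernel = np.ones(w) / w
    half = w // 2
    smooth = np.convolve(s0, kernel, mode="full")[half : half + len(s0)]
    resid = s0 - smooth
    valid = (lags >= max(long_lag_start, lags[0] + half * step)) & (
        lags <= lags[-1] - half * step
    )
    n_phase = w
    phase_idx = np.round(np.mod(lags[valid], period) / step).astype(int) % n_phase
    profile = np.bincount(phase_idx, weights=resid[valid], minlength=n_phase)
    counts = np.bincount(phase_idx, minlength=n_phase)
    profile = profile / np.maximum(counts, 1)
    profile -= profile.mean()
    return ArtifactProfiles(
        period=period,
        periodic_phase=np.arange(n_phase) * step,
        periodic_profile=profile,
    )


def estimate_short_lag_artifact(
    cov: CovarianceTable,
    support: float = 0.2,
    fit_range: tuple = (0.3, 3.0),
) -> ArtifactProfiles:
    """Estimate the measurement-error artifact on 0 ≤ τ ≤ ``support`` (ms).

    The smooth subthreshold component under the peak is extrapolated from
    lags just beyond the support by a linear fit in log τ (the known
    short-lag form of the field covariance); the profile is S(0, τ) minus
    that extrapolation, clipped to the support.  For the τ = 0 cell the
    extrapolation is evaluated at the smallest positive lag available.
    """
    s0 = cov.row(0.0)
    lags = cov.lags
    inside = (lags >= 0) & (lags <= support + 1e-12)
    if inside.sum() < 3:
        raise ValueError("lag grid does not resolve the artifact support (need >= 3 lags)")
    band = (lags >= fit_range[0]) & (lags <= fit_range[1])
    if band.sum() < 2:
        raise ValueError("no lags available in the extrapolation fit range")
    coef = np.polyfit(np.log(lags[band]), s0[band], 1)
    tau_floor = lags[(lags > 0)].min()
    smooth = np.polyval(coef, np.log(np.maximum(lags[inside], tau_floor)))
    profile = s0[inside] - smooth
    return ArtifactProfiles(
        short_lag_support=support,
        short_lag_lags=lags[inside],
        short_lag_profile=profile,
    )


def remove_artifacts(cov: CovarianceTable, profiles: ArtifactProfiles) -> CovarianceTable:
    """Subtract the artifact profiles from a covariance table.

    The periodic profile (extended periodically to all lags) is removed from
    every separation row; the short-lag profile from the ρ = 0 row only.
    """
    values = cov.values.copy()
    if profiles.periodic_profile is not None:
        values -= profiles.periodic_at(cov.lags)[None, :]
    if profiles.short_lag_profile is not None:
        i0 = cov._bin_index(0.0)
        for lag, v in zip(profiles.short_lag_lags, profiles.short_lag_profile):
            hits = np.nonzero(np.abs(cov.lags - lag) <= 1e-9)[0]
            if hits.size == 0:
                raise ValueError(
                    f"short-lag profile lag {lag} ms not present in the table's lag grid"
                )
            values[i0, hits[0]] -= v
    return replace(cov, values=values)


def decompose_slow_fast(
    cov: CovarianceTable, rho_large: float = 1.7, tol: float = 0.05
) -> CovarianceDecomposition:
    """Split S into slow and fast parts: slow := the row at ``rho_large``
    (the largest available separation, where activity-driven covariance is
    negligible), fast := every row minus slow.

    The default 1.7 mm matches the largest separation class of the standard
    0.2 mm grid (6·0.2·√2 ≈ 1.697 mm, hence the loose bin tolerance).
    """
    i = cov._bin_index(rho_large, tol=tol)
    slow = cov.values[i].copy()
    fast = replace(cov, values=cov.values - slow[None, :])
    return CovarianceDecomposition(slow=slow, fast=fast, rho_large=float(cov.separations[i]))
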