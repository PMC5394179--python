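"""Synthetic MEA recordings with the statistical structure the analysis assumes.

The generator composes, additively and in this order:

1. the relaxation–diffusion field driven by space-time white noise of
   intensity σ²(r, t), simulated spectrally on a periodic lattice with an
   exact per-Fourier-mode Ornstein–Uhlenbeck update (no finite-difference
   stability limit, no discretization bias in time);
2. the slowly varying, spatially uniform equilibrium potential μ(t),
   low-pass filtered by the field at rate γ;
3. stereotyped extracellular spikes (bursty negative or slowly rate-modulated
   positive populations);
4. a common-mode periodic artifact (145 ms period by default) and
   exponentially correlated per-electrode measurement noise;
5. 16-bit quantization (0.15 μV steps).

One root seed drives independent child streams per component, so a fixed
seed reproduces the recording bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .io import ElectrodeLayout, Recording, make_standard_layout
from .spikes import SpikeEvent
from .theory import FieldModelParams, REFERENCE_PARAMS

__all__ = [
    "FieldSimulationGrid",
    "EquilibriumProcessParams",
    "ArtifactParams",
    "SpikeTemplate",
    "SimulationConfig",
    "simulate_field",
    "simulate_equilibrium_potential",
    "inject_spikes",
    "inject_artifacts",
    "generate_recording",
    "paper_like_layout",
    "default_config",
    "stochastic_activity_field",
    "laplacian_eigenvalues",
    "mode_stationary_variance",
]


@dataclass(frozen=True)
class FieldSimulationGrid:
    """Periodic simulation lattice and time axis.

    The lattice approximates the infinite plane of the continuum model; it
    must extend well beyond the electrode array (checked at sampling time) so
    periodic images do not bias covariances.
    """

    lattice_shape: tuple = (128, 128)
    lattice_spacing: float = 0.05  # mm
    time_step: float = 1.0  # ms (1 kHz output; set 0.04 for 25 kHz)
    duration: float = 600_000.0  # ms
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive")
        if self.duration < self.time_step:
            raise ValueError("duration must be at least one time step")
        if self.boundary != "periodic":
            raise ValueError("only periodic boundaries are supported")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.time_step))

    @property
    def extent(self) -> tuple:
        return (
            self.lattice_shape[0] * self.lattice_spacing,
            self.lattice_shape[1] * self.lattice_spacing,
        )


@dataclass(frozen=True)
class EquilibriumProcessParams:
    """Gaussian model of the equilibrium potential μ(t).

    An Ornstein–Uhlenbeck process of the given variance (μV²) and timescale
    (ms); if ``oscillation_frequency`` (1/ms) is set, the covariance is
    modulated to ``variance · e^{−τ/timescale} · cos(2πfτ)``, emulating the
    damped 0–2 Hz oscillation seen in slow covariances.
    """

    variance: float = 6.0  # μV²
    timescale: float = 1000.0  # ms
    oscillation_frequency: Optional[float] = 0.001  # 1/ms (1 Hz)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.timescale <= 0:
            raise ValueError("timescale must be positive")

    def covariance(self, tau):
        """Sμ²(τ) implied by the parameters."""
        tau = np.asarray(tau, dtype=float)
        c = self.variance * np.exp(-np.abs(tau) / self.timescale)
        if self.oscillation_frequency:
            c = c * np.cos(2.0 * np.pi * self.oscillation_frequency * tau)
        return c


@dataclass(frozen=True)
class ArtifactParams:
    """Instrumental artifact model.

    ``periodic_amplitude`` is the common-mode signal amplitude in μV; the
    default √(2·0.12) ≈ 0.49 μV makes the artifact's covariance amplitude
    0.12 μV².  Measurement noise is exponentially correlated with the given
    marginal sd so its covariance support stays below ~0.2 ms.  Quantization
    rounds to the nearest ``quantization_step`` and is applied last.
    """

    periodic_period: float = 145.0  # ms
    periodic_amplitude: float = float(np.sqrt(2 * 0.12))  # μV
    periodic_overtones: int = 0
    noise_sd: float = 2.0  # μV
    noise_correlation_time: float = 0.05  # ms
    quantization_step: float = 10_000.0 / 2**16  # 0.15 μV

    def __post_init__(self) -> None:
        for name in (
            "periodic_period",
            "periodic_amplitude",
            "noise_sd",
            "noise_correlation_time",
            "quantization_step",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.periodic_overtones < 0:
            raise ValueError("periodic_overtones must be non-negative")


@dataclass(frozen=True)
class SpikeTemplate:
    """Stereotyped extracellular spike population for one region.

    ``rate`` is events per second per region.  ``burst_structure`` selects the
    temporal statistics: a positive ``burst_length`` gives short bursts of
    events (< 1 s), a positive ``modulation_timescale`` gives a slowly
    rate-modulated Poisson train; with neither, events are homogeneous
    Poisson.
    """

    polarity: str = "negative"  # or "positive"
    rate: float = 5.0  # events/s over the region
    amplitude_range: tuple = (30.0, 300.0)  # μV
    duration: float = 2.0  # ms of the waveform
    burst_structure: dict = dc_field(default_factory=dict)
    waveform: Optional[np.ndarray] = None  # unit-peak samples; built if None

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        lo, hi = self.amplitude_range
        if not (10.0 <= lo <= hi <= 500.0):
            raise ValueError("amplitude_range must lie within 10-500 μV")
        if self.duration > 4.0:
            raise ValueError("waveform duration must be <= 4 ms")

    def sampled_waveform(self, sampling_interval: float) -> np.ndarray:
        """Unit-peak waveform at the recording's sampling rate."""
        if self.waveform is not None:
            return np.asarray(self.waveform, dtype=float)
        half = self.duration / 2.0
        t = np.arange(-half, half + 1e-9, sampling_interval)
        s = self.duration / 6.0
        w = np.exp(-0.5 * (t / s) ** 2) - 0.35 * np.exp(-0.5 * ((t - 2.2 * s) / (1.6 * s)) ** 2)
        return w / np.max(np.abs(w))


@dataclass
class SimulationConfig:
    """Full recipe for a synthetic recording; fixed seed ⇒ identical output."""

    grid: FieldSimulationGrid = dc_field(default_factory=FieldSimulationGrid)
    model: FieldModelParams = REFERENCE_PARAMS
    layout: Optional[ElectrodeLayout] = None  # paper-like 58-active grid if None
    activity_field: Optional[object] = None  # None, (nx, ny) array, or callable t->array
    equilibrium: EquilibriumProcessParams = dc_field(default_factory=EquilibriumProcessParams)
    artifacts: ArtifactParams = dc_field(default_factory=ArtifactParams)
    spikes: Sequence = dc_field(default_factory=list)  # [(electrode_indices, SpikeTemplate)]
    seed: int = 0


def paper_like_layout() -> ElectrodeLayout:
    """The standard 60-electrode grid: 8×8 minus corners, one reference and
    one unused electrode, leaving 58 active at 0.2 mm spacing."""
    return make_standard_layout(
        8, 8, 0.2, reference_index=24, unused_indices=[0, 7, 56, 63, 62]
    )


def default_config(**overrides) -> SimulationConfig:
    """Paper-like simulation: reference field parameters, 0.2 mm electrode
    spacing, slow equilibrium process, both artifact classes, a stochastic
    activity field with the observed exponential correlation structure, and
    spiking populations in two regions (bursty negative / slowly modulated
    positive)."""
    layout = overrides.pop("layout", None) or paper_like_layout()
    active = layout.active_indices
    pos = layout.positions
    xmid = np.median(pos[active, 0])
    ymid = np.median(pos[active, 1])
    lower_right = [i for i in active if pos[i, 0] > xmid and pos[i, 1] <= ymid]
    upper_left = [i for i in active if pos[i, 0] <= xmid and pos[i, 1] > ymid]
    spikes = [
        (
            lower_right,
            SpikeTemplate(
                polarity="negative",
                rate=4.7,
                burst_structure={"burst_length": 500.0, "intra_burst_interval": 30.0},
            ),
        ),
        (
            upper_left,
            SpikeTemplate(
                polarity="positive",
                rate=4.6,
                burst_structure={"modulation_timescale": 100_000.0},
            ),
        ),
    ]
    cfg = SimulationConfig(layout=layout, spikes=overrides.pop("spikes", spikes))
    for k, v in overrides.items():
        setattr(cfg, k, v)
    if "activity_field" not in overrides:
        act_seed = np.random.SeedSequence([cfg.seed, 0x5EED]).spawn(1)[0]
        cfg.activity_field = stochastic_activity_field(cfg.grid, seed=act_seed)
    return cfg


def laplacian_eigenvalues(grid: FieldSimulationGrid) -> np.ndarray:
    """Eigenvalues k̂² of (minus) the 5-point discrete Laplacian on the
    rfft2 mode grid, shape (nx, ny//2 + 1), units mm⁻²."""
    nx, ny = grid.lattice_shape
    h2 = grid.lattice_spacing**2
    kx = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(nx) / nx)) / h2
    ky = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(ny // 2 + 1) / ny)) / h2
    return kx[:, None] + ky[None, :]


def mode_stationary_variance(grid: FieldSimulationGrid, model: FieldModelParams) -> np.ndarray:
    """Stationary variance E|p_k|² of each rfft2 coefficient of the field,
    σ²N/(2h²λ_k) with λ_k = γ + α·k̂²."""
    nx, ny = grid.lattice_shape
    lam = model.gamma + model.alpha * laplacian_eigenvalues(grid)
    n_sites = nx * ny
    return model.sigma2 * n_sites / (2.0 * grid.lattice_spacing**2 * lam)


def stochastic_activity_field(
    grid: FieldSimulationGrid,
    seed: int = 0,
    spatial_decay: float = 1.4,  # mm⁻¹, exponential spatial correlation decay
    temporal_rate: float = 1e-4,  # ms⁻¹ (0.1 s⁻¹), OU decay of the modulation
    log_sd: float = 0.6,  # sd of the log-multiplier
    epoch: float = 1000.0,  # ms between refreshes of the multiplier map
):
    """Space-time activity multiplier field with exponential correlations.

    A Gaussian field g(r, t) with Matérn-½ spatial covariance (∝ e^{−κ|Δr|},
    spectral amplitude ∝ (κ² + k²)^{−3/4}) and OU temporal covariance
    (∝ e^{−β|Δt|}) is exponentiated to a unit-mean log-normal multiplier
    exp(log_sd·g − log_sd²/2), emulating activity that fluctuates around its
    spatial/temporal average with the observed decay constants.  Returns
    ``(times, maps)`` accepted by the ``activity_field`` configuration slot.
    """
    nx, ny = grid.lattice_shape
    h = grid.lattice_spacing
    rng = np.random.default_rng(seed)
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=h)
    ky = 2.0 * np.pi * np.fft.rfftfreq(ny, d=h)
    k2 = kx[:, None] ** 2 + ky[None, :] ** 2
    amp = (spatial_decay**2 + k2) ** -0.75
    # normalize so the filtered field has unit site variance
    weights = np.full((nx, ny // 2 + 1), 2.0)
    weights[:, 0] = 1.0
    if ny % 2 == 0:
        weights[:, -1] = 1.0
    amp /= np.sqrt((weights * amp**2).sum() / (nx * ny))

    def draw():
        return np.fft.irfft2(np.fft.rfft2(rng.standard_normal((nx, ny))) * amp, s=(nx, ny))

    a = np.exp(-temporal_rate * epoch)
    times = np.arange(0.0, grid.duration, epoch)
    maps = np.empty((len(times), nx, ny))
    g = draw()
    for i in range(len(times)):
        if i:
            g = a * g + np.sqrt(1.0 - a * a) * draw()
        maps[i] = np.exp(log_sd * g - 0.5 * log_sd**2)
    return times, maps


def _activity_epochs(activity_field, grid: FieldSimulationGrid):
    """Normalize the activity specification to sqrt-multiplier maps.

    Accepts None (uniform), a static (nx, ny) array, a precomputed
    ``(times, maps)`` pair, or a callable t → map sampled every 100 ms (the
    method's stated temporal resolution floor).  Returns (times, sqrt_maps)
    where sqrt_maps[i] applies from times[i].
    """
    if activity_field is None:
        return None, None
    nx, ny = grid.lattice_shape
    if isinstance(activity_field, tuple):
        times, maps = activity_field
        times = np.asarray(times, dtype=float)
        maps = np.asarray(maps, dtype=float)
    elif callable(activity_field):
        step = max(grid.time_step, 100.0)
        times = np.arange(0.0, grid.duration, step)
        maps = np.stack([np.asarray(activity_field(t), dtype=float) for t in times])
    else:
        times = np.array([0.0])
        maps = np.asarray(activity_field, dtype=float)[None, :, :]
    if maps.shape[1:] != (nx, ny):
        raise ValueError(f"activity maps must have lattice shape {(nx, ny)}")
    if np.any(maps < 0):
        raise ValueError("activity multipliers must be non-negative")
    return times, np.sqrt(maps)


def simulate_field(
    grid: FieldSimulationGrid,
    model: FieldModelParams,
    equilibrium: Optional[EquilibriumProcessParams] = None,
    activity_field=None,
    seed: int = 0,
    sample_positions: Optional[np.ndarray] = None,
    frame_stride: Optional[int] = None,
):
    """Simulate the stochastic field on the periodic lattice.

    Each Fourier mode is an independent Ornstein–Uhlenbeck process with rate
    λ_k = γ + α·k̂² (k̂² the discrete-Laplacian eigenvalue); the update over a
    step is the exact OU transition, and the initial state is drawn from the
    exact stationary law, so the output is stationary from the first sample.
    The per-step driving noise is white in space with site variance
    σ²(r)·Δt/h², giving ⟨ξξ⟩ = σ² δ²(r) δ(t) in the continuum limit.

    Parameters
    ----------
    sample_positions : (n, 2) array, optional
        Positions (mm) at which to record traces; must lie on lattice nodes
        and within the central half of the lattice extent.
    frame_stride : int, optional
        If given, store every ``frame_stride``-th full lattice frame.

    Returns
    -------
    dict with ``times`` (ms), ``traces`` ((n_pos, n_steps), if positions
    given), ``frames`` ((n_frames, nx, ny), if requested), and ``mu_response``
    (the spatially uniform filtered-μ component, included in traces/frames).
    """
    nx, ny = grid.lattice_shape
    h = grid.lattice_spacing
    dt = grid.time_step
    n_steps = grid.n_steps
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_field, rng_mu = [np.random.default_rng(s) for s in ss.spawn(2)]

    idx = None
    if sample_positions is not None:
        sample_positions = np.asarray(sample_positions, dtype=float)
        extent = min(grid.extent)
        span = sample_positions.max(axis=0) - sample_positions.min(axis=0)
        if 2.0 * max(span) > extent:
            raise ValueError(
                f"lattice extent {extent:.2f} mm must be at least twice the "
                f"array extent {max(span):.2f} mm"
            )
        # center the array on the lattice
        offset = (
            np.array([nx, ny]) // 2
            - np.round((sample_positions.max(axis=0) + sample_positions.min(axis=0)) / (2 * h))
        ).astype(int)
        ij = np.round(sample_positions / h).astype(int)
        if not np.allclose(sample_positions / h, np.round(sample_positions / h), atol=1e-6):
            raise ValueError("sample positions must lie on lattice nodes")
        ij = (ij + offset) % np.array([nx, ny])
        idx = (ij[:, 0], ij[:, 1])

    lam = model.gamma + model.alpha * laplacian_eigenvalues(grid)
    decay = np.exp(-lam * dt)
    # innovation filter: real-space white noise of variance σ²Δt/h² per site,
    # shaped per mode so the stationary variance is exact at any Δt
    innov_gain = np.sqrt((1.0 - decay**2) / (2.0 * lam * dt))
    base_site_sd = np.sqrt(model.sigma2 * dt) / h

    act_times, act_sqrt = _activity_epochs(activity_field, grid)

    # stationary initial state via a spectrally shaped white field
    init = np.fft.rfft2(rng_field.standard_normal((nx, ny)))
    state = init * np.sqrt(mode_stationary_variance(grid, model) / (nx * ny))

    # spatially uniform filtered-μ component (k = 0 response)
    if equilibrium is not None and equilibrium.variance > 0:
        pre = int(np.ceil(10.0 / model.gamma / dt))
        mu = simulate_equilibrium_potential(
            equilibrium, (n_steps + pre) * dt, dt, rng=rng_mu
        )
        a_g = np.exp(-model.gamma * dt)
        q = lfilter([1.0 - a_g], [1.0, -a_g], mu)[pre:]
    else:
        q = np.zeros(n_steps)

    traces = np.empty((len(idx[0]), n_steps)) if idx is not None else None
    frames = [] if frame_stride else None
    epoch = 0
    block = 256
    states = np.empty((block,) + state.shape, dtype=complex)
    for start in range(0, n_steps, block):
        stop = min(start + block, n_steps)
        b = stop - start
        noise = rng_field.standard_normal((b, nx, ny)) * base_site_sd
        if act_sqrt is not None:
            for j in range(b):
                while epoch + 1 < len(act_times) and act_times[epoch + 1] <= (start + j) * dt:
                    epoch += 1
                noise[j] *= act_sqrt[epoch]
        innov = np.fft.rfft2(noise, axes=(1, 2))
        innov *= innov_gain
        for j in range(b):
            state = state * decay + innov[j]
            states[j] = state
        if traces is not None or frames is not None:
            fields = np.fft.irfft2(states[:b], s=(nx, ny), axes=(1, 2))
            if traces is not None:
                traces[:, start:stop] = fields[:, idx[0], idx[1]].T
            if frames is not None:
                for j in range(b):
                    if (start + j) % frame_stride == 0:
                        frames.append(fields[j] + q[start + j])
    if traces is not None:
        traces += q[None, :]
    out = {"times": np.arange(n_steps) * dt, "mu_response": q}
    if traces is not None:
        out["traces"] = traces
    if frames is not None:
        out["frames"] = np.array(frames)
    return out


def simulate_equilibrium_potential(
    params: EquilibriumProcessParams,
    duration: float,
    time_step: float,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate μ(t): a zero-mean Gaussian process with covariance
    ``variance·e^{−τ/timescale}`` (times ``cos(2πfτ)`` when an oscillation
    frequency is set, realized as an OU-modulated quadrature pair)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration / time_step))
    if params.variance == 0:
        return np.zeros(n)
    a = np.exp(-time_step / params.timescale)
    innov_sd = np.sqrt(params.variance * (1.0 - a * a))

    def ou() -> np.ndarray:
        x0 = rng.normal(0.0, np.sqrt(params.variance))
        w = rng.normal(0.0, innov_sd, size=n)
        w[0] = 0.0
        x = lfilter([1.0], [1.0, -a], w)
        x += x0 * a ** np.arange(n)
        return x

    if not params.oscillation_frequency:
        return ou()
    t = np.arange(n) * time_step
    omega = 2.0 * np.pi * params.oscillation_frequency
    return ou() * np.cos(omega * t) + ou() * np.sin(omega * t)


def inject_spikes(
    rec: Recording,
    templates: Sequence,
    seed: int = 0,
    overlap_limit: float = 0.1,
):
    """Add stereotyped spike events to electrode traces.

    ``templates`` is a list of ``(electrode_indices, SpikeTemplate)`` pairs;
    each event lands on one electrode of its region.  Returns a new Recording
    and the ground-truth event list (exact times and signed amplitudes).  If
    more than ``overlap_limit`` of a region's events overlap within a
    waveform duration on one electrode, a warning is recorded in the
    annotations.
    """
    out = rec.copy()
    truth: list = []
    rng = np.random.default_rng(seed)
    duration_s = rec.duration / 1000.0
    for region, tpl in templates:
        region = np.asarray(region, dtype=int)
        if region.size == 0:
            continue
        times_ms = _event_times(tpl, duration_s, rng) * 1000.0
        wave = tpl.sampled_waveform(rec.sampling_interval)
        half = len(wave) // 2
        sign = -1.0 if tpl.polarity == "negative" else 1.0
        lo, hi = tpl.amplitude_range
        electrodes = rng.choice(region, size=len(times_ms))
        amplitudes = sign * rng.uniform(lo, hi, size=len(times_ms))
        n_overlap = 0
        per_el_last: dict = {}
        for t_ms, el, amp in zip(times_ms, electrodes, amplitudes):
            s = int(round(t_ms / rec.sampling_interval))
            if not half <= s < rec.n_samples - half - 1:
                continue
            prev = per_el_last.get(el)
            if prev is not None and (t_ms - prev) < tpl.duration:
                n_overlap += 1
            per_el_last[el] = t_ms
            out.potentials[el, s - half : s - half + len(wave)] += amp * wave
            truth.append(
                SpikeEvent(
                    electrode=int(el),
                    time=s * rec.sampling_interval,
                    deviation=float(amp),
                    polarity=tpl.polarity,
                )
            )
        if truth and n_overlap > overlap_limit * max(len(times_ms), 1):
            out.annotations.setdefault("warnings", []).append(
                f"{n_overlap} overlapping spike events in region of size {region.size}"
            )
    truth.sort(key=lambda e: (e.time, e.electrode))
    return out, truth


def _event_times(tpl: SpikeTemplate, duration_s: float, rng) -> np.ndarray:
    """Event times (s) for one template over the registration."""
    bs = tpl.burst_structure or {}
    if bs.get("burst_length", 0) > 0:
        burst_len_s = bs["burst_length"] / 1000.0
        isi_s = bs.get("intra_burst_interval", 30.0) / 1000.0
        events_per_burst = burst_len_s / isi_s + 1.0
        burst_rate = tpl.rate / events_per_burst
        n_bursts = rng.poisson(burst_rate * duration_s)
        times = []
        for onset in rng.uniform(0.0, duration_s, size=n_bursts):
            t = onset
            while t < onset + burst_len_s:
                times.append(t)
                t += rng.exponential(isi_s)
        return np.sort(np.array(times))
    if bs.get("modulation_timescale", 0) > 0:
        period_s = bs["modulation_timescale"] / 1000.0
        peak = 2.0 * tpl.rate  # rate(t) = rate·(1 + sin), thinned from peak
        n = rng.poisson(peak * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, size=n))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        accept = rng.uniform(size=n) < 0.5 * (
            1.0 + np.sin(2.0 * np.pi * cand / period_s + phase)
        )
        return cand[accept]
    n = rng.poisson(tpl.rate * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def inject_artifacts(rec: Recording, params: ArtifactParams, seed: int = 0) -> Recording:
    """Add the two instrumental artifact classes and quantize.

    (i) a common-mode periodic signal (same on every electrode) whose
    covariance amplitude is ``periodic_amplitude²/2``; (ii) independent
    exponentially correlated measurement noise per electrode; (iii)
    round-to-nearest quantization, applied last.
    """
    out = rec.copy()
    rng = np.random.default_rng(seed)
    t = out.times
    if params.periodic_amplitude > 0 and params.periodic_period > 0:
        n_harm = params.periodic_overtones + 1
        rel = 1.0 / np.arange(1, n_harm + 1)  # falling overtone content
        scale = params.periodic_amplitude / np.sqrt(np.sum(rel**2))
        common = np.zeros_like(t)
        for hharm, r in enumerate(rel, start=1):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            common += scale * r * np.cos(2.0 * np.pi * hharm * t / params.periodic_period + phase)
        out.potentials += common[None, :]
    if params.noise_sd > 0:
        a = (
            np.exp(-rec.sampling_interval / params.noise_correlation_time)
            if params.noise_correlation_time > 0
            else 0.0
        )
        w = rng.normal(
            0.0, params.noise_sd * np.sqrt(1.0 - a * a), size=out.potentials.shape
        )
        out.potentials += lfilter([1.0], [1.0, -a], w, axis=1)
    if params.quantization_step > 0:
        np.round(out.potentials / params.quantization_step, out=out.potentials)
        out.potentials *= params.quantization_step
    return out


def generate_recording(config: SimulationConfig):
    """Simulate a full synthetic recording.

    Returns ``(Recording, truth)`` where ``truth`` bundles everything the
    analysis is later asked to recover: the field parameters, activity
    specification, equilibrium parameters, exact spike list and artifact
    parameters.
    """
    layout = config.layout or paper_like_layout()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    field = simulate_field(
        config.grid,
        config.model,
        equilibrium=config.equilibrium,
        activity_field=config.activity_field,
        seed=seeds[0],
        sample_positions=layout.positions,
    )
    rec = Recording(
        potentials=field["traces"],
        sampling_interval=config.grid.time_step,
        layout=layout,
        annotations={"seed": config.seed, "synthetic": True},
    )
    rec, spike_truth = inject_spikes(rec, config.spikes, seed=seeds[1])
    rec = inject_artifacts(rec, config.artifacts, seed=seeds[2])
    truth = {
        "model": config.model,
        "activity_field": config.activity_field,
        "equilibrium": config.equilibrium,
        "artifacts": config.artifacts,
        "spikes": spike_truth,
        "seed": config.seed,
    }
    return rec, truth
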