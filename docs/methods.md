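# Methods

## The model

The subthreshold (local-field) potential p(**r**, t) recorded by a planar
multi-electrode array is modelled as a Gaussian, Markovian stochastic field
in two spatial dimensions:

    ∂p/∂t = −γ (p − μ(t)) + α ∇²p + ξ(**r**, t),

with

* γ (ms⁻¹) — the relaxation constant, the rate at which the potential
  returns toward the equilibrium potential;
* α (mm²·ms⁻¹) — the diffusion constant, the rate at which spatial
  inhomogeneities smooth out;
* ξ — driving noise, white in space and time with intensity σ²
  (μV²·mm²·ms⁻¹), ⟨ξξ'⟩ = σ² δ²(**r**−**r**′) δ(t−t′), interpreted as the
  local neural activity;
* μ(t) — a slowly varying, spatially uniform equilibrium potential with
  covariance Sμ²(τ), uncorrelated with ξ.

Units are fixed package-wide to mm / ms / μV; all I/O converts at the
boundary.

Under stationarity, homogeneity and isotropy the two-point function
S(ρ, τ) = ⟨p(**r**₁, t) p(**r**₂, t+τ)⟩ splits into a slow part (filtered
μ) and a fast, activity-driven part

    S_fast(ρ, τ) = (σ²/8πα) ∫_τ^∞ exp(−γu − ρ²/4αu) / u du,

whose slices are closed forms: S_fast(0, τ) = (σ²/8πα)·Γ(0, γτ) and
S_fast(ρ, 0) = (σ²/4πα)·K0(√(γ/α)·ρ).  Both diverge logarithmically at the
origin — the generic short-scale signature of field theories in two spatial
dimensions, and the empirical fingerprint the analysis looks for.  Derived
characteristic scales are 1/γ (time), √(α/γ) (length) and √(σ²/α)
(voltage); at the package's reference parameters (α ≈ 0.0025 mm² ms⁻¹,
γ ≈ 0.0030 ms⁻¹, σ² ≈ 0.035 μV² mm² ms⁻¹, obtained from a hippocampal-slice
recording) they are ≈ 330 ms, 0.91 mm and 3.7 μV.

## Numerical evaluation of the covariance

`s_fast_theory` evaluates the integral in the log variable u = e^w with a
fixed 400-point Gauss–Legendre rule and upper cutoff u = τ + 30/γ (+ a
Gaussian-tail allowance in ρ); the integrand is analytic and O(1) there, and
the rule agrees with adaptive quadrature and with the Γ(0,·)/K0 closed forms
to better than 1e-8 relative across the tested domain (γτ ∈ [1e-6, 10],
√(γ/α)ρ ∈ [1e-3, 10]).  Γ(0,·) and K0 come from scipy.special (`exp1`,
`k0`) and are cross-checked in the tests against an independent power
series and the integral representation ∫ e^{−x cosh t} dt.

## Fitting

`SubthresholdFieldModel` fits (α, γ, σ²) to the empirical fast covariance by
unweighted least squares over ρ ≤ 1.0 mm and τ ∈ [0.3, 80] ms — below the
slow regime, above the measurement-noise artifact support.  Positivity is
enforced by optimizing log-parameters (Levenberg–Marquardt); the initial
guess inverts the closed-form logarithmic slopes.

The empirical fast covariance is defined as S(ρ, τ) − S(ρ_large, τ) with
ρ_large = 1.7 mm (the largest separation class of the 0.2 mm grid).  The
theoretical fast covariance at 1.7 mm (~0.1 μV²) is small but not negligible
against long-lag values, so the default forward model predicts exactly the
measured difference, S_fast(ρ, τ) − S_fast(ρ_large, τ).  On noiseless
tables the raw-theory model biases γ upward by ~50%; the subtraction-aware
model recovers all three parameters exactly, which is why it is the
default (`model_rho_large_subtraction=False` restores the raw behaviour).
No parameter uncertainties are quoted; the covariance cells entering the
loss are strongly correlated and a bootstrap is left out of scope.

## Preprocessing

*Spike removal.*  Spikes (10–500 μV action-potential signatures) are
detected per electrode from the deviation d(**r**, t) of the potential from
its trailing 10 ms mean: an event requires |d| ≥ 20 μV and |d| maximal in a
±2 ms window (plateau ties resolved to the earliest sample; no two events
closer than 2 ms — the refractory window and the peak window are treated as
the same 2 ms parameter).  Detection is disabled over the first 10 ms of a
recording (no trailing history).  Events are excised by linear
interpolation between p(t ± 2 ms); endpoint samples are untouched,
overlapping intervals are merged, and edge events use the nearest available
endpoints.

*Artifact subtraction* operates on the covariance table, not the traces.
The periodic common-mode component (period 145 ms) is the residual of
S(0, τ) after subtracting a one-period centered moving average, folded over
the period for lags ≥ 1 s (where the subthreshold covariance itself is
smooth) and extended periodically to all lags and separations.  The
measurement-error component (support ≲ 0.2 ms, amplitude ~4 μV² for 2 μV
errors) is S(0, τ) minus a smooth component extrapolated into the support by
a linear fit in log τ over τ ∈ [0.3, 3] ms — the known short-lag form; at
τ = 0, where the log diverges, the extrapolation is evaluated at the
smallest positive lag.  It is subtracted from the ρ = 0 row only, and only
when the sampling rate resolves the support (at 1 kHz it cannot, and the
4 μV² legitimately remains in the single (0, 0) cell, which the fit domain
excludes anyway).

*Slow/fast split.*  S_slow(τ) := S(ρ_large, τ); the slow oscillation itself
(damped, 0–2 Hz) is described but not modelled further.

## Activity mapping and connectivity

With α fixed by the global fit, the local activity obeys
⟨p(t)p(t+δt)⟩ = σ²(**r**, t)/(8πα)·(−log(γδt) + O(1)) at short lags, so
σ²(**r**, t) is 8πα × the slope of windowed lagged products against
−log δt.  Slope-plus-intercept regression absorbs the constant inside the
log, the O(1) term and any within-window-constant covariance (equilibrium
potential, periodic artifact).  Defaults: 8 log-uniform lags in 0.2–10 ms
snapped to the sample grid, 1000 ms windows with 50% overlap (100 ms is the
hard floor — expectations must be replaced by window averages), per-window
mean removal.  Negative slopes, possible in quiet windows, are clipped to
zero and counted as a QC statistic.

Connectivity is purely descriptive: exponential-decay fits (log-linear
least squares over Δt ∈ [2, 20] s and |Δr| ∈ [0.4, 1.2] mm, ranges chosen
to dodge estimation-noise contamination at the origin and shrunk
automatically if the autocorrelation goes non-positive) give β (s⁻¹) and κ
(mm⁻¹); Pearson correlations between electrode pairs at exactly one grid
spacing (0.2 mm, no diagonals) populate a graph whose edge weight is r⁴
(negative r keeps its sign in the stored coefficient).  Correlation is
symmetric, so no direction of information flow is inferred.

## The synthetic-data generator

Since no public recording accompanies the reference parameters, a
first-class generator produces recordings with the exact statistical
structure the analysis assumes:

* **Field** — simulated spectrally on a periodic lattice.  Each Fourier
  mode is an exact Ornstein–Uhlenbeck process with rate γ + α·k̂² (k̂² the
  5-point discrete-Laplacian eigenvalue); the update over a step uses the
  exact OU transition and the initial state is drawn from the exact
  stationary law, so there is no time-discretization bias, no stability
  limit, and no burn-in transient.  Per-step site noise has variance
  σ²(r)Δt/h², shaped per mode so the stationary spectrum is exact at any Δt.
* **Equilibrium potential** — an OU process (default variance 6 μV²,
  timescale 1 s), optionally modulated to a damped 1 Hz oscillation; the
  field low-pass filters it at rate γ (10/γ pre-roll).
* **Spikes** — stereotyped biphasic events on single electrodes: a bursty
  negative population (bursts < 1 s) and a positive population whose rate is
  modulated on ~100 s timescales; amplitudes uniform in 30–300 μV; exact
  ground-truth event lists are returned.
* **Artifacts** — a common-mode cosine of period 145 ms scaled so its
  covariance amplitude is 0.12 μV² (overtones are a config knob, default
  none — their harmonic content is not constrained by anything we model);
  per-electrode exponentially correlated measurement noise (2 μV, 0.05 ms
  correlation time, so the covariance support stays within 0.2 ms); 16-bit
  quantization at 0.15 μV, applied last.
* **Activity field** — optionally σ²(**r**, t) varies as a unit-mean
  log-normal field with Matérn-½ spatial covariance (decay 1.4 mm⁻¹) and OU
  temporal covariance (decay 0.1 s⁻¹), refreshed every 1 s — the correlation
  structure the connectivity analysis reports on real tissue.  This is the
  default for `default_config`; recovery tests use a uniform field so
  "truth" is a single number.

One root seed spawns independent child streams per component; a fixed seed
reproduces a recording bit-for-bit.

What the generator does **not** emulate: biophysical spike shapes and
propagation, volume conduction into the bath (a 3-D effect the 2-D model
deliberately excludes), electrode impedance variation, line noise, drift of
the preparation.  Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to every
failure mode of real recordings.

## Problem sizes and desk-scale defaults

The reference recording was 58 electrodes × 600 s × 25 kHz.  The package's
test and validation runs use 1 kHz output sampling (the model's informative
band for fitting is ≲ 100 ms, and the exact per-mode update is unbiased at
any step), 100–600 s registrations, and lattices of 64–128² sites at
0.05 mm.  Two sizes matter:

* the lattice must dwarf the 0.91 mm correlation length, or periodic images
  inflate large-separation covariances — at 64² (3.2 mm) the 1.7 mm row
  reads 0.34 instead of 0.15 μV² and the fitted γ degrades, at 96² (4.8 mm)
  the discrepancy is < 0.02 μV²; end-to-end recovery therefore runs on 96²
  lattices (the general default is 128²);
* the periodic-artifact amplitude (0.12 μV²) is only resolvable by folding
  many periods of lags ≥ 1 s, so its recovery check keeps the full 600 s
  registration; the 0.2 ms measurement-noise support requires 25 kHz
  sampling, so its recovery check runs a short high-rate simulation.

## Known limitations

* γ is the weakest-identified parameter (it only enters through the gentle
  curvature of the log law below γτ ≈ 0.25); single-run estimates scatter
  by tens of percent at 100 s and benefit from longer registrations.
* The activity estimator's temporal resolution is bounded by the ≥ 100 ms
  window; no deconvolution of window smoothing is attempted.
* S_slow is described, not modelled; the inversion recovering Sμ² from
  S_slow (a second-derivative operation) is deliberately out of scope.
* Activity decay constants β and κ estimated from full simulations are
  biased by estimation noise in the activity maps themselves; the
  quantitative recovery guarantees are stated for activity with known
  injected correlation structure.
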