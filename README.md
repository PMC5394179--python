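# meafield

Statistical field theory analysis of subthreshold multi-electrode-array
(MEA) potentials.

MEA recordings of brain tissue mix three things: action-potential spikes,
instrumental artifacts, and the much smaller subthreshold fluctuations of
the local field potential (LFP).  `meafield` characterizes those
subthreshold fluctuations compactly by modelling the potential p(**r**, t)
on the electrode plane as a Gaussian relaxation–diffusion field,

    ∂p/∂t = −γ (p − μ(t)) + α ∇²p + ξ(r, t),    ⟨ξξ′⟩ = σ² δ²(Δr) δ(Δt),

where γ is a relaxation rate, α a diffusion constant, μ(t) a slowly varying
equilibrium potential, and the white-noise intensity σ² is read as the
local neural activity.  The stationary covariance of the activity-driven
part has closed-form slices

    S_fast(0, τ) = (σ²/8πα) Γ(0, γτ),    S_fast(ρ, 0) = (σ²/4πα) K0(√(γ/α) ρ),

both logarithmically divergent at short scales — the tell-tale signature of
a field theory in two spatial dimensions, and the feature the fit exploits.
The package is aimed at electrophysiologists and computational
neuroscientists who want a small number of robust, physically interpretable
parameters (α, γ, σ², and the derived time/length/voltage scales) from
slice or culture MEA data, plus maps and correlation statistics of the
activity σ²(**r**, t).

It provides, as library modules behind a `statsmodels`-style model/results
surface and a thin `meafield` CLI:

* `simulate` — a synthetic-recording generator with the exact statistical
  structure the analysis assumes (spectral, bias-free field simulation;
  equilibrium process; bursty/modulated spike populations; periodic and
  measurement-noise artifacts; 16-bit quantization), with full ground truth;
* `spikes` — trailing-mean threshold detection and linear-interpolation
  removal;
* `covariance` — spatio-temporal covariance estimation S(ρ, τ) with
  artifact-profile subtraction and the slow/fast decomposition;
* `model` — `SubthresholdFieldModel(...).fit()` →
  `SubthresholdFieldResults` with parameters, derived scales, diagnostics
  and `summary()`;
* `activity` — windowed σ²(**r**, t) maps from the short-lag log law;
* `connectivity` — exponential decay constants (β, κ) of the activity's
  autocovariances and the adjacent-pair Pearson graph (edge weight r⁴);
* `pipeline` — one-config orchestration with a results manifest.

## Worked example

Simulate a 100 s paper-like recording (58 active electrodes on a 0.2 mm
grid, 1 kHz output; truth α = 0.0025, γ = 0.0030, σ² = 0.035 with spikes
and artifacts on), then despike, clean, and fit it:

```python
from meafield import simulate as sim
from meafield.model import SubthresholdFieldModel

grid = sim.FieldSimulationGrid(lattice_shape=(96, 96), time_step=1.0,
                               duration=100_000.0)
cfg = sim.default_config(grid=grid, seed=300, activity_field=None)
rec, truth = sim.generate_recording(cfg)

model = SubthresholdFieldModel.from_recording(rec)
results = model.fit()
print(f"spikes removed: {model.preprocessing['n_spikes_removed']}")
print(results.summary())
```

```
spikes removed: 1064
Subthreshold field model fit
==============================================
alpha (diffusion)               0.0025122 mm^2/ms
gamma (relaxation)              0.0027808 1/ms
sigma^2 (activity)               0.035033 uV^2 mm^2/ms
----------------------------------------------
time scale 1/gamma                  359.6 ms
length scale sqrt(a/g)             0.9505 mm
voltage scale sqrt(s2/a)            3.734 uV
----------------------------------------------
fit cells                             378
residual SS                      0.058122 uV^4
R^2                               0.99893
converged                            True
```

The fitted parameters sit within a few percent of the generating truth; the
derived scales say the field forgets its past over ~0.36 s, correlates over
~0.95 mm (several electrode spacings, so the 0.2 mm grid oversamples it
comfortably), and fluctuates by ~3.7 μV.  `results.residuals` holds the
per-cell (ρ, τ) diagnostics behind the R².

The same chain from the shell, writing every stage product plus
`manifest.json`:

```bash
meafield run-all --config pipeline.yaml --seed 300 --out run/
```

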