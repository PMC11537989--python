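# flyhue

Tools for analyzing hue selectivity in the *Drosophila* chromatic circuit: a
tetrachromatic color space built from opsin photon captures, response
extraction from calcium-imaging traces, tuning indices, three encoding
models of chromatic responses, a connectome-constrained recurrent circuit
model with perturbation experiments, and a synthetic-data generator that
exercises the whole pipeline end to end.

Intended users are visual neuroscientists who record chromatic neuron
responses (photoreceptor axons, medulla interneurons, transmedullary
projection neurons) to full-field colored stimuli and want to quantify and
model how hue-selective those responses are.

## The models

**Color space.** A stimulus is a vector of photon captures `q` of the four
chromatic opsins Rh3–Rh6, relative to the adapting background. Log captures
`X_mu = ln((q_mu + 0.001)/1.001)` decompose into a chromatic 3-vector `x`
inside a regular tetrahedron plus a luminance scalar `l` along the
equal-capture ("white") axis; saturation is `s = |x|` and hue is the
direction of `x`.

**Encoding models.** For a neuron with preferred direction `p̂`:

- linear: `y_i = a_L p̂·x_i + b l_i`
- LNL: the linear drive through an asymmetric saturating tanh
- nonlinear selectivity:
  `y_i = (a_NL s_i^α / κ) (exp(κ cos θ_i) − 1) + b l_i`,
  a von Mises dependence on hue with sharpness `κ` and saturation exponent
  `α`; `κ → 0, α = 1` is the linear model. Fits are weighted by per-stimulus
  observation counts and scored with a noise-corrected R².

**Circuit model.** Twelve rate units (R7/R8 photoreceptor axons, Dm9,
pDm8/yDm8, Tm5a/Tm5b/Tm5c and the two Tm20 subtypes) interact through
signed, row-normalized synaptic-count weights:

    τ_a dy_a/dt = −y_a + f( g_a ( Σ_b w_ab y_b + Σ_μ j_aμ X_μ + p_a x_0 ) )

Responses are fixed points (Anderson acceleration with exact-Jacobian
safeguards); parameters are fitted in three stages by Adam on a negative
correlation loss with implicit differentiation through the fixed point.
Perturbation experiments — blocking single neurons' outputs (TeNT), ablating
Tm–Tm recurrence, random-weight nulls — probe which circuit features create
hue selectivity. See `docs/methods.md` for the full account.

## Worked example

Simulate a gamut experiment from the packaged (synthetic) example circuit and
quantify tuning:

```python
import numpy as np
from flyhue import circuit, metrics, tuning_models
from flyhue.stimgen import (LEDSystem, sample_gamut,
                            session_observation_counts, simulate_responses)

led = LEDSystem()
stimuli = sample_gamut(200, seed=7, led_system=led)     # isoluminant, Σq = 5
m = session_observation_counts(stimuli, seed=8)         # per-stimulus repeats
spec = circuit.example_spec()                           # synthetic 12-neuron circuit
responses = simulate_responses(stimuli, spec, noise_sd=0.05, m=m, seed=9,
                               unit_names=list(circuit.NEURONS))
v = responses.pivot(index="stimulus_id", columns="roi_id",
                    values="amplitude")[list(circuit.NEURONS)].to_numpy()

for name in ("yR7", "Tm5a", "Tm5c"):
    k = circuit.IDX[name]
    sp = metrics.sparsity_index(v[:, k])
    hsi = metrics.hue_sensitivity_index(v[:, k], stimuli.opponent, m=m).hsi
    fit = tuning_models.fit_selectivity(stimuli.chroma, stimuli.luminance,
                                        v[:, k], m=m.astype(float),
                                        sigma2=0.05**2)
    print(f"{name}: sparsity={sp:.2f}  HSI={hsi:.2f}  kappa={fit.kappa:.2f}  "
          f"alpha={fit.alpha:.2f}  R2={fit.r2:.2f}")
```

Output:

```
yR7: sparsity=0.53  HSI=0.70  kappa=0.06  alpha=0.32  R2=0.95
Tm5a: sparsity=0.53  HSI=0.65  kappa=0.78  alpha=0.22  R2=0.79
Tm5c: sparsity=0.33  HSI=0.65  kappa=0.01  alpha=0.68  R2=0.87
```

The photoreceptor analog (yR7) and the broadly tuned Tm5c fit best at the
smallest hue-sharpness values on the grid (`kappa` 0.06 and 0.01 — near the
linear limit), while the hue-selective Tm5a analog needs `kappa` ≈ 0.8: its
responses rise much more steeply around the preferred hue direction than a
linear model allows. Zeroing the Tm–Tm recurrent weights
(`circuit.ablate_recurrence`) or the neuron's own outputs
(`circuit.simulate_tent`) and re-simulating lowers the fitted `kappa` — in
this model, recurrence creates the extra hue sharpening.

A full pipeline run (stimuli → responses → indices → model fits → circuit
fit → report) is available as `flyhue run --seed 1 --out results/`, with
`simulate`, `fit-tuning`, `fit-circuit`, `perturb`, `ablate-recurrence` and
`null` subcommands for the individual stages.

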