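# Methods

`flyhue` models chromatic processing in the *Drosophila* optic lobe: how the
photon captures of four chromatic opsins (Rh3, Rh4, Rh5, Rh6) are turned into
hue-selective responses in the transmedullary neurons Tm5a, Tm5b, Tm5c and
Tm20. This note records the models, the conventions and the numerical
choices, in the order the pipeline runs.

## Color space

A stimulus spectrum is reduced to photon captures per opsin, expressed
relative to the adapting background (background = 1). Captures are computed
by trapezoid quadrature of the spectrum against peak-normalized pigment
templates (the Govardovskii A1 nomogram, alpha plus beta band); the template
peaks are configuration, with literature-ballpark defaults (Rh1 478, Rh3 331,
Rh4 355, Rh5 442, Rh6 515 nm) that the synthetic-data stage and the tests use
as fixtures — analyses of real measurements should supply their own.

Log relative captures `X_mu = ln((q_mu + 0.001)/1.001)` (natural log
throughout) are split into a luminance component `l = X·u` along the unit
white axis `u = (1,1,1,1)/2` and a chromatic 3-vector `x = B(X − l·u)`. The
basis `B` is fixed:

    B = 1/2 [ [ 1,  1, -1, -1],
              [ 1, -1,  1, -1],
              [ 1, -1, -1,  1] ]

Its rows are orthonormal and orthogonal to `u`, and the four opsin axes map
to the vertices of a regular tetrahedron; a test freezes the matrix.
Saturation is `s = |x|`, hue the direction of `x`; `cos(theta)` denotes the
cosine between `x` and a neuron's preferred direction. The 2D opponent
projection used for plotting and for the hue sensitivity index is
`((Rh5+Rh6)−(Rh3+Rh4), (Rh4+Rh5)−(Rh3+Rh6))`, computed on `X` by default
(it can be applied to `q` instead; both are exposed because either reading
is defensible and they differ only by the log transform's curvature).

## Stimulus design and synthetic data

The gamut set draws capture 4-vectors uniformly (symmetric Dirichlet) on the
isoluminant simplex `sum q = 5`, optionally restricted to the targets a
six-LED system can realize. The synthetic LED system uses Gaussian spectra
(sd 12 nm) at the nominal peaks 340/360/415/455/565/615 nm, maximum
intensities 6/7/11/18/25/160 uE, and background drives
0.01/0.06/0.10/0.25/0.33/0.25 uE. Only the resulting captures matter
downstream, so the spectral shapes are free parameters. Captures are linear
in the drives, so LED solving is bounded linear least squares; because six
LEDs against four opsins are underdetermined, ties are broken toward the
background mixture scaled by the target's mean capture, which makes the
solve deterministic and reproduces proportional intensity scalings exactly.
Realized stimuli also carry the broadband Rh1 capture of the mixture; its
log, `x0`, is the achromatic R1–6 drive of the circuit model.

The contrast set flashes each LED and eleven fixed mixtures at added
intensities 0.1–3 uE per LED on top of the background.

Per-session observation counts emulate the real design: each simulated
session covers ~20% of the stimuli (greedy farthest-point subsampling, so
sessions span color space) with three repeats; counts accumulate over
sessions (default 15), so `m_i` varies across stimuli.

Synthetic response amplitudes are the ground-truth model means plus Gaussian
noise of sd `sigma/sqrt(m_i)`; `sigma^2` is recorded as the single-trial
noise power used by the noise-corrected R². Synthetic fluorescence traces
hold a plateau for the 0.5 s stimulus plus 0.3 s, then decay exponentially
(tau 0.2 s) — a caricature of indicator offset kinetics whose specific
purpose is that the extraction's smoothing stage sees no hard falling edge
inside the measurement window. The generator does not model indicator
nonlinearity, adaptation, or movement artifacts; passing round-trip tests
therefore validates the extraction arithmetic, not robustness to those
effects.

## Signal extraction

dF/F uses a rolling 25th-percentile baseline (40 s window) and
Savitzky-Golay smoothing (0.5 s, third order). The response amplitude is the
mean dF/F over [onset+0.35 s, onset+0.5 s] minus the mean over
[onset−0.35 s, onset−0.1 s]; window membership uses closed intervals
(boundary samples included), fixed for determinism. ROIs are kept when
`SNR = |v_stim|^2 / |v_baseline|^2 >= 2`, with baseline amplitudes from 100
randomly placed 0.15 s windows outside the stimulation period (count and
placement are a package choice; a fixed seed makes the filter reproducible).
`sigma^2` is the mean squared baseline amplitude. Response vectors are
normalized so that `sum v'^2 = N − 1`.

## Tuning indices

* sparsity: `1 − mean(|v_i| / max_j |v_j|)`; 0.5 for uniformly distributed
  amplitudes, 1 − 1/N for a single responder.
* luminance invariance: R²(chromatic-only linear fit) / R²(luminance-only
  fit), both intercept-free weighted least squares with uncentered R²; a
  luminance R² below 1e-6 caps the ratio and flags it.
* hue sensitivity index: opponent-plane saturations are scaled to [0,1] by
  the set maximum; stimuli at or above 0.5 scaled saturation (and the white
  point itself, whose direction is undefined) are dropped; the index is the
  norm of `sum m_i p_hat_i y_i / sum m_i |y_i|`.

Goodness of fit is a noise-corrected R² that removes the bias trial noise
introduces into the weighted uncentered correlation. The printed form of the
numerator's first term is ambiguous; the default reading `(sum m y v)^2` is
the only one that reduces to a squared correlation at `sigma^2 = 0`, and the
literal reading `sum m (y v)^2` is kept behind `reading="literal"`.
Confidence intervals bootstrap ROIs with replacement (1,000 draws,
percentile CI).

## Encoding models

* linear: `y = a_L (p_hat·x) + b l`.
* LNL: the linear drive through an asymmetric saturating tanh
  (`a_NL`, asymmetry `gamma`); fitted by nonlinear least squares initialized
  at the linear solution with `gamma = 0`, with a small number of jittered
  restarts.
* nonlinear selectivity: `y = (a_NL s^alpha / kappa)(exp(kappa cos theta) − 1)
  + b l`; `kappa -> 0, alpha = 1` recovers the linear model (the analytic
  `kappa = 0` limit is a separate evaluation path used by tests).

The selectivity fit searches a fixed grid — kappa: 20 log-spaced values in
[1e-2, 1e1]; alpha: 13 in [1e-1, 1e1] — refitting `p_hat`, `a_NL` and `b`
per grid point. Implementation: for a candidate direction the two linear
coefficients are profiled out in closed form at every grid point at once;
the direction is then refined by Nelder-Mead at the six most promising grid
points and the grid is re-swept at each refined direction. Ties break toward
smaller kappa. The preferred direction is parameterized as an unconstrained
3-vector normalized inside the objective, avoiding angular degeneracies.

## Circuit model

Twelve rate units (pR7, yR7, pR8, yR8, Dm9, pDm8, yDm8, Tm5a, Tm5b, Tm5c,
pTm20, yTm20) follow

    tau_a dy_a/dt = −y_a + f( g_a ( sum_b w_ab y_b + sum_mu j_amu X_mu
                                    + p_a x0 ) )

with `f` the asymmetric tanh (unit output gain, per-neuron `gamma`, Dm9
fixed at 0). Weights onto each neuron are signed synaptic-count proportions:
`sum_b |w_ab| + sum_mu j_amu = 1`. Tm–Tm weights sum direct and disynaptic
counts before normalization. Time constants are irrelevant at steady state;
they are kept (default 0.05 s) for the ODE-integration cross-checks.

Responses are fixed points solved by Anderson acceleration (memory 5,
damping 1, zero initial iterate, tolerance 1e-4 by default and tighter
in fitting). Strong recurrent inhibition can make the fixed point repel the
plain Picard map (period-two cycling) even though the underlying ODE is
stable; when the accelerated iteration stalls, the solver switches to a
heavily damped sweep and, for any stimuli still unresolved, a per-stimulus
Newton/Powell root solve with the exact 12x12 Jacobian (deterministic
fallback starts). The solve remains deterministic.

Fitting minimizes the summed negative m-weighted uncentered correlation per
neuron (scale-free, since calcium amplitudes are relative), in three stages:
photoreceptors+Dm9 (shared photoreceptor gain, Dm9 gain, shared opsin input
`j`, photoreceptor gammas), then Dm8s (positive R1–6 weights, two negative
Dm8<->Dm8 proportions, shared gain, gammas), then Tms (per-neuron R1–6
weight with free sign, gain, gamma). That is 8 gains + 11 gammas + 1 opsin
input + 7 achromatic weights + 2 Dm8 weights = 29 free parameters. Each
stage runs mini-batch Adam (batch 64, up to 100 epochs, learning rate 0.001,
early stop when the full-data loss stalls) with gradients obtained by
implicit differentiation at the fixed point — the adjoint solves
`(I − J)^T lambda = dL/dy` — never by unrolling solver iterations. Because
the loss can be rugged near bistability boundaries, each stage may retry
from a few jittered starts (default two extra) and keep the best full-data
loss. Bounded parameters use smooth transforms (exp for gains and the
positive Dm8 achromatic weights, tanh for gammas, sigmoid for the convex
weight proportions), so the row-normalization constraint holds exactly for
every parameter value: photoreceptor rows are `(1−j)` times the normalized
counts with `j` the shared opsin input; Dm8 rows mix the fixed R7 counts
with the free recurrent proportion.

Free-sign recurrent edges are resolved by exhaustive enumeration when `2^k`
fits the budget, otherwise seeded random search; each candidate re-runs the
Tm stage. Perturbations: TeNT zeroes a Tm neuron's outgoing weights (a
companion refit frees only that neuron's gain and gamma, mirroring the
two-parameter refit of the TeNT experiments); recurrence ablation zeroes the
whole Tm–Tm block without renormalizing (the lost input is genuinely
removed, not redistributed); the random-weight null redraws Tm input
magnitudes from a standard uniform, renormalizes, and re-runs the Tm stage
(desk-scale default 200 draws; the full-scale experiment used 10,000). Tm20
observables are the pale/yellow column mixture `(1/3) pTm20 + (2/3) yTm20`.

### The packaged example circuit

`example_connectivity()` is a synthetic, clearly labeled count table — not
measured data — carrying the qualitative sign structure of the medulla
circuit: photoreceptors are histaminergic (negative onto each other, Dm9 and
most Tm targets), R8 is positive onto Tm5c, pDm8 positive onto Tm5b, yDm8
negative onto Tm5a, R1–6 positive onto Dm8s, and Dm8<->Dm8 coupling
negative. Its default parameters were chosen so the example *exhibits the
mechanism the model is about*: Tm5a/Tm5b/Tm20 drives are rectified (strongly
negative gamma), thresholded by the broadband achromatic input (negative
`p`), and amplified by recurrent loops whose gain is near critical; fitting
the selectivity model to the simulated responses then yields kappa well
above the photoreceptor level, and silencing outputs or ablating the Tm–Tm
block lowers it. Tm5c is predominantly feedforward and stays broadly tuned.
Real counts are supplied as a CSV with the same columns.

## Interpolation and spectral classification

Tuning maps over 4D log-capture space (gamut + contrast stimuli combined)
use a thin-plate-spline RBF whose polynomial tail keeps the linear monomials
but drops the constant — baseline-subtracted amplitudes need no offset — and
interpolate the training data exactly. Queries outside the convex hull of
the training points are projected to the nearest hull point (a small
quadratic program over the hull's facet inequalities, solved per query;
idempotent by construction). The single-wavelength line evaluates 10 nm-wide
Gaussian lights with peaks 320–580 nm, renormalized to the isoluminant
total; nonspectral lines connect the single-wavelength points of maximal
excitation of each nonadjacent opsin pair (Rh3–Rh5, Rh3–Rh6, Rh4–Rh6) in
capture space, renormalized, parameterized by mixture fraction. A neuron is
nonspectral when its peak interpolated response on a nonspectral line
exceeds its single-wavelength peak.

## Problem sizes and reproducibility

Default experiment sizes are desk scale, chosen so the full test suite and
pipeline complete comfortably on one CPU: gamut sets of 100–320 stimuli,
200-draw nulls, 1,000 bootstrap draws, 100-run recovery studies. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline fans a single seed out to one
stream per stage, so partial reruns reproduce exactly.

## Known limitations

* The synthetic example circuit demonstrates mechanism and ordering, not the
  published per-neuron parameter values, which depend on the real imaging
  data and real synaptic counts.
* The selectivity model uses one hue angle (the cosine with a single
  preferred direction), not a two-angle parameterization.
* The staged fit's loss is discontinuous where a near-critical recurrent
  loop crosses a bistability boundary; the jittered restarts mitigate but do
  not eliminate sensitivity to initialization there.
* Amplitude extraction assumes step-locked responses; kinetics-aware
  deconvolution is out of scope.
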