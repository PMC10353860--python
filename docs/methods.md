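# Methods

## The model

`rdwm` treats visual working memory as a capacity-limited communication
channel. A circular stimulus θ ∈ (−π, π] (a color on a color wheel, an
orientation, a location) is stored and later reported as θ̂; the channel
Q(θ̂|θ) is chosen to minimize the expected distortion D = E[d(θ, θ̂)]
subject to an information-rate bound R = I(θ; θ̂) ≤ C. With the
Lagrangian form min_Q R + βD, the optimal channel is the fixed point

    Q(θ̂|θ) ∝ exp[−β·d(θ, θ̂) + log Q̄(θ̂)],     Q̄ = Σ_θ P(θ) Q(θ̂|θ),

computed by the Blahut–Arimoto alternating iteration
(`rdwm.channel.blahut_arimoto`). The distortion is cosine,
d(θ, θ̂) = −ω·cos(θ − θ̂), so stimuli are coded by populations with
cosine input tuning and von Mises output tuning. All information
quantities are in nats; stimulus space is discretized into K bins
(default K = 100).

The same channel is realized by a spiking winner-take-all circuit
(`rdwm.circuit`). Each stored item m has a subpopulation of N = 100
Poisson neurons with preferred stimuli φ_i; neuron i receives drive
u_im = −β·π_m·d(θ_m, φ_i) + w_im (π_m is the item's probing
probability) and fires with divisively normalized rate
r_i = exp(u_i)/Σ_j exp(u_j), i.e. spikes λ_i = r̄·r_i·Δt per step.
Whenever neuron i spikes, the momentary channel output is φ_i. Two slow
processes implement the channel optimization online:

* **Intrinsic plasticity.** Δw_i = η·(c·e^{−w_i}·z_i − 1) drives
  e^{w_i} toward c·E[z_i], i.e. w toward the log marginal winner
  probability — the log Q̄ term of the optimal channel. Because w
  integrates spike history, it carries traces of recent and frequent
  stimuli; this single mechanism produces serial dependence and
  frequency biases.
* **Homeostatic gain adaptation.** Δβ = α·(C_eff − R), where R is the
  mutual information of the winner channel implied by the current
  (β, w) and C_eff = C·(T_RI + T_ITI)/T_RI rescales the capacity by the
  duty cycle: no information flows during the intertrial interval, so
  longer ITIs permit a higher rate during retention. This yields
  set-size effects (capacity divided over items), retention-interval
  decay, ITI benefits, approximate timescale invariance, and
  performance rebounds after poor trials.

Reports are decoded from the spikes of the probed subpopulation in the
final T_d = 0.1 s of the retention interval by maximum likelihood
against the stimulus-driven tuning curves (scores Σ_i n_i log r_i(θ)
with r_i computed from the β·π·ω·cos term only). The decoder is
deliberately blind to w: an ideal observer that knew the excitability
field would subtract the marginal-rate bias and with it all history
effects. This is the standard population-coding decoding convention,
and it is required for the model to exhibit serial dependence and
frequency biases at all. An option (`CircuitParams.decode_uses_w`)
restores the w-aware decoder. Trials with zero decode-window spikes
return a uniform random report and are flagged.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| N | 100 | neurons | per-item subpopulation size; also grid K |
| ω | 1 | – | distortion scale (absorbed into β) |
| η | 1e-3 | 1/s | plasticity rate (per-step update η·Δt) |
| α | 0.1 | 1/s | gain-adaptation rate (per-step α·Δt) |
| Δt | 0.05 | s | simulation step |
| β₀ | 15 | – | initial gain; clipped to [0, 1000] |
| w clip | [−12, 0] | log-prob | excitability range |
| T_d | 0.1 | s | decode window |
| C | 1.0 | nats | channel capacity (subject-level) |
| r̄ | 50 | spikes/s | population rate scale (subject-level) |
| c | 1/(r̄·Δt) | – | plasticity gain; this value makes the w fixed point equal the marginal winner probability exactly |

C, r̄ and c are subject-level quantities that in practice are fitted to
behavioral data (`rdwm.model_compare.fit_subject_params`). The package
defaults emulate plausible study populations and were calibrated once
against published regularities, not tuned per analysis:

* **Default (C = 1, r̄ = 50).** Single-item error variance ≈ 0.02–0.05
  (human color/orientation scale), zero-spike guess rate < 1%,
  positive excess kurtosis growing as per-item gain falls.
* **Timing paradigm: C = 0.1**, reflecting the unusually noisy color
  dataset this design emulates.
* **Serial-dependence paradigm: r̄ = 200.** The emulated task is
  single-item location memory, where human reports are very precise
  (σ ≈ 2–4°); the higher decode spike count brings simulated precision
  to that scale. The plasticity-driven attraction itself is invariant
  to r̄ (the c default rescales the per-spike increment accordingly).
* **Biased-color paradigm: C = 2.** Frequency biases require the spike
  kernel (width ≈ 1/√(βπ_m)) to be narrower than the bump spacing so
  the excitability field retains contrast between frequent and rare
  stimuli; the bias phenomena themselves imply this sharper-kernel
  regime for those subjects.

## Synthetic paradigms

`rdwm.paradigms` generates the trial schedules: set sizes {1,2,4,8}
with a 3:1 cue probing priority; M = 6 items with factorial RI {1,3} s ×
ITI {1,7.5} s; single-item serial-dependence blocks with RI
{0,1,3,6,10} s and ITI {1,3,6,10} s; two items drawn from four equally
spaced uniform arcs of width π/9 with RI 0.5 or 4 s; and an 8-location
oculomotor delayed response schedule. Missing or RI = 0 cases simulate
an active time of max(RI, T_d) so the decode window always exists. The
ITI is not simulated step-by-step; it enters only through C_eff, and
(w, β) persist unchanged across it.

What the generators do **not** emulate: stimulus rendering and color
space, perceptual encoding noise, attention lapses, motor error, and
subject heterogeneity beyond the three subject-level parameters.
Passing phenomenology checks therefore demonstrates the model's
internal regularities, not fits to any particular human dataset.

`gen_synthetic_behavior` and `gen_synthetic_spikes` are model-free
fixtures with planted ground truth (von Mises noise + DoG attraction;
Poisson counts with cosine tuning, a gain on negative distortion, and a
spike-history EMA term with decay 0.8) used to validate the analysis
modules by parameter recovery. The spike generator caps rates at 10³
spikes/trial: a positive history coefficient makes the count→EMA→rate
loop a positive feedback, and the cap keeps pathological settings
bounded.

## Analyses

* **Circular statistics** (`rdwm.behavior`): trigonometric moments,
  σ² = −2 log|m̄₁| (∞ sentinel for vanishing resultant), Fisher-style
  kurtosis k = (|m̄₂|cos(Arg m̄₂ − 2Arg m̄₁) − |m̄₁|⁴)/(1 − |m̄₁|)²
  (0 by convention for a point mass).
* **Serial dependence**: DoG curve y = x·a·w·c·exp(−(wx)²) with
  c = √(2e), which makes the peak-to-peak amplitude exactly 2a (the
  extrema are at x = ±1/(w√2); a literal constant 2e would break this
  normalization and is available as an argument). Fitting profiles the
  amplitude out in closed form over a log-spaced width grid and refines
  with bounded least squares; the grid-only fit is used inside
  permutation loops. Folded error is θ_e·sign(θ_d) with sign(0) → 0.
  The set-size permutation test shuffles group labels, refits with the
  same rule, and reports the one-sided proportion of null amplitude
  differences at least as large as the observed one.
* **Model comparison** (`rdwm.model_compare`): simulated errors become
  a likelihood through a von Mises KDE per experimental condition,
  mixed with a 1% uniform component. The mixture is essential: the
  simulator's rare guess trials otherwise force the cross-validated
  kernel far too wide and bias fits toward over-tight simulations.
  Kernel concentration is chosen by 5-fold cross-validation on the
  simulated errors. Subject fits maximize this likelihood over a
  coarse candidate grid with common random numbers, refining the
  capacity axis by bisection; BIC uses k = 3 (C, r̄, c). Random-effects
  model selection follows the variational Dirichlet scheme with Monte
  Carlo exceedance probabilities and the protected correction
  pxp = xp·(1 − BOR) + BOR/K, where the Bayes omnibus risk compares the
  random-effects free energy against the equal-frequency null.
* **Neural gain** (`rdwm.neural`): per-neuron bell-shaped tuning fits
  (multi-start least squares over the preferred angle), Poisson GLM of
  trial counts on the cosine distortion to the preferred angle (ω = 1,
  absorbed into β; reported gain is the negated distortion
  coefficient) plus the spike-history EMA (current trial excluded).
  Exclusions: negative gains first, then gains above mean + 5 SD of
  the retained fits. The behavioral error-quantile analysis regresses
  current squared error on the previous-trial above/below-mean
  indicator with a per-session random intercept (MixedLM), falling
  back to session-demeaned OLS for degenerate designs.

## Numerical choices

* Blahut–Arimoto: uniform initialization, residual = max elementwise
  change of Q per sweep, tol 1e-10, max 10⁵ sweeps; rows rescaled by
  their max before exponentiation. For a uniform circular source the
  iteration converges in two sweeps (the marginal is exactly uniform).
* Capacity matching uses bisection on the monotone R(β), tolerance
  1e-6 in rate or gain; capacities above the achievable rate return
  the upper bound with a saturation flag.
* The per-step information rate is the exact mutual information of the
  winner channel implied by the deterministic rates (an idealization:
  R is assumed available to the homeostat, and online estimation is
  deliberately not modeled). For the aligned case K = N the K×N
  softmax field is circulant, and a compiled kernel evaluates R with
  O(N) exponentials and O(N²) multiply–adds; a pure-numpy path computes
  the identical quantity (equality asserted in tests) and is used when
  numba is unavailable.
* Per-trial RNG substreams are spawned from one session seed, so
  changing one trial cannot perturb later trials; the compiled step
  loop draws its Poisson variates from a per-trial seeded stream.
* Decode ties break toward the lowest grid index. Learning rates are
  pre-scaled by Δt so results are insensitive to the step size.

## Scaled-down validation conditions

The acceptance suite (tests/test_acceptance.py) replicates the model's
behavioral regularities at desk scale with fixed seeds; sizes were set
by pilot power analysis before freezing the test seeds:

* set size/prioritization: 3 sessions × 600 trials;
* timing: 3 sessions × 400 trials per interval cell, bootstrap CIs on
  circular variance;
* serial dependence: 16 sessions × 500 trials per interval level.
  Because the attraction effect at the printed η is only ~0.01–0.03 rad
  against report noise, trends are asserted on pooled low-vs-high
  interval contrasts of the folded-error mean within the attraction
  window |x| ∈ [0.1, 1.0] rad (the window matches the spike-kernel
  scale), not on per-level free-width DoG amplitudes, whose sampling
  error at this scale exceeds the effect;
* set-size serial dependence (M = 3 vs M = 1): the model predicts an
  equal peak shift with a wider attraction curve at larger set size; at
  desk scale the windowed folded-error contrast (~0.003 rad against
  σ ≈ 0.4) sits at the edge of resolution, and the check documents
  rather than hides this;
* bias build-up and stationarity: 6 mixed-RI sessions × 900 trials and
  3 × 1000 trials. The within-session growth of serial dependence is
  measured on near pairs (previous target within 0.35 rad, i.e. in the
  same bump), because for distant previous targets the frequency bias
  enters the folded error with random sign and masks the attraction;
  the excitability field is compared against the
  kernel-smoothed empirical stimulus histogram — the winner marginal
  the plasticity rule actually targets. Against a raw 100-bin
  histogram even the analytically ideal field only reaches Spearman
  ρ ≈ 0.73 because of rank ties outside the bumps (measured circuit:
  ≈ 0.6 raw, ≈ 0.97 smoothed);
* blocked-RI bias contrast: per-trial mixed RIs leave the shared gain
  nearly identical across conditions at decode time, so the RI
  dependence of the frequency bias is asserted on RI-blocked sessions
  where the gain equilibrates per condition;
* model recovery: 10 cohorts × 12 subjects × 320 trials, biased
  stimuli with two RI blocks; per-variant candidate grids of two
  parameter points, evidence = −BIC/2, random-effects selection.

## Known limitations

* The delay drive is a clamped stimulus trace; no attractor or
  synaptic maintenance dynamics, and no separate stimulus-presentation
  period is simulated.
* Within-session build-up of serial dependence under *uniform*
  stimulus distributions is below desk-scale resolution in this
  implementation: excitability bumps decay within ~10 trials at the
  default rates, so first-vs-last-third contrasts are ≲ 0.002 rad. The
  build-up checks therefore use biased stimulus distributions, where
  history accumulation is strong.
* The likelihood construction (KDE per condition) is a pragmatic
  choice; nothing in the model fixes how simulated trials should be
  converted into a likelihood.
* Idle location slots (set-size designs) freeze their excitability
  between appearances rather than decaying.
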