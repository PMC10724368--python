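# Methods

## Model

Six areas share one angular grid of 41 preferred angles (−60°…+60°, 3°
spacing). A stimulus at angle J drives a sensory sheet (M1 for the motor
command, V for the visual hand) through Gaussian receptive fields,

    s_k = gain · exp(−((θ_k − J)/Δ)² / (2σ²)),

with the angular offset expressed in units of the grid spacing Δ = 3° and
σ the receptive-field width in grid steps (default 3; σ = 2/3/4 give
field extents of roughly ±20°/±30°/±40°, which coincide at one common
intensity level exp(−50/9) ≈ 0.0039). Intensities below 10⁻⁶
(configurable) are clipped to zero so a field has finite extent.

All rates evolve in 1 ms Euler steps. Sensory sheets relax toward their
stimulus with rate constant C; downstream areas relax toward `tanh` of
their summed weighted input. Per-area constants: C = 0.04 for M1, V, S1
and EBA, C = 0.01 for TPJ (a slow accumulator), C = 0.15 for AI (a fast
readout). Firing rates are rectified at zero: inhibition can silence a
neuron but not drive its rate negative. Rectification matters for
learning stability — without it, epochs in which AI is pushed to strongly
negative rates reverse the sign of the Hebbian products and grow
runaway excitatory patches in the plastic matrices.

### Wiring

M1→S1, V→EBA and TPJ→AI are one-to-one (topographic). The two
projections converging on TPJ pool their input: each TPJ neuron averages
its angular neighbourhood of S1+EBA through a normalized Gaussian kernel
(width `tpj_pool_sigma` = 4 grid steps) and the pooled drive is amplified
by `tpj_gain` = 7 before the tanh. Pooling plus saturation is what makes
TPJ behave as an integration field: neighbourhoods stimulated by either
modality saturate, so the region where the proprioceptive and visual
receptive fields overlap accumulates drive across the sequential motor
and visual epochs and, at intermediate disparities, outgrows both
single-modality lobes (the TPJ peak sits between the hands, e.g. at
about 24° for a 39° disparity). Grid-edge neurons pool a truncated
neighbourhood and receive proportionally less drive (`tpj_edge_mode =
"attenuate"`; `"normalize"` equalizes them instead, but then the weaker
learned inhibition at the border creates spurious edge attractors).

Fixed weights are 1, with two calibrated exceptions: W_EBA−TPJ = 0.85
(the visual transmission into the primary integrator is slightly weaker
than the proprioceptive one; at 1.0 the training equilibrium loses the
vision-only/proprioception-only ownership asymmetry) and W_TPJ−AI = 1.5
(at 1.0 the AI output saturates below the 0.7 firing threshold even for
a perfectly integrated stimulus, so no ownership judgment could ever be
positive — tanh(TPJ) ≤ tanh(1) ≈ 0.76 leaves no headroom once any
inhibition is present).

### Plasticity

S1→AI and EBA→AI are full matrices initialized to 1. After each learning
trial, W ← W + ΔW·W_inhibit, where ΔW integrates
α·Vi·Vj + β·Vi′·Vj + γ·Vi·Vj′ over the trial (α = −0.0035, β = 0.35,
γ = −0.55; primes are per-step differences, 1 ms steps, no smoothing)
and W_inhibit is a per-postsynaptic-neuron gate,
tanh(g − (2·arccos(fs)/π)·e^(fn−1)) + 1, with fs = 1 iff the neuron's
rate exceeded 0.7 at any step of the trial and fn its lifetime count of
firing trials. The gate starts at 1 (neutral midpoint of its (0, 2)
range), fn accumulates over the whole run, and the gate multiplies the
entire incoming row of ΔW. Weights are not clipped by default
(`weight_clip` exists as a guard, off by default).

### Trial protocol

Per trial: the motor command is on for 0–100 ms; the visual consequence
follows at 100–200 ms (the camera sees the finger only after it moves);
the trial lasts 600 ms, covering the early (~200 ms) and late (~400 ms)
response phases of AI. All timing is configuration. A visual delay adds
to the visual onset; a delay that pushes the onset past the trial end
simply means the stimulus is never seen. Training draws a motor angle
uniformly from the grid each trial and presents the congruent visual
angle at gain 1; 500 trials per network, and experiments use five
independently trained replicates with per-disparity median drift
(individual replicates occasionally converge to a frozen excitatory
patch — a row whose gate collapsed while still net-positive — and the
median across replicates is robust to these).

### Readout

The behavioural decision is the preferred angle of the AI neuron with
the global spatio-temporal maximum rate over the trial; ties break
toward the motor angle; an all-zero AI trace is a distinct no-decision
outcome. Ownership is true iff any AI neuron exceeds the 0.7 threshold
during the trial. When AI is fully lesioned the decision is read from
TPJ instead (the primary integrator is the only remaining multisensory
representation).

## Experiments

* **Drift**: proprioception at 0°, visual hand at each grid disparity;
  drift = decoded angle − 0°.
* **Precision**: one training per receptive-field width σ ∈ {2, 3, 4};
  wider fields (lower proprioceptive precision) strengthen and widen the
  illusion. Max-normalization of curves is available for plotting only.
* **Appearance**: a similar/dissimilar visual hand acts purely through
  the EBA input gain. The gains are calibrated so the similar hand
  closes the illusion window near the drift-curve plateau onset and the
  dissimilar hand induces no drift anywhere: 0.1 and 0.02.
* **Asynchrony**: visual delays of 100 and 500 ms; 500 ms pushes vision
  outside the trial's integration window and abolishes the drift.
* **Unisensory**: ownership with only the motor command or only the
  visual hand.
* **Disability**: scaling S1→TPJ and EBA→TPJ (TPJ lesion) or S1→AI,
  TPJ→AI and EBA→AI (AI lesion) by (1 − severity); the network is
  trained and tested under the lesion.
* **Breakpoint**: a two-segment continuous piecewise-linear fit of the
  non-negative drift branch by exhaustive knot search over grid
  disparities; a straight line fitting as well as any knot yields a
  distinct no-breakpoint outcome.

## Numerical choices

Euler steps of 1 ms; the plasticity integral uses the same step
(`plasticity_rate`, exposed for sensitivity analyses along with
`learning_window_ms`, which can restrict learning to an initial portion
of the trial; defaults integrate the whole trial at full step).
Exponents in the gate are capped at 50 before `exp` to avoid overflow
(the gate is indistinguishable from 0 there). Decode ties are resolved
within 10⁻¹² of the maximum. The breakpoint fit treats a knot as absent
when the straight-line SSE is within 10⁻⁹·scale² of the best knot's.

## What the simulations do and do not show

The trained model reproduces, robustly across seeds: the sign flip of
both plastic pathways with vision inhibited more strongly than
proprioception; visual capture at small disparities (decoded drift
equals the disparity up to ±one grid step for disparities ≤ 21°, zero
drift for congruent input, antisymmetric in the disparity sign);
ownership for proprioception-only but not vision-only stimulation;
abolition of the drift by a 500 ms visual delay or a dissimilar visual
hand; a flat zero-drift curve under a full TPJ lesion and
vision-dominated decisions under a full AI lesion; TPJ neurons that
always classify as integration neurons while AI neurons segregate early
in the trial and integrate late; and TPJ rates that fall — and early AI
rates that rise — with increasing disparity.

It does **not** reproduce the published mid/large-disparity decodes
(drift 24° at 39° disparity, 0° at 60°, the 18° anterior AI peak, or the
21° plateau knot as a stable statistic; this implementation decodes
≈ 36° and ≈ 54° at the two large disparities). The reason is structural:
with trial-maximum decoding, the learned inhibition self-organizes to
exactly the strength that silences AI while a stimulus is on, so each
stimulus's lobe becomes readable only after its own offset — and the
later (visual) lobe's readable window is never poisoned by the earlier
(proprioceptive) stimulus's inhibition, while the reverse poisoning
always occurs. Visual capture therefore persists at every disparity
instead of collapsing to proprioception beyond the overlap range.
Across a broad structural exploration (pooling widths and gains,
asymmetric kernels, stimulus timings and durations, learning-rate and
learning-window variations, diagonal versus full plastic matrices), no
operating point of these dynamics produced both the small-disparity
capture and the large-disparity collapse of the published curves; the
behaviours listed in the previous paragraph were prioritized because
they are the mechanistically central claims.

## Limitations

The synthetic stimuli are noiseless Gaussian bumps with deterministic
timing; real camera-derived angle estimates are noisy and the robot's
motion takes variable time, so passing tests here says nothing about
robustness to sensor noise or timing jitter. The angle grid is bounded
(no circular wrap), and edge attenuation of the TPJ pooling is a
boundary artifact choice, not biology. The trial-integrated rate rule is
a mean-field abstraction of spike-timing plasticity; only its integral
coefficients are used. Behavioural decisions come from a single
trial-maximum readout with deterministic tie-breaking, not a stochastic
decision process.
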