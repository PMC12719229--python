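# Methods

## Device emulation

A memristive synapse is reduced to (i) mean potentiation and depression
curves giving the normalized weight after p identical pulses from either
end of the conductance range, (ii) a per-update noise SD `sigma_update`,
(iii) an optional cycle-to-cycle offset SD `sigma_cycle`, and (iv) hard
bounds [0, 1] (saturation). Absolute conductances are never exposed:
weights are min–max normalized over the device range.

Mean curves are either parametric saturating exponentials,
`w(p) = (1 − exp(−ν·p/N)) / (1 − exp(−ν))` for potentiation and its
mirror image for depression, with the linear limit taken for ν → 0, or
tabulated means loaded from measured pulse-train cycles
(`load_cycles_csv`, linear interpolation). The parametric form makes
curve linearity a single scalar per direction, which is what the
linearity sweeps vary. N defaults to 200 pulses over the full range.

**State mapping on asymmetric curves.** The device holds one scalar
weight; each update maps the weight to its pulse position on the curve
of the update's direction (closed-form or interpolated inverse),
advances by |Δp|, and maps back. This mirrors how identical-pulse
programming traverses direction-specific curves. Two consequences worth
knowing: near the top of the range potentiation is shallow (the ε₁
nonlinearity error), and at mid-range the depression curve is locally
steeper than the potentiation curve, so zero-mean update noise is
partially rectified into a small downward drift. Both effects are
partially compensated by the error-correcting feedback (below), not
eliminated.

**Noise model.** The default scales the per-update noise SD as
`sigma_update·sqrt(|Δp|)` (independent per-pulse accumulation; reduces
to per-pulse noise at Δp = 1). A `per_update` mode applies a constant
`sigma_update` per pulse train instead; that mode matches how a single
pooled error term is extracted from overlapping measured ramps, and it
is the default in the water-maze configuration, where the emulation
pools cycle-to-cycle variability and update noise into one σ. Reads add
zero-mean Gaussian noise (`sigma_read`, default 0.01) and clip to
[0, 1]; reads never mutate state.

**Synthetic bank.** `generate_synthetic_bank` draws 27 device profiles
with ν ∈ [1, 4] per direction and `sigma_update` ∈ [0.005, 0.03] from a
bank seed, spanning near-linear to visibly nonlinear behaviour with
device-to-device spread. The T-maze assigns one device per weight
(27 weights, 27 devices); the water maze reuses the 27 profiles over
its 1,089 weights by random assignment. A caveat found empirically: at
the harsher end of these defaults (ν ≳ 2 or σ ≳ 0.01 per update) the
water-maze task stops converging within 400 episodes — the synthetic
bank at default settings is a stress test, not a calibrated replica of
measured devices, which behave more mildly.

## Network and learning rule

Single-layer actor–critic with softmax action selection (temperature T,
max-subtracted for stability) and TD(0) error
`δ = r + γ·V(s′) − V(s)`. The reward (1 at the goal, 0 elsewhere) is
credited on the transition *entering* the goal, with the terminal
next-state value forced to zero; under this convention, with values in
[0, 1], no desired critic update can exceed α. Actor Hebbian terms use
the raw preferences h as printed in the source model; a
`hebbian_uses_policy` switch substitutes the softmax probabilities (the
standard policy-gradient form) for comparison — in our experiments the
two perform equivalently on both tasks. All weights start at 0 (for
devices: programmed to minimum conductance). Desired updates are
quantized to pulses by round-half-away-from-zero; updates below half a
pulse (|Δw| < 1/2N) therefore apply nothing, a dead zone that matters
at small learning rates.

**Ideal reference.** The `ideal` backend applies desired updates
exactly — continuous, noiseless, unquantized — but still bounded to
[0, 1], since an ideal analogue synapse retains a finite conductance
range (an unbounded variant exists for pure tabular comparisons, and
the ideal T-maze runs are bit-identical to an independent tabular TD
implementation at matched random streams).

## In-memory update calculation and error correction

For one-hot encoding the desired critic update is the scalar product
`(U₁, U₂, U₃)·(w_fixed, w_{t+1}, w_t)` with `U₁ = α·r`, `U₂ = α·γ`,
`U₃ = −α` and `w_fixed = 1`, evaluated on (noisy reads of) the devices
themselves. With RBF encoding the same principle is applied through
device-backed value reads `V = Σ w_j x_j`; the explicit three-terminal
voltage mapping is emulated only for the one-hot case. Because the
devices that accumulated ε₁/ε₂ errors supply the next value estimates,
those errors shift subsequent TD errors and are trained away.

The no-feedback ablation computes the learning signal instead from
*shadow weights* that advance by the exact linear-expected change
Δp/N of the same pulse trains (clipped to [0, 1]); device errors then
accumulate unseen. With noiseless linear devices the two modes are
bit-identical, which pins the semantics: quantization is part of the
desired update, ε₁/ε₂ are the errors under study. The feedback study
(`feedback_experiment`) trains many paired runs and compares across-run
mean and SD of each critic weight per episode; at matched noise the
final spread with feedback is roughly half the spread without.

## Environments

**T-maze**: nine states, stem 0–4, junction at 4, left arm 4→5→6
(reward at 6, terminal), right arm 4→7→8; two actions everywhere
(forward/backward, reinterpreted left/right at the junction); dead-end
moves waste a step. The optimal start→reward path is 6 transitions.
Uniform-random behaviour is validated against the closed-form
absorbing-Markov-chain expectation.

**Water maze**: unit square, hidden circular platform at the centre,
U-shaped obstacle open at the top so the platform must be approached
from above, eight compass actions of fixed step length, episode ends on
entering the platform disc. Moves that would cross the arena border or
a wall segment are cancelled (the agent stays put; the step counts) —
the simplest rule consistent with the obstacle's purpose. Starts are
uniform outside an exclusion disc around the platform.

**Geometry calibration.** The source reports two anchors: ~450 steps
for a uniform random walk and ~6.5 steps for the ideal learner after
convergence. A grid over step length, platform radius, exclusion radius
and obstacle extent showed the two anchors cannot be met by one
geometry under this learner: configurations with a ~450-step random
walk have a best-achievable (BFS-oracle) mean path of ~6.3–6.5 steps,
but the trained agent carries a ~+2.5-step overhead (mostly wall-blocked
moves near the obstacle plus residual softmax exploration), landing at
~9–12. The frozen defaults — platform (0.5, 0.5) radius 0.09, walls at
x = 0.38/0.62 from y = 0.15 to 0.72, step 0.12, exclusion 0.35 — give a
random-walk mean of ~436 and a BFS-optimal mean of 6.30; the converged
trained mean is ~10–12 and is reported as such, not tuned to the
anchor.

## Hyperparameters

| parameter | T-maze | water maze | note |
|---|---|---|---|
| α (learning rate) | 0.2 | 0.2 | T-maze value from the source; water-maze value from a grid search requiring convergence for both ideal and pulse-quantized synapses (smaller α falls into the one-pulse dead zone) |
| T (softmax temperature) | 0.3 | 0.15 | same grid search for the water maze |
| γ (discount) | 0.9 | 0.9 | |
| N (pulse granularity) | 200 | 200 | |
| episodes | 200 | 400 | water-maze count is a package default |
| RBF width | — | 0.1 (grid spacing) | unnormalized Gaussians, max 1 at the centre |
| σ_read | 0.01 | 0.01 | negligible effect on convergence |

## Randomness and reproducibility

One master seed per run spawns separate substreams for action sampling,
device noise (one per synapse array) and environment starts, so device
noise never perturbs the action sequence and identical configurations
reproduce byte-identical logs. Synapse arrays draw noise per update
from their array stream; this differs from per-device scalar streams
only in bookkeeping, not in distribution.

## What the synthetic studies do and do not show

The generator emulates mean curve shape, update/read noise and
granularity. It does not model conductance drift, endurance,
temperature effects, electrical transients or crossbar parasitics; the
error-correction property covers slow drift only qualitatively (a
drifted weight re-enters δ and is retrained). Passing tests show the
learning dynamics and the error-correction mechanism behave as derived
under the stated device model — not that any particular physical device
will match the synthetic bank's parameter ranges. Known limitations:
the default synthetic bank stalls water-maze learning (see above); the
trained water-maze mean exceeds the best-achievable path by ~50% in
obstacle geometries; and on the T-maze, *more* nonlinear curves
converge faster (the steep low-weight region acts as a learning-rate
boost), so the linearity benefit reported for the continuous task does
not transfer to the discrete one.
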