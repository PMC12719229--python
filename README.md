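# memtd — actor–critic TD learning on emulated memristor synapses

`memtd` simulates reward-based navigation learning in which every
synaptic weight of a small actor–critic network lives on an analogue
memristive device. It is aimed at researchers in neuromorphic
engineering and computational neuroscience who want to study how device
non-idealities — nonlinear potentiation/depression, update noise,
finite pulse granularity — interact with temporal-difference (TD)
learning, and how computing the weight updates *in memory* on the very
devices that carry the errors gives an error-correction mechanism for
free.

## The model

Place cells `x_t` encode the agent's position (one-hot state indicators
in a discrete T-maze; Gaussian radial basis functions on an 11×11 grid
in a continuous water maze). A single-layer network carries action
preferences and a state value,

    h_i = Σ_j θ_ij x_j,   π(i|s_t) = exp(h_i/T) / Σ_k exp(h_k/T),
    V(s_t) = Σ_j w_j x_j,

and all weights follow a three-factor (neo-Hebbian) rule gated by the
TD error δ_t, the global reward-prediction-error signal:

    δ_t  = r(s_t) + γ V(s_{t+1}) − V(s_t)
    Δθ_ij = α · δ_t · H_act(i,j),   Δw_j = α · δ_t · H_cri(j)

with `H_act(i,j) = (1−h_i)x_j` for the chosen action and `−h_i x_j`
otherwise, and `H_cri(j) = x_j`. Desired updates are converted to
signed trains of identical programming pulses, `Δp = round(Δw·N)`, and
applied to emulated devices whose mean response is a saturating
exponential with per-direction nonlinearity ν, per-update noise σ and
hard bounds [0, 1]. Because the next TD error is computed from reads of
the same error-bearing devices (for one-hot encoding, literally as the
scalar product `(αr, αγ, −α)·(1, w_{t+1}, w_t)`), programming errors
re-enter the learning signal and are trained away.

## Worked example

```python
import numpy as np
from memtd import ExperimentConfig, TMazeEnv, run_tmaze, evaluate_greedy

log = run_tmaze(ExperimentConfig(episodes=200, seeds=[0]), seed=0)
print("trailing-50 mean steps:", log.steps[-50:].mean())
print("greedy steps to reward:", evaluate_greedy(log.net, TMazeEnv()))
print("critic weights:", np.round(log.final_w, 3))
```

prints

```
trailing-50 mean steps: 6.8
greedy steps to reward: 6
critic weights: [0.499 0.568 0.638 0.753 0.862 0.961 0.    0.488 0.354]
```

The agent converges close to the six-step optimal path of the nine-state
T-maze (trailing mean 6.8 under continued softmax exploration; exactly 6
when evaluated greedily), and the learned critic weights approach the
discounted-value profile γ^(d−1) of each state's distance d to the
reward — e.g. w₅ near 1 and w₄ near 0.9 — with the residual gap
reflecting device noise and pulse quantization on the emulated
memristors. The same interfaces drive the continuous water-maze task
(`run_watermaze`), device-bank generation and loading
(`generate_synthetic_bank`, `load_cycles_csv`), the error-correction
study (`feedback_experiment`) and parameter sweeps (`sweep`,
`grid_search`), either from Python or through the `memtd` command-line
tool (`memtd run-tmaze`, `memtd baseline --task watermaze`, ...).

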