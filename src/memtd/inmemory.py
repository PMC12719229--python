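"""In-memory desired-weight-update calculation and error-correcting feedback.

The desired critic update for a one-hot-encoded transition is a
three-term scalar product that analogue hardware evaluates directly on
the devices storing the values,

    dw_des = alpha * r + alpha * gamma * V(s') - alpha * V(s)
           = (U1, U2, U3) . (w_fixed, w_{t+1}, w_t),

with input voltages U1 = alpha * r, U2 = alpha * gamma, U3 = -alpha
applied to a unit fixed weight and the two critic devices.  Because the
very devices that accumulated the programming errors (epsilon_1 from
curve nonlinearity, epsilon_2 from update noise) are read to form the
next TD error, those errors re-enter the learning signal and are trained
away: the error-correction mechanism.  The no-feedback ablation instead
computes the learning signal from shadow weights holding what exact
(noiseless, linear) devices would have realized from the same pulse
trains, so the real devices' errors accumulate unseen.

For RBF encoding the explicit three-device product generalizes to a full
vector product; here the TD error is computed from (noisy) device-backed
value reads V = sum_j w_j x_j, which preserves the feedback property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AgentNetwork, delta_to_pulses, hebbian_actor

__all__ = [
    "InMemoryConfig",
    "Transition",
    "UpdateRecord",
    "compute_dw_inmemory",
    "update_step",
    "feedback_experiment",
]


@dataclass(frozen=True)
class InMemoryConfig:
    """Settings of the emulated in-memory update calculation."""

    sigma_read: float = 0.01  # read-noise SD on device value reads
    feedback: bool = True     # False = the no-feedback ablation
    w_fixed: float = 1.0      # the unit reference weight carrying alpha * r

    def __post_init__(self) -> None:
        if self.sigma_read < 0:
            raise ValueError(f"sigma_read must be >= 0, got {self.sigma_read}")
        if self.w_fixed != 1.0:
            raise ValueError("w_fixed must be 1 (it carries the reward term)")


@dataclass(frozen=True)
class Transition:
    """One environment step as seen by the learner."""

    x_t: np.ndarray          # place-cell activation of the current state
    x_next: np.ndarray       # activation of the next state
    chosen: int              # sampled action index i*
    h: np.ndarray            # actor preferences used for action selection
    pi: np.ndarray           # softmax policy used for action selection
    reward: float
    terminal: bool
    state: int | None = None       # one-hot state index, if applicable
    next_state: int | None = None


@dataclass(frozen=True)
class UpdateRecord:
    """What one learning step computed and applied."""

    delta: float
    dw_des: np.ndarray       # desired critic updates, per weight
    dtheta_des: np.ndarray   # desired actor updates (n_actions x n_cells)
    dp_critic: np.ndarray | None   # pulses applied (None for ideal backends)
    dp_actor: np.ndarray | None
    realized_dw: np.ndarray        # actual critic weight changes
    realized_dtheta: np.ndarray


def compute_dw_inmemory(w_t_syn, w_next_syn, r: float, alpha: float,
                        gamma: float, cfg: InMemoryConfig,
                        terminal: bool | None = None) -> float:
    """Desired critic update from device reads (the emulated scalar product).

    ``w_t_syn`` and ``w_next_syn`` expose ``read(sigma)``; pass ``None``
    for ``w_next_syn`` on a terminal transition (the next-state value is
    taken as zero).  With ``cfg.sigma_read = 0`` this is exactly
    alpha * (r + gamma * V(s') - V(s)) on the stored weights.
    """
    if w_t_syn is None:
        raise ValueError("missing device for the current state")
    if terminal is None:
        terminal = w_next_syn is None
    if not terminal and w_next_syn is None:
        raise ValueError("missing device for a non-terminal next state")
    if terminal:
        w_next_syn = None
    u1 = alpha * r
    u2 = alpha * gamma
    u3 = -alpha
    v_curr = float(w_t_syn.read(cfg.sigma_read))
    v_next = 0.0 if w_next_syn is None else float(w_next_syn.read(cfg.sigma_read))
    return u1 * cfg.w_fixed + u2 * v_next + u3 * v_curr


def update_step(net: AgentNetwork, tr: Transition,
                cfg: InMemoryConfig) -> UpdateRecord:
    """One three-factor learning step with device-backed update calculation.

    Computes the TD error from device value reads (feedback mode) or
    from the exact shadow weights (no-feedback ablation), forms the
    desired actor/critic updates, converts them to pulse counts and
    applies them to the backing devices.  In both modes the shadows
    advance by the linear-expected change dp / N of the same pulses.
    """
    if cfg.feedback:
        w_read = net.critic.read(cfg.sigma_read)
    else:
        w_read = net.shadow_w
    v_curr = float(w_read @ tr.x_t)
    v_next = 0.0 if tr.terminal else float(w_read @ tr.x_next)
    delta = tr.reward + net.gamma * v_next - v_curr

    post = tr.pi if net.hebbian_uses_policy else tr.h
    h_act = hebbian_actor(tr.chosen, post, tr.x_t)
    dw_des = net.alpha * delta * tr.x_t
    dtheta_des = net.alpha * delta * h_act

    if net.critic.quantized:
        dp_c = delta_to_pulses(dw_des, net.n_pulses)
        realized_dw = net.critic.apply_pulses(dp_c)
        # shadow: what an exact linear device would do with these pulses
        net.shadow_w = np.clip(net.shadow_w + dp_c / net.n_pulses, 0.0, 1.0)
    else:
        dp_c = None
        realized_dw = net.critic.apply_dw(dw_des)
        net.shadow_w = net.shadow_w + realized_dw
    if net.actor.quantized:
        dp_a = delta_to_pulses(dtheta_des.ravel(), net.n_pulses)
        realized_dth = net.actor.apply_pulses(dp_a).reshape(dtheta_des.shape)
        dp_a = dp_a.reshape(dtheta_des.shape)
        net.shadow_theta = np.clip(
            net.shadow_theta + dp_a / net.n_pulses, 0.0, 1.0)
    else:
        dp_a = None
        realized_dth = net.actor.apply_dw(dtheta_des.ravel()).reshape(dtheta_des.shape)
        net.shadow_theta = net.shadow_theta + realized_dth

    return UpdateRecord(
        delta=float(delta), dw_des=dw_des, dtheta_des=dtheta_des,
        dp_critic=dp_c, dp_actor=dp_a,
        realized_dw=realized_dw, realized_dtheta=realized_dth,
    )


def feedback_experiment(n_runs: int, noise_level: float, episodes: int,
                        seed: int, nonlinearity: float = 2.5,
                        sigma_read: float = 0.0):
    """Across-run variability of the learned T-maze critic weights,
    with the error-correcting feedback on versus off.

    Every device uses the same update-noise SD ``noise_level`` and
    nonlinearity ``nonlinearity`` for both ramp directions; each run is
    trained twice from the same per-run seed, once per mode.  Returns,
    per mode, the per-episode mean and SD of each critic weight across
    runs.
    """
    from .experiments import ExperimentConfig, run_tmaze  # avoid import cycle
    from .devices import DeviceBank, generate_synthetic_curve

    results = {}
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
    for mode in ("feedback", "no_feedback"):
        snaps = []
        for rs in run_seeds:
            curve = generate_synthetic_curve(
                nu_pot=nonlinearity, nu_dep=nonlinearity,
                sigma_update=noise_level)
            bank = DeviceBank([curve] * 27, bank_seed=0)
            cfg = ExperimentConfig(
                task="tmaze", episodes=episodes, seeds=[rs],
                inmemory=InMemoryConfig(sigma_read=sigma_read,
                                        feedback=(mode == "feedback")),
            )
            log = run_tmaze(cfg, bank=bank, seed=rs)
            snaps.append(log.critic_snapshots)
        snaps = np.stack(snaps)  # (runs, episodes, n_cells)
        results[mode] = {
            "mean": snaps.mean(axis=0),
            "sd": snaps.std(axis=0, ddof=1) if n_runs > 1
                  else np.zeros(snaps.shape[1:]),
            "degenerate": n_runs < 2,
        }
    return results
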