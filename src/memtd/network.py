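"""Single-layer actor-critic network with three-factor plasticity.

Place cells x encode the agent's position (one-hot state indicators in
the discrete maze, Gaussian radial basis functions on an 11 x 11 grid in
the continuous maze).  An actor neuron per action i carries a preference
h_i = sum_j theta_ij x_j turned into a softmax policy with temperature
T; a single critic neuron carries the state value V = sum_j w_j x_j.

Both weight sets follow the neo-Hebbian three-factor rule

    d theta_ij = alpha * delta * H_act(i, j)
    d w_j      = alpha * delta * H_cri(j)

where the third factor delta = r + gamma * V(s') - V(s) is the TD error
(the global reward-prediction-error signal) and the Hebbian terms are
built from pre-synaptic activity x_j and post-synaptic activity: for the
actor, H_act(i, j) = (1 - h_i) x_j for the chosen action i* and
-h_i x_j otherwise; for the critic, H_cri(j) = x_j.

Desired weight changes are converted into signed counts of identical
programming pulses via dp = round(dw * N) (linear conversion with N the
device's full-range pulse count); the mismatch between this linear
assumption and the actual device response is what the error-correcting
feedback loop in :mod:`memtd.inmemory` compensates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .devices import DeviceBank, IdealWeights, SynapseArray

__all__ = [
    "PlaceCellLayer",
    "AgentNetwork",
    "activation",
    "action_preferences",
    "policy",
    "sample_action",
    "value",
    "td_error",
    "hebbian_actor",
    "hebbian_critic",
    "desired_updates",
    "delta_to_pulses",
]


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaceCellLayer:
    """Fixed input encoder mapping a position to place-cell activations."""

    mode: str  # "one-hot" | "rbf"
    n_cells: int
    centers: np.ndarray | None = None  # (n_cells, 2), rbf mode
    width: float = 0.1  # RBF standard deviation, arena units

    @classmethod
    def one_hot(cls, n_states: int) -> "PlaceCellLayer":
        return cls(mode="one-hot", n_cells=n_states)

    @classmethod
    def rbf_grid(cls, n_side: int = 11, width: float | None = None,
                 lo: float = 0.0, hi: float = 1.0) -> "PlaceCellLayer":
        """Evenly spaced grid of RBF centers over the square arena.

        Default width equals the grid spacing, giving substantially
        overlapping fields.
        """
        xs = np.linspace(lo, hi, n_side)
        cx, cy = np.meshgrid(xs, xs, indexing="ij")
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        if width is None:
            width = (hi - lo) / (n_side - 1)
        return cls(mode="rbf", n_cells=n_side * n_side,
                   centers=centers, width=width)

    def activation(self, position) -> np.ndarray:
        if self.mode == "one-hot":
            s = int(position)
            if not 0 <= s < self.n_cells:
                raise IndexError(f"state index {s} out of range [0, {self.n_cells})")
            x = np.zeros(self.n_cells)
            x[s] = 1.0
            return x
        pos = np.asarray(position, dtype=float)
        if pos.shape != (2,):
            raise ValueError("rbf mode expects a 2-D position")
        lo = self.centers.min()
        hi = self.centers.max()
        if np.any(pos < lo - 1e-9) or np.any(pos > hi + 1e-9):
            raise ValueError(f"position {pos} outside arena bounds [{lo}, {hi}]")
        d2 = np.sum((self.centers - pos) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * self.width**2))


def activation(layer: PlaceCellLayer, position) -> np.ndarray:
    """Place-cell activation vector x_t for a position (see the layer)."""
    return layer.activation(position)


# ---------------------------------------------------------------------------
# Forward pass and policy
# ---------------------------------------------------------------------------

def action_preferences(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Actor-neuron activities h_i = sum_j theta_ij x_j."""
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    if theta.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: theta {theta.shape}, x {x.shape}")
    return theta @ x


def policy(h: np.ndarray, temperature: float) -> np.ndarray:
    """Softmax policy pi_i = exp(h_i / T) / sum_k exp(h_k / T)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    z = np.asarray(h, dtype=float) / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def sample_action(pi: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw from the policy; reproducible given the rng state."""
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi is not a probability vector")
    return int(rng.choice(pi.size, p=pi / pi.sum()))


def value(w: np.ndarray, x: np.ndarray) -> float:
    """Critic-neuron activity V = sum_j w_j x_j."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"shape mismatch: w {w.shape}, x {x.shape}")
    return float(w @ x)


def td_error(r: float, v_next: float, v_curr: float, gamma: float,
             terminal: bool = False) -> float:
    """TD error delta = r + gamma * V(s') - V(s); V(s') = 0 at termination.

    The reward is credited on the transition that enters the reward
    state, with the terminal next-state value forced to zero; this is
    the convention under which the desired critic update is bounded by
    alpha for rewards in {0, 1} and values in [0, 1].
    """
    if terminal:
        v_next = 0.0
    return float(r + gamma * v_next - v_curr)


# ---------------------------------------------------------------------------
# Three-factor updates
# ---------------------------------------------------------------------------

def hebbian_actor(chosen: int, h: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Actor Hebbian term: (1 - h_i) x_j on the chosen row, -h_i x_j elsewhere."""
    h = np.asarray(h, dtype=float)
    x = np.asarray(x, dtype=float)
    if not 0 <= chosen < h.size:
        raise IndexError(f"chosen action {chosen} out of range [0, {h.size})")
    post = -h.copy()
    post[chosen] += 1.0
    return np.outer(post, x)


def hebbian_critic(x: np.ndarray) -> np.ndarray:
    """Critic Hebbian term: the pre-synaptic activity itself."""
    return np.asarray(x, dtype=float)


def desired_updates(delta: float, h_act: np.ndarray, h_cri: np.ndarray,
                    alpha: float):
    """Three-factor desired updates (d theta, d w) = alpha * delta * H."""
    return alpha * delta * np.asarray(h_act), alpha * delta * np.asarray(h_cri)


def delta_to_pulses(dw, n_pulses: int):
    """Signed pulse count dp = round(dw * N), half rounded away from zero."""
    if n_pulses < 1:
        raise ValueError(f"n_pulses must be >= 1, got {n_pulses}")
    dw = np.asarray(dw, dtype=float)
    dp = np.sign(dw) * np.floor(np.abs(dw) * n_pulses + 0.5)
    dp = dp.astype(int)
    return int(dp) if dp.ndim == 0 else dp


# ---------------------------------------------------------------------------
# The agent network
# ---------------------------------------------------------------------------

@dataclass
class AgentNetwork:
    """Actor weight matrix and critic weight vector plus hyperparameters.

    Each weight is backed either by an emulated memristor (a slot of a
    :class:`~memtd.devices.SynapseArray`, updated only by pulses) or by
    an ideal continuous scalar.  Alongside the physical weights the
    network tracks *shadow* copies holding what an exact (noiseless,
    linear) device would have realized from the same pulse trains;
    these serve as the error-free reference for the no-feedback
    ablation and for error bookkeeping.
    """

    layer: PlaceCellLayer
    n_actions: int
    actor: SynapseArray | IdealWeights
    critic: SynapseArray | IdealWeights
    alpha: float = 0.2
    gamma: float = 0.9
    temperature: float = 0.3
    n_pulses: int = 200
    hebbian_uses_policy: bool = False
    shadow_theta: np.ndarray = field(init=False)
    shadow_w: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        n = self.layer.n_cells
        if self.actor.n != self.n_actions * n or self.critic.n != n:
            raise ValueError("backend sizes do not match layer/action counts")
        self.shadow_theta = np.zeros((self.n_actions, n))
        self.shadow_w = np.zeros(n)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, layer: PlaceCellLayer, n_actions: int, *,
              backend: str = "device", bank: DeviceBank | None = None,
              rng: np.random.Generator | None = None,
              noise_mode: str = "per_pulse_sqrt", **hyper) -> "AgentNetwork":
        """Build a network with ``backend`` in {"device", "ideal"}.

        Device backing draws one RNG substream for the actor array and
        one for the critic array so that device noise never perturbs
        action sampling.  All weights start at zero (for devices: each
        programmed to its minimum-conductance weight).
        """
        n = layer.n_cells
        if backend == "ideal":
            actor = IdealWeights(n_actions * n)
            critic = IdealWeights(n)
        elif backend == "device":
            if bank is None or rng is None:
                raise ValueError("device backend needs a bank and an rng")
            r_actor, r_critic, r_assign = rng.spawn(3)
            n_total = n_actions * n + n
            assignment = bank.assignment
            if assignment is None or len(assignment) != n_total:
                assignment = bank.assign(n_total, r_assign)
            actor = SynapseArray(bank.curves, assignment[:n_actions * n],
                                 r_actor, noise_mode=noise_mode)
            critic = SynapseArray(bank.curves, assignment[n_actions * n:],
                                  r_critic, noise_mode=noise_mode)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        return cls(layer=layer, n_actions=n_actions, actor=actor,
                   critic=critic, **hyper)

    # -- reads --------------------------------------------------------------

    def theta(self, sigma_read: float = 0.0) -> np.ndarray:
        """Actor weight matrix (n_actions x n_cells), optionally noisy."""
        return self.actor.read(sigma_read).reshape(self.n_actions, -1)

    def w(self, sigma_read: float = 0.0) -> np.ndarray:
        """Critic weight vector, optionally noisy."""
        return self.critic.read(sigma_read)

    def preferences(self, x: np.ndarray, sigma_read: float = 0.0) -> np.ndarray:
        return action_preferences(self.theta(sigma_read), x)

    def state_value(self, x: np.ndarray, sigma_read: float = 0.0) -> float:
        return value(self.w(sigma_read), x)
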