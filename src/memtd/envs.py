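"""Navigation environments: the discrete T-maze and the continuous water maze.

The T-maze has nine states, 0-8: a stem 0-1-2-3-4, a junction at 4, a
left arm 4-5-6 with the reward in the left corner (state 6) and a right
arm 4-7-8.  Two actions are available everywhere: forward/backward along
the current corridor, reinterpreted as left/right at the junction.

The water maze is a unit-square arena with a hidden circular platform
(the reward) at the centre, surrounded by a U-shaped obstacle open at
the top so that the platform can only be approached from above.  The
agent moves by fixed-length steps in one of eight compass directions;
a move whose path would cross the arena boundary or an obstacle wall is
cancelled (the agent stays in place, the step still counts).

Geometry defaults are calibrated so that a uniform-random policy needs
about 450 steps on average to find the platform while the shortest
achievable mean path is about 6.5 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TMazeEnv",
    "WaterMazeEnv",
    "tmaze_step",
    "tmaze_shortest_path",
    "watermaze_step",
    "random_walk_baseline",
]


# ---------------------------------------------------------------------------
# T-maze
# ---------------------------------------------------------------------------

# action indices: 0 = forward (left at the junction), 1 = backward (right)
_FORWARD = {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6, 6: 6, 7: 8, 8: 8}
_BACKWARD = {0: 0, 1: 0, 2: 1, 3: 2, 4: 7, 5: 4, 6: 5, 7: 4, 8: 7}


@dataclass(frozen=True)
class TMazeEnv:
    """Nine-state T-maze with the reward in the left corner (state 6)."""

    n_states: int = 9
    n_actions: int = 2
    reward_state: int = 6
    start_state: int = 0
    max_steps: int = 1000

    def step(self, state: int, action: int):
        """Deterministic transition; dead-end moves leave the state unchanged."""
        if not 0 <= state < self.n_states:
            raise IndexError(f"state {state} out of range")
        if action not in (0, 1):
            raise IndexError(f"action {action} out of range")
        nxt = (_FORWARD if action == 0 else _BACKWARD)[state]
        terminal = nxt == self.reward_state
        return nxt, (1.0 if terminal else 0.0), terminal

    def shortest_path(self, start: int | None = None) -> int:
        """Breadth-first-search distance from start to the reward state."""
        start = self.start_state if start is None else start
        if start == self.reward_state:
            return 0
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt_frontier = []
            for s in frontier:
                for a in (0, 1):
                    t, _, _ = self.step(s, a)
                    if t not in dist:
                        dist[t] = dist[s] + 1
                        if t == self.reward_state:
                            return dist[t]
                        nxt_frontier.append(t)
            frontier = nxt_frontier
        raise RuntimeError("reward state unreachable")

    def transition_matrix(self) -> np.ndarray:
        """Uniform-random-policy transition matrix (reward state absorbing)."""
        P = np.zeros((self.n_states, self.n_states))
        for s in range(self.n_states):
            if s == self.reward_state:
                P[s, s] = 1.0
                continue
            for a in (0, 1):
                t, _, _ = self.step(s, a)
                P[s, t] += 0.5
        return P


def tmaze_step(env: TMazeEnv, state: int, action: int):
    """Functional alias for :meth:`TMazeEnv.step`."""
    return env.step(state, action)


def tmaze_shortest_path(env: TMazeEnv, start: int | None = None) -> int:
    """Functional alias for :meth:`TMazeEnv.shortest_path`."""
    return env.shortest_path(start)


# ---------------------------------------------------------------------------
# Water maze
# ---------------------------------------------------------------------------

def _orient(o, u, v) -> float:
    return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])


def _on_segment(a, b, p) -> bool:
    """p collinear with a-b: is p within the segment's bounding box?"""
    return (min(a[0], b[0]) <= p[0] <= max(a[0], b[0]) and
            min(a[1], b[1]) <= p[1] <= max(a[1], b[1]))


def _segments_intersect(p, q, a, b) -> bool:
    """True if closed segments p-q and a-b intersect (touching counts)."""
    d1 = _orient(a, b, p)
    d2 = _orient(a, b, q)
    d3 = _orient(p, q, a)
    d4 = _orient(p, q, b)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) \
            and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0:
        return True
    if d1 == 0 and _on_segment(a, b, p):
        return True
    if d2 == 0 and _on_segment(a, b, q):
        return True
    if d3 == 0 and _on_segment(p, q, a):
        return True
    if d4 == 0 and _on_segment(p, q, b):
        return True
    return False


@dataclass(frozen=True)
class WaterMazeEnv:
    """Unit-square arena, hidden platform, U-shaped obstacle open at the top."""

    platform_center: tuple = (0.5, 0.5)
    platform_radius: float = 0.09
    obstacle_x_left: float = 0.38
    obstacle_x_right: float = 0.62
    obstacle_y_bottom: float = 0.15
    obstacle_y_top: float = 0.72
    step_length: float = 0.12
    n_actions: int = 8
    start_exclusion: float = 0.35  # min start distance from the platform centre
    max_steps: int = 5000

    _dirs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        phi = np.arange(self.n_actions) * (2.0 * math.pi / self.n_actions)
        object.__setattr__(
            self, "_dirs",
            np.column_stack([np.cos(phi), np.sin(phi)]) * self.step_length,
        )

    @property
    def obstacle_segments(self):
        """The three wall segments of the U (left, right, bottom)."""
        xl, xr = self.obstacle_x_left, self.obstacle_x_right
        yb, yt = self.obstacle_y_bottom, self.obstacle_y_top
        return (
            ((xl, yb), (xl, yt)),
            ((xr, yb), (xr, yt)),
            ((xl, yb), (xr, yb)),
        )

    def blocked(self, pos, candidate) -> bool:
        """True if the move pos -> candidate leaves the arena or hits a wall."""
        x, y = candidate
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            return True
        for a, b in self.obstacle_segments:
            if _segments_intersect(pos, candidate, a, b):
                return True
        return False

    def step(self, pos, action: int):
        """Move one step in compass direction ``action`` (45-degree grid)."""
        if not 0 <= action < self.n_actions:
            raise IndexError(f"action {action} out of range")
        dx, dy = self._dirs[action]
        candidate = (pos[0] + dx, pos[1] + dy)
        nxt = pos if self.blocked(pos, candidate) else candidate
        cx, cy = self.platform_center
        terminal = (nxt[0] - cx) ** 2 + (nxt[1] - cy) ** 2 <= self.platform_radius**2
        return nxt, (1.0 if terminal else 0.0), terminal

    def sample_start(self, rng: np.random.Generator):
        """Uniform start in free space outside the platform exclusion disc."""
        cx, cy = self.platform_center
        while True:
            x, y = rng.uniform(0.0, 1.0, 2)
            if (x - cx) ** 2 + (y - cy) ** 2 >= self.start_exclusion**2:
                return (float(x), float(y))


def watermaze_step(env: WaterMazeEnv, pos, action: int):
    """Functional alias for :meth:`WaterMazeEnv.step`."""
    return env.step(pos, action)


# ---------------------------------------------------------------------------
# Random-walk baseline
# ---------------------------------------------------------------------------

def random_walk_baseline(env, n_episodes: int, seed: int,
                         max_steps: int | None = None):
    """Mean and SD of steps-to-reward under uniformly random actions.

    Works for both environments; episodes that hit the step cap
    contribute the cap (and are counted in the returned ``truncated``).
    """
    rng = np.random.default_rng(seed)
    cap = env.max_steps if max_steps is None else max_steps
    steps = np.empty(n_episodes)
    truncated = 0
    is_tmaze = isinstance(env, TMazeEnv)
    for ep in range(n_episodes):
        if is_tmaze:
            state = env.start_state
            terminal = state == env.reward_state
        else:
            state = env.sample_start(rng)
            cx, cy = env.platform_center
            terminal = ((state[0] - cx) ** 2 + (state[1] - cy) ** 2
                        <= env.platform_radius**2)
        n = 0
        while n < cap and not terminal:
            a = int(rng.integers(env.n_actions))
            state, _, terminal = env.step(state, a)
            n += 1
        if not terminal:
            truncated += 1
        steps[ep] = n
    return {
        "mean": float(steps.mean()),
        "sd": float(steps.std(ddof=1)) if n_episodes > 1 else 0.0,
        "steps": steps,
        "truncated": truncated,
    }
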