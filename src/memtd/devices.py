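"""Emulation of analogue memristor synapses.

A memristive device stores one normalized synaptic weight in [0, 1]
(a min-max mapping of its conductance range) and is programmed only by
trains of identical voltage pulses: positive pulses potentiate (increase
conductance), negative pulses depress.  The emulation reduces a device to

* a mean potentiation curve w(p) and a mean depression curve, giving the
  weight reached after p pulses from the respective end of the range;
* an update-noise level ``sigma_update`` (stochastic deviation of a
  realized update from the mean curve, the epsilon_2 error);
* a cycle-to-cycle offset level ``sigma_cycle`` (run-to-run variability
  between repeated ramps of the same device).

Mean curves are either parametric saturating exponentials with a single
nonlinearity parameter ``nu`` per direction,

    w_pot(p) = (1 - exp(-nu * p / N)) / (1 - exp(-nu)),

(depression is the mirror image, w_dep(p) = 1 - w_pot(p) with its own
``nu``) or tabulated means extracted from measured pulse-train cycles
loaded via :func:`load_cycles_csv`.  The nonlinear deviation from the
linear expectation dw = dp / N is the epsilon_1 error of pulse-based
programming.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DeviceCurve",
    "MemristorSynapse",
    "SynapseArray",
    "IdealWeights",
    "DeviceBank",
    "generate_synthetic_curve",
    "generate_synthetic_bank",
    "load_cycles_csv",
    "apply_pulses",
    "read_weight",
]

_NU_LINEAR_EPS = 1e-9  # below this the parametric curve is treated as linear


class DeviceError(ValueError):
    """Invalid device parameter or malformed cycle data."""


# ---------------------------------------------------------------------------
# Device curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceCurve:
    """Mean potentiation/depression curves plus noise levels for one device.

    Parameters
    ----------
    n_pulses
        Total pulse count N spanning the full conductance range.
    nu_pot, nu_dep
        Nonlinearity of the parametric potentiation/depression curves
        (0 = linear).  Ignored when tabulated curves are given.
    sigma_update
        SD of the per-update weight noise, normalized weight units.
    sigma_cycle
        SD of the cycle-to-cycle curve offset, normalized weight units.
    pot_table, dep_table
        Optional tabulated mean weights at pulse positions 0..N
        (length N + 1); when present they override the parametric form.
    """

    n_pulses: int
    nu_pot: float = 0.0
    nu_dep: float = 0.0
    sigma_update: float = 0.0
    sigma_cycle: float = 0.0
    pot_table: np.ndarray | None = None
    dep_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise DeviceError(f"n_pulses must be >= 1, got {self.n_pulses}")
        for name in ("nu_pot", "nu_dep", "sigma_update", "sigma_cycle"):
            if getattr(self, name) < 0:
                raise DeviceError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("pot_table", "dep_table"):
            tab = getattr(self, name)
            if tab is not None:
                tab = np.asarray(tab, dtype=float)
                if tab.shape != (self.n_pulses + 1,):
                    raise DeviceError(
                        f"{name} must have length n_pulses + 1 = {self.n_pulses + 1}"
                    )
                object.__setattr__(self, name, tab)

    # -- mean curves (p is a continuous pulse position in [0, N]) ----------

    def pot(self, p):
        """Mean weight after ``p`` potentiation pulses from weight 0."""
        p = np.clip(p, 0.0, self.n_pulses)
        if self.pot_table is not None:
            return np.interp(p, np.arange(self.n_pulses + 1), self.pot_table)
        return _sat_exp(p / self.n_pulses, self.nu_pot)

    def dep(self, p):
        """Mean weight after ``p`` depression pulses from weight 1."""
        p = np.clip(p, 0.0, self.n_pulses)
        if self.dep_table is not None:
            return np.interp(p, np.arange(self.n_pulses + 1), self.dep_table)
        return 1.0 - _sat_exp(p / self.n_pulses, self.nu_dep)

    def pot_inv(self, w):
        """Pulse position on the potentiation curve holding weight ``w``."""
        w = np.clip(w, 0.0, 1.0)
        if self.pot_table is not None:
            return _interp_inverse(w, self.pot_table, increasing=True)
        return self.n_pulses * _sat_exp_inv(w, self.nu_pot)

    def dep_inv(self, w):
        """Pulse position on the depression curve holding weight ``w``."""
        w = np.clip(w, 0.0, 1.0)
        if self.dep_table is not None:
            return _interp_inverse(w, self.dep_table, increasing=False)
        return self.n_pulses * _sat_exp_inv(1.0 - w, self.nu_dep)

    @property
    def is_linear(self) -> bool:
        """Both mean curves are exactly linear (additive pulse response)."""
        return (self.pot_table is None and self.dep_table is None
                and self.nu_pot < _NU_LINEAR_EPS and self.nu_dep < _NU_LINEAR_EPS)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_pulses": self.n_pulses,
            "nu_pot": self.nu_pot,
            "nu_dep": self.nu_dep,
            "sigma_update": self.sigma_update,
            "sigma_cycle": self.sigma_cycle,
        }
        if self.pot_table is not None:
            d["pot_table"] = self.pot_table.tolist()
        if self.dep_table is not None:
            d["dep_table"] = self.dep_table.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceCurve":
        kw = dict(d)
        for name in ("pot_table", "dep_table"):
            if kw.get(name) is not None:
                kw[name] = np.asarray(kw[name], dtype=float)
        return cls(**kw)


def _sat_exp(u, nu):
    """Normalized saturating exponential on u in [0, 1]; linear as nu -> 0."""
    if nu < _NU_LINEAR_EPS:
        return np.asarray(u, dtype=float) if np.ndim(u) else float(u)
    return (1.0 - np.exp(-nu * np.asarray(u, dtype=float))) / (1.0 - math.exp(-nu))

def _sat_exp_inv(w, nu):
    if nu < _NU_LINEAR_EPS:
        return np.asarray(w, dtype=float) if np.ndim(w) else float(w)
    arg = 1.0 - np.asarray(w, dtype=float) * (1.0 - math.exp(-nu))
    return -np.log(np.maximum(arg, 1e-300)) / nu

def _interp_inverse(w, table, increasing):
    # tables may have flat spots; strictify for a well-defined inverse
    t = table if increasing else table[::-1]
    t = np.maximum.accumulate(t)
    p = np.interp(w, t, np.arange(t.size, dtype=float))
    return p if increasing else (t.size - 1) - p


def generate_synthetic_curve(
    nu_pot: float,
    nu_dep: float,
    n_pulses: int = 200,
    sigma_update: float = 0.0,
    sigma_cycle: float = 0.0,
) -> DeviceCurve:
    """Build a parametric saturating-exponential device curve.

    Stands in for measured pulse-train cycles; nonlinearity is one
    tunable parameter per ramp direction so linearity sweeps reduce to a
    scalar sweep.
    """
    return DeviceCurve(
        n_pulses=n_pulses,
        nu_pot=nu_pot,
        nu_dep=nu_dep,
        sigma_update=sigma_update,
        sigma_cycle=sigma_cycle,
    )


# ---------------------------------------------------------------------------
# Stateful synapses
# ---------------------------------------------------------------------------

@dataclass
class MemristorSynapse:
    """One emulated device holding one network weight in [0, 1].

    The weight changes only through :meth:`apply_pulses`; reads may add
    noise but never mutate state.
    """

    curve: DeviceCurve
    weight: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    noise_mode: str = "per_pulse_sqrt"  # or "per_update"

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise DeviceError(f"weight must be in [0, 1], got {self.weight}")
        if self.noise_mode not in ("per_pulse_sqrt", "per_update"):
            raise DeviceError(f"unknown noise_mode {self.noise_mode!r}")

    def apply_pulses(self, delta_p: int) -> "MemristorSynapse":
        """Advance the weight by ``delta_p`` pulses along the mean curve.

        Positive counts potentiate, negative depress.  The realized
        change generally differs from ``delta_p / N``: the traversal of
        the nonlinear mean curve realizes the epsilon_1 error and the
        added Gaussian noise the epsilon_2 error.  The weight is clipped
        to the device's conductance bounds (saturation).
        """
        delta_p = int(delta_p)
        if delta_p == 0:
            return self
        c = self.curve
        n = abs(delta_p)
        if c.is_linear:
            # additive response; keeps linear devices bit-exact with the
            # linear-expected update dp / N
            w = self.weight + delta_p / c.n_pulses
        elif delta_p > 0:
            p = c.pot_inv(self.weight)
            w = float(c.pot(min(p + n, c.n_pulses)))
        else:
            p = c.dep_inv(self.weight)
            w = float(c.dep(min(p + n, c.n_pulses)))
        scale = math.sqrt(n) if self.noise_mode == "per_pulse_sqrt" else 1.0
        if c.sigma_update > 0:
            w += self.rng.normal(0.0, c.sigma_update * scale)
        if c.sigma_cycle > 0:
            w += self.rng.normal(0.0, c.sigma_cycle)
        self.weight = min(max(w, 0.0), 1.0)
        return self

    def read(self, sigma_read: float = 0.0) -> float:
        """Noisy, non-mutating read of the stored weight, clipped to [0, 1]."""
        if sigma_read < 0:
            raise DeviceError(f"sigma_read must be >= 0, got {sigma_read}")
        if sigma_read == 0:
            return self.weight
        return min(max(self.weight + self.rng.normal(0.0, sigma_read), 0.0), 1.0)


def apply_pulses(syn: MemristorSynapse, delta_p: int) -> MemristorSynapse:
    """Functional alias for :meth:`MemristorSynapse.apply_pulses`."""
    return syn.apply_pulses(delta_p)


def read_weight(syn: MemristorSynapse, sigma_read: float = 0.0) -> float:
    """Functional alias for :meth:`MemristorSynapse.read`."""
    return syn.read(sigma_read)


class SynapseArray:
    """Vector of emulated memristor synapses sharing one RNG stream.

    Semantically equivalent to a list of :class:`MemristorSynapse`, but
    updates are applied with vectorized curve evaluations grouped by
    device profile, which keeps large networks (hundreds of weights per
    step) fast.
    """

    quantized = True  # updates arrive as integer pulse counts

    def __init__(self, curves, assignment, rng, noise_mode="per_pulse_sqrt"):
        self.curves = list(curves)
        self.assignment = np.asarray(assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise DeviceError("assignment must be 1-D")
        if np.any(self.assignment < 0) or np.any(self.assignment >= len(self.curves)):
            raise DeviceError("assignment index out of range")
        self.n = self.assignment.size
        self.weights = np.zeros(self.n)
        self.rng = rng
        if noise_mode not in ("per_pulse_sqrt", "per_update"):
            raise DeviceError(f"unknown noise_mode {noise_mode!r}")
        self.noise_mode = noise_mode
        self._groups = [np.flatnonzero(self.assignment == k)
                        for k in range(len(self.curves))]

    def read(self, sigma_read: float = 0.0) -> np.ndarray:
        if sigma_read < 0:
            raise DeviceError(f"sigma_read must be >= 0, got {sigma_read}")
        if sigma_read == 0:
            return self.weights.copy()
        return np.clip(self.weights + self.rng.normal(0.0, sigma_read, self.n), 0.0, 1.0)

    def apply_pulses(self, delta_p: np.ndarray) -> np.ndarray:
        """Apply per-synapse signed pulse counts; returns realized changes."""
        delta_p = np.asarray(delta_p, dtype=int)
        before = self.weights.copy()
        active = np.flatnonzero(delta_p != 0)
        for k in np.unique(self.assignment[active]):
            idx = active[self.assignment[active] == k]
            c = self.curves[k]
            dp = delta_p[idx]
            w0 = self.weights[idx]
            if c.is_linear:
                w = w0 + dp / c.n_pulses
            else:
                w = np.empty_like(w0)
                pot = dp > 0
                if np.any(pot):
                    p = c.pot_inv(w0[pot])
                    w[pot] = c.pot(np.minimum(p + dp[pot], c.n_pulses))
                if np.any(~pot):
                    p = c.dep_inv(w0[~pot])
                    w[~pot] = c.dep(np.minimum(p - dp[~pot], c.n_pulses))
            n = np.abs(dp)
            scale = np.sqrt(n) if self.noise_mode == "per_pulse_sqrt" else 1.0
            if c.sigma_update > 0:
                w = w + self.rng.normal(0.0, 1.0, idx.size) * (c.sigma_update * scale)
            if c.sigma_cycle > 0:
                w = w + self.rng.normal(0.0, c.sigma_cycle, idx.size)
            self.weights[idx] = np.clip(w, 0.0, 1.0)
        return self.weights - before


class IdealWeights:
    """Continuous, noiseless ideal synapses (the software reference).

    Updates are applied exactly as desired, with no pulse quantization
    and no noise: this is the idealized learner that device-backed runs
    are compared against.  By default weights remain bounded to the
    normalized conductance range [0, 1] like any analogue synapse;
    ``clip=False`` gives unbounded tabular weights.
    """

    quantized = False

    def __init__(self, n: int, clip: bool = True):
        self.n = int(n)
        self.clip = bool(clip)
        self.weights = np.zeros(self.n)

    def read(self, sigma_read: float = 0.0) -> np.ndarray:
        return self.weights.copy()

    def apply_dw(self, dw: np.ndarray) -> np.ndarray:
        before = self.weights
        w = before + np.asarray(dw, dtype=float)
        self.weights = np.clip(w, 0.0, 1.0) if self.clip else w
        return self.weights - before


# ---------------------------------------------------------------------------
# Device banks
# ---------------------------------------------------------------------------

@dataclass
class DeviceBank:
    """An ordered collection of device profiles plus a weight assignment.

    Every network weight maps to exactly one curve; curves may be reused
    when the network is larger than the bank.
    """

    curves: list
    assignment: np.ndarray | None = None
    bank_seed: int | None = None

    def assign(self, n_weights: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Assignment of ``n_weights`` weights to curves.

        With as many (or more) curves than weights the assignment is the
        identity on the first ``n_weights`` curves (each weight its own
        device); otherwise curves are drawn uniformly at random, which
        is how device-to-device variability is carried into networks
        larger than the measured bank.
        """
        if n_weights <= len(self.curves):
            return np.arange(n_weights)
        if rng is None:
            raise DeviceError("random assignment of reused curves needs an rng")
        return rng.integers(0, len(self.curves), size=n_weights)

    def make_array(self, n_weights, rng, noise_mode="per_pulse_sqrt") -> SynapseArray:
        assignment = self.assignment
        if assignment is None or len(assignment) != n_weights:
            assignment = self.assign(n_weights, rng)
        return SynapseArray(self.curves, assignment, rng, noise_mode=noise_mode)

    def with_sigma_update(self, sigma: float) -> "DeviceBank":
        """Bank with every device's update noise overridden to ``sigma``."""
        return DeviceBank(
            [replace(c, sigma_update=sigma) for c in self.curves],
            assignment=self.assignment,
            bank_seed=self.bank_seed,
        )

    @property
    def min_sigma_update(self) -> float:
        return min(c.sigma_update for c in self.curves)

    def to_json(self, path) -> None:
        payload = {
            "bank_seed": self.bank_seed,
            "curves": [c.to_dict() for c in self.curves],
            "assignment": None if self.assignment is None else np.asarray(self.assignment).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DeviceBank":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            curves=[DeviceCurve.from_dict(d) for d in payload["curves"]],
            assignment=None if payload["assignment"] is None else np.asarray(payload["assignment"]),
            bank_seed=payload["bank_seed"],
        )


def generate_synthetic_bank(
    n_devices: int = 27,
    bank_seed: int = 0,
    n_pulses: int = 200,
    nu_range: tuple = (1.0, 4.0),
    sigma_update_range: tuple = (0.005, 0.03),
    sigma_cycle: float = 0.0,
) -> DeviceBank:
    """Synthetic bank of device profiles spanning near-linear to visibly
    nonlinear update behaviour with device-to-device noise spread."""
    rng = np.random.default_rng(bank_seed)
    curves = [
        generate_synthetic_curve(
            nu_pot=rng.uniform(*nu_range),
            nu_dep=rng.uniform(*nu_range),
            n_pulses=n_pulses,
            sigma_update=rng.uniform(*sigma_update_range),
            sigma_cycle=sigma_cycle,
        )
        for _ in range(n_devices)
    ]
    return DeviceBank(curves, bank_seed=bank_seed)


# ---------------------------------------------------------------------------
# Measured-cycle CSV loading
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("device_id", "cycle_id", "direction", "pulse_index", "weight")


def load_cycles_csv(path) -> DeviceBank:
    """Build a bank of tabulated device profiles from measured pulse cycles.

    The CSV must have columns (device_id, cycle_id, direction in
    {pot, dep}, pulse_index, weight).  Per device the mean curve over
    cycles is renormalized to span [0, 1] and ``sigma_update`` is the SD
    of the pooled pointwise deviations of all cycles from their mean
    (both ramp directions pooled), on the renormalized scale.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DeviceError(f"cycle CSV missing columns: {missing}")
    bad = df[(df["weight"] < -0.1) | (df["weight"] > 1.1)]
    if len(bad):
        raise DeviceError(f"weight outside [-0.1, 1.1] at row {bad.index[0]}")
    bad = df[~df["direction"].isin(["pot", "dep"])]
    if len(bad):
        raise DeviceError(f"direction must be 'pot' or 'dep' at row {bad.index[0]}")

    curves = []
    for dev, ddf in df.groupby("device_id", sort=True):
        tables = {}
        deviations = []
        for direction, sdf in ddf.groupby("direction"):
            cycles = []
            for _, cdf in sdf.groupby("cycle_id"):
                pi = cdf["pulse_index"].to_numpy()
                if np.any(np.diff(pi) <= 0):
                    row = cdf.index[np.flatnonzero(np.diff(pi) <= 0)[0] + 1]
                    raise DeviceError(
                        f"non-monotone pulse_index within a cycle at row {row}"
                    )
                cycles.append(cdf.sort_values("pulse_index")["weight"].to_numpy())
            lengths = {len(c) for c in cycles}
            if len(lengths) != 1:
                raise DeviceError(
                    f"device {dev} {direction}: cycles have unequal pulse grids"
                )
            mat = np.vstack(cycles)
            mean = mat.mean(axis=0)
            span = mean.max() - mean.min()
            if span <= 0:
                raise DeviceError(f"device {dev} {direction}: flat mean curve")
            tables[direction] = (mean - mean.min()) / span
            deviations.append(((mat - mean) / span).ravel())
        if set(tables) != {"pot", "dep"}:
            raise DeviceError(f"device {dev}: need both pot and dep cycles")
        n_pulses = tables["pot"].size - 1
        if tables["dep"].size - 1 != n_pulses:
            raise DeviceError(f"device {dev}: pot/dep pulse grids differ")
        sigma = float(np.std(np.concatenate(deviations)))
        curves.append(
            DeviceCurve(
                n_pulses=n_pulses,
                sigma_update=sigma,
                pot_table=tables["pot"],
                dep_table=tables["dep"],
            )
        )
    return DeviceBank(curves)
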