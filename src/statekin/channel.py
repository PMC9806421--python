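"""Continuous-time Markov model of voltage-gated sodium channel (VGSC) gating
with state-dependent binding of a diffusible inhibitor.

The gating scheme is the minimal loop

    R <-> O -> FI <-> SI        with an FI -> R recovery path,

where R is the resting (closed, available) state, O the open state, FI the
fast-inactivated state and SI the slow-inactivated state.  Each unbound state
S additionally binds the inhibitor X with a state-specific association rate
``k_S * x`` into a non-conducting bound mirror state (B_R, B_FI, B_SI; the
open state binds into B_R at ``k_O``), and every bound state unbinds back to
its gating partner at a single voltage-independent rate ``k_off``.  Bound
channels do not interconvert between gating conformations.

Voltage dependence of each gating transition is a capped exponential
``base * exp((V - v_half) / efold_mV)``; all rate constants are in 1/s,
voltages in mV, times in s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.linalg import expm, null_space
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GATING_STATES",
    "BOUND_STATES",
    "ALL_STATES",
    "RateSpec",
    "ChannelModel",
    "InhibitorSchedule",
    "StateDistribution",
    "ConfigurationError",
    "build_rate_matrix",
    "steady_state",
    "propagate",
    "default_model",
]

#: Unbound gating states, in matrix order.
GATING_STATES: tuple[str, ...] = ("R", "O", "FI", "SI")
#: Bound (non-conducting) mirror states.  The open state binds into B_R.
BOUND_STATES: tuple[str, ...] = ("B_R", "B_FI", "B_SI")
ALL_STATES: tuple[str, ...] = GATING_STATES + BOUND_STATES

#: Which bound state each unbound state binds into.
_BIND_TARGET = {"R": "B_R", "O": "B_R", "FI": "B_FI", "SI": "B_SI"}
#: Which unbound state each bound state unbinds back to.
_UNBIND_TARGET = {"B_R": "R", "B_FI": "FI", "B_SI": "SI"}

_IDX = {s: i for i, s in enumerate(ALL_STATES)}


class ConfigurationError(ValueError):
    """Raised for structurally invalid models, schedules or protocols."""


@dataclass(frozen=True)
class RateSpec:
    """One voltage-dependent transition rate.

    rate(V) = min(base * exp((V - v_half) / efold_mV), cap)

    ``efold_mV`` may be None for a voltage-independent rate.  A positive
    e-fold constant gives a rate that grows with depolarization, a negative
    one a rate that grows with hyperpolarization.
    """

    base: float
    efold_mV: float | None = None
    v_half: float = 0.0
    cap: float = 2.0e4

    def __post_init__(self) -> None:
        if self.base < 0:
            raise ConfigurationError(f"negative base rate {self.base}")

    def __call__(self, V: float) -> float:
        if not math.isfinite(V):
            raise ValueError(f"non-finite voltage {V}")
        if self.efold_mV is None:
            return min(self.base, self.cap)
        arg = (V - self.v_half) / self.efold_mV
        # exp cap keeps rates finite over the physiological command range
        return min(self.base * math.exp(min(arg, 60.0)), self.cap)


@dataclass(frozen=True)
class ChannelModel:
    """Gating topology, voltage-dependent rates, and inhibitor binding.

    Parameters
    ----------
    rates
        Map of (from_state, to_state) -> RateSpec over the gating transitions
        R->O, O->R, O->FI, FI->R, FI->SI, SI->FI.
    k_assoc
        Association rate constant per unbound state (1/s per unit inhibitor);
        keys must be exactly {R, O, FI, SI}.
    k_off
        Voltage-independent unbinding rate (1/s) from every bound state.
    """

    rates: Mapping[tuple[str, str], RateSpec]
    k_assoc: Mapping[str, float] = field(
        default_factory=lambda: {"R": 1.0, "O": 1.0, "FI": 10.0, "SI": 2.0}
    )
    k_off: float = 1.0

    def __post_init__(self) -> None:
        expected = set(GATING_STATES)
        if set(self.k_assoc) != expected:
            raise ConfigurationError(
                f"k_assoc keys {sorted(self.k_assoc)} != expected {sorted(expected)}"
            )
        if any(v < 0 for v in self.k_assoc.values()) or self.k_off < 0:
            raise ConfigurationError("association/unbinding rates must be >= 0")
        for (src, dst) in self.rates:
            if src not in GATING_STATES or dst not in GATING_STATES:
                raise ConfigurationError(f"unknown state in transition {src}->{dst}")

    def with_binding(
        self, k_R: float, k_FI: float, k_SI: float, k_O: float | None = None,
        k_off: float | None = None,
    ) -> "ChannelModel":
        """Return a copy with new association constants (k_O defaults to k_R)."""
        k_assoc = {"R": k_R, "O": k_R if k_O is None else k_O,
                   "FI": k_FI, "SI": k_SI}
        return replace(self, k_assoc=k_assoc,
                       k_off=self.k_off if k_off is None else k_off)


@dataclass(frozen=True)
class InhibitorSchedule:
    """Time course of the lumped inhibitor concentration x(t) = [X]*C.

    ``shape``:
      - "zero": x(t) = 0 always (control).
      - "step": x jumps to ``plateau`` at ``onset_time``.
      - "ramp": x rises linearly at ``ramp_rate`` from ``onset_time`` until it
        reaches ``plateau`` (the mechanism that yields a squared-exponential
        onset of inhibition: a hazard growing linearly in time integrates to
        exp(-(t/tau)^2)).
    """

    shape: str = "zero"
    onset_time: float = 0.0
    ramp_rate: float = 0.0
    plateau: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("zero", "step", "ramp"):
            raise ConfigurationError(f"unknown schedule shape {self.shape!r}")
        if self.plateau < 0 or self.ramp_rate < 0:
            raise ConfigurationError("schedule must be non-negative")

    def concentration(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "zero":
            out = np.zeros_like(t)
        elif self.shape == "step":
            out = np.where(t >= self.onset_time, self.plateau, 0.0)
        else:
            out = np.clip(self.ramp_rate * (t - self.onset_time), 0.0, self.plateau)
        return float(out) if out.ndim == 0 else out

    def is_constant_over(self, t0: float, t1: float) -> bool:
        if self.shape == "zero":
            return True
        if t1 <= self.onset_time:
            return True
        if self.shape == "step":
            return t0 >= self.onset_time
        # ramp: constant only once the plateau has been reached
        if self.ramp_rate == 0.0:
            return True
        t_plateau = self.onset_time + self.plateau / self.ramp_rate
        return t0 >= t_plateau


ZERO_SCHEDULE = InhibitorSchedule(shape="zero")


@dataclass(frozen=True)
class StateDistribution:
    """Occupancy probability per state (over all 7 states)."""

    occupancy: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array([self.occupancy.get(s, 0.0) for s in ALL_STATES])
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {vals.sum()}, not 1")

    @classmethod
    def from_vector(cls, p: np.ndarray) -> "StateDistribution":
        p = np.clip(np.asarray(p, dtype=float), 0.0, None)
        p = p / p.sum()
        return cls(dict(zip(ALL_STATES, p)))

    @classmethod
    def pure(cls, state: str) -> "StateDistribution":
        if state not in ALL_STATES:
            raise ConfigurationError(f"unknown state {state!r}")
        return cls({s: 1.0 if s == state else 0.0 for s in ALL_STATES})

    def vector(self) -> np.ndarray:
        return np.array([self.occupancy.get(s, 0.0) for s in ALL_STATES])

    def __getitem__(self, state: str) -> float:
        return float(self.occupancy.get(state, 0.0))

    @property
    def bound_fraction(self) -> float:
        return float(sum(self.occupancy.get(s, 0.0) for s in BOUND_STATES))

    @property
    def availability(self) -> float:
        """Occupancy of the unbound resting-side states (R plus the open
        state, which re-equilibrates with R within milliseconds)."""
        return self["R"] + self["O"]


def build_rate_matrix(model: ChannelModel, V: float, x: float = 0.0) -> np.ndarray:
    """Infinitesimal generator Q over (R, O, FI, SI, B_R, B_FI, B_SI).

    Q[i, j] (i != j) is the transition rate from state i to state j at
    command voltage ``V`` (mV) and inhibitor concentration ``x``; rows sum
    to zero.
    """
    if not math.isfinite(V):
        raise ValueError(f"non-finite voltage {V}")
    if x < 0:
        raise ValueError(f"negative inhibitor concentration {x}")
    n = len(ALL_STATES)
    Q = np.zeros((n, n))
    for (src, dst), spec in model.rates.items():
        Q[_IDX[src], _IDX[dst]] += spec(V)
    for s in GATING_STATES:
        Q[_IDX[s], _IDX[_BIND_TARGET[s]]] += model.k_assoc[s] * x
    for b, s in _UNBIND_TARGET.items():
        Q[_IDX[b], _IDX[s]] += model.k_off
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # one compensation pass so re-summed rows vanish to rounding level
    np.fill_diagonal(Q, np.diag(Q) - Q.sum(axis=1))
    if not np.all(np.isfinite(Q)):
        raise FloatingPointError(f"non-finite rates in generator at V={V} mV")
    return Q


def _closed_classes(Q: np.ndarray) -> list[list[str]]:
    """Strongly-connected components with no outgoing edges (closed classes)."""
    adj = (Q > 0).astype(int)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        outside = np.setdiff1d(np.arange(Q.shape[0]), members)
        if not np.any(Q[np.ix_(members, outside)] > 0):
            closed.append([ALL_STATES[i] for i in members])
    return closed


def steady_state(model: ChannelModel, V: float, x: float = 0.0) -> StateDistribution:
    """Stationary distribution: the null vector of Q^T, normalized to sum 1.

    Raises
    ------
    ValueError
        If the chain has more than one closed communicating class (the
        stationary distribution is then not unique); the error names the
        closed classes.
    """
    Q = build_rate_matrix(model, V, x)
    closed = _closed_classes(Q)
    if len(closed) > 1:
        raise ValueError(
            "reducible chain with multiple closed classes: "
            + "; ".join("{" + ",".join(c) + "}" for c in closed)
        )
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        # fall back to the eigenvector of the smallest-magnitude eigenvalue
        w, v = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        vec = np.real(v[:, i])
    else:
        vec = ns[:, 0]
    vec = np.abs(vec)
    return StateDistribution.from_vector(vec)


def propagate(
    model: ChannelModel,
    start: StateDistribution,
    V: float,
    schedule: InhibitorSchedule = ZERO_SCHEDULE,
    duration: float = 0.0,
    dt: float = 1e-3,
    t0: float = 0.0,
    stride: int = 1,
) -> tuple[np.ndarray, list[StateDistribution]]:
    """Propagate a state distribution at fixed voltage under a schedule.

    The interval is cut into steps of at most ``dt``; over each step the
    inhibitor concentration is frozen at the step midpoint and the exact
    matrix exponential of the generator is applied.  When the schedule is
    constant over the whole interval and no intermediate samples are
    requested, a single matrix exponential covers the interval (identical
    result, since the generator commutes with itself).

    Returns (times, distributions) sampled every ``stride`` steps, always
    including the initial and final time.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0.0:
        return np.array([t0]), [start]
    if duration < dt:
        dt = duration

    p = start.vector()
    # fast path: constant x, endpoints only
    if stride <= 0 or (schedule.is_constant_over(t0, t0 + duration) and stride >= 1):
        n_steps = max(int(round(duration / dt)), 1)
        if schedule.is_constant_over(t0, t0 + duration):
            x = float(schedule.concentration(t0 + duration / 2))
            Q = build_rate_matrix(model, V, x)
            if stride >= n_steps or stride <= 0:
                p_end = p @ expm(Q * duration)
                return (np.array([t0, t0 + duration]),
                        [start, StateDistribution.from_vector(p_end)])
            T = expm(Q * (duration / n_steps))
            times, out = [t0], [start]
            for k in range(1, n_steps + 1):
                p = p @ T
                if k % stride == 0 or k == n_steps:
                    times.append(t0 + k * duration / n_steps)
                    out.append(StateDistribution.from_vector(p))
            return np.asarray(times), out

    n_steps = max(int(math.ceil(duration / dt)), 1)
    stride = stride if stride >= 1 else n_steps  # endpoints only
    h = duration / n_steps
    times, out = [t0], [start]
    cache: dict[float, np.ndarray] = {}
    for k in range(n_steps):
        t_mid = t0 + (k + 0.5) * h
        x = float(schedule.concentration(t_mid))
        key = round(x, 12)
        T = cache.get(key)
        if T is None:
            T = expm(build_rate_matrix(model, V, x) * h)
            if len(cache) < 64:
                cache[key] = T
        p = p @ T
        if (k + 1) % stride == 0 or k == n_steps - 1:
            times.append(t0 + (k + 1) * h)
            out.append(StateDistribution.from_vector(p))
    return np.asarray(times), out


def _rates_from_dict(d: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, str], RateSpec]:
    rates = {}
    for key, spec in d.items():
        src, dst = key.split("->")
        rates[(src.strip(), dst.strip())] = RateSpec(
            base=float(spec["base"]),
            efold_mV=None if spec.get("efold_mV") is None else float(spec["efold_mV"]),
            v_half=float(spec.get("v_half", 0.0)),
            cap=float(spec.get("cap", 2.0e4)),
        )
    return rates


def model_from_config(cfg: Mapping) -> ChannelModel:
    """Build a ChannelModel from a JSON-style config dict."""
    return ChannelModel(
        rates=_rates_from_dict(cfg["rates"]),
        k_assoc=dict(cfg.get("k_assoc", {"R": 1.0, "O": 1.0, "FI": 10.0, "SI": 2.0})),
        k_off=float(cfg.get("k_off", 1.0)),
    )


def default_model(**overrides) -> ChannelModel:
    """The package's default calibrated channel model.

    Calibration constants live in ``data/default_model.json``; the defaults
    place the fast-inactivation availability midpoint near -58 mV (100 ms
    conditioning) and the slow-inactivation midpoint near -59 mV (5 s
    conditioning), with millisecond repriming and ~1 s slow recovery at
    -120 mV.  Keyword overrides are applied on top (see
    :meth:`ChannelModel.with_binding` for the binding constants).
    """
    with resources.files("statekin.data").joinpath("default_model.json").open() as fh:
        cfg = json.load(fh)
    model = model_from_config(cfg)
    if overrides:
        model = replace(model, **overrides)
    return model
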