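"""Discrete-time hierarchical dynamical systems.

A network is a stack of ``n_levels`` identical levels, each holding one
*observable* unit ``x`` (its activity is what virtual sensors can see) and
one *hidden* unit ``y``.  Units are wired by *connection types* that apply
identically at every level: a connection is described by the role of its
source unit, the role of its target unit, and a level offset (0 = recurrent
within a level, +1 = feedforward to the level above, -1 = feedback to the
level below).  With two roles on each end and three offsets there are
exactly 12 possible connection types.

All units update synchronously::

    z(t+1) = f_z( sum_u  w(z, u) * u(t) )

where the sum runs over the incoming connections of ``z`` and ``f_z`` is a
monotone activation (identity, relu, saturating relu, or saturating
linear).  An external step input drives the network as if it were a
virtual level 0 feeding level 1 through the network's feedforward
connection weights; by default the input stands in for both the ``x`` and
``y`` unit of that virtual level (``input_roles="xy"``).  Feedforward out
of the top level and feedback out of level 1 address units that do not
exist and are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "CONNECTION_SLOTS",
    "SLOT_INDEX",
    "STABILITY_LIMIT",
    "apply_activation",
    "activation_function",
    "ConnectionSpec",
    "NetworkSpec",
    "StepInput",
    "SimulationTrace",
    "step_state",
    "simulate",
]

ACTIVATIONS = ("linear", "relu", "satrelu", "satlin")

ROLE_INDEX = {"x": 0, "y": 1}

#: The 12 possible connection types, as (source_role, target_role, level_offset).
#: Order: recurrent, feedforward, feedback; within each offset, sources x then
#: y, targets x then y.  This ordering fixes the meaning of 12-vector weight
#: and sign representations throughout the package.
CONNECTION_SLOTS: tuple[tuple[str, str, int], ...] = tuple(
    (src, dst, off) for off in (0, 1, -1) for src in "xy" for dst in "xy"
)

SLOT_INDEX = {slot: j for j, slot in enumerate(CONNECTION_SLOTS)}

#: Any sample whose magnitude exceeds this (or is non-finite) marks a
#: simulation as unstable; unstable models are rejected downstream.
STABILITY_LIMIT = 1.0e6


def apply_activation(kind: str, value):
    """Apply one of the four monotone activation functions.

    linear: f(z) = z; relu: f(z) = max(z, 0); satrelu: f(z) = min(max(z, 0), 1);
    satlin: f(z) = min(max(z, -1), 1).
    """
    return activation_function(kind)(np.asarray(value, dtype=float))


def activation_function(kind: str) -> Callable[[np.ndarray], np.ndarray]:
    """Return the vectorized activation map for ``kind``."""
    try:
        return _ACTIVATION_FNS[kind]
    except KeyError:
        raise ValueError(
            f"unknown activation kind {kind!r}; expected one of {ACTIVATIONS}"
        ) from None


_ACTIVATION_FNS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda z: z,
    "relu": lambda z: np.maximum(z, 0.0),
    "satrelu": lambda z: np.clip(z, 0.0, 1.0),
    "satlin": lambda z: np.clip(z, -1.0, 1.0),
}


@dataclass(frozen=True)
class ConnectionSpec:
    """One connection type: source role, target role, level offset, weight.

    ``level_offset`` +1 is feedforward (level i feeds level i+1), -1 is
    feedback, 0 is recurrent within a level.  A present connection must have
    a nonzero weight in [-1, 1].
    """

    source_role: str
    target_role: str
    level_offset: int
    weight: float

    def __post_init__(self) -> None:
        if self.source_role not in ("x", "y") or self.target_role not in ("x", "y"):
            raise ValueError("roles must be 'x' or 'y'")
        if self.level_offset not in (-1, 0, 1):
            raise ValueError("level_offset must be -1, 0 or +1")
        if not (-1.0 <= self.weight <= 1.0) or self.weight == 0.0:
            raise ValueError("weight must be nonzero and within [-1, 1]")

    @property
    def slot(self) -> tuple[str, str, int]:
        return (self.source_role, self.target_role, self.level_offset)


@dataclass(frozen=True)
class StepInput:
    """A constant external drive delivered between two sample indices.

    The drive at sample ``t`` is ``amplitude`` for ``on_start <= t < on_end``
    and zero otherwise; it enters the state update for sample ``t+1``.
    """

    n_samples: int = 120
    on_start: int = 30
    on_end: int = 60
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.on_start < self.on_end <= self.n_samples):
            raise ValueError("need 0 <= on_start < on_end <= n_samples")

    def drive(self, t: int) -> float:
        return self.amplitude if self.on_start <= t < self.on_end else 0.0

    def drive_series(self) -> np.ndarray:
        u = np.zeros(self.n_samples)
        u[self.on_start : self.on_end] = self.amplitude
        return u


@dataclass(frozen=True)
class NetworkSpec:
    """A hierarchical network: level count, connection set, activations.

    At most one connection per (source_role, target_role, level_offset)
    type; each type applies with the same weight at every level.
    """

    n_levels: int = 10
    connections: tuple[ConnectionSpec, ...] = ()
    activation_x: str = "linear"
    activation_y: str = "linear"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be positive")
        if self.activation_x not in ACTIVATIONS or self.activation_y not in ACTIVATIONS:
            raise ValueError(f"activations must be among {ACTIVATIONS}")
        slots = [c.slot for c in self.connections]
        if len(slots) != len(set(slots)):
            raise ValueError("duplicate connection type in NetworkSpec")
        object.__setattr__(self, "connections", tuple(self.connections))

    @classmethod
    def from_weights(
        cls,
        weights: Mapping[tuple[str, str, int], float] | Iterable[float],
        n_levels: int = 10,
        activation_x: str = "linear",
        activation_y: str = "linear",
    ) -> "NetworkSpec":
        """Build a spec from a slot->weight mapping or a 12-vector."""
        if isinstance(weights, Mapping):
            items = weights.items()
        else:
            vec = np.asarray(list(weights), dtype=float)
            if vec.shape != (12,):
                raise ValueError("weight vector must have 12 entries")
            items = [(slot, vec[j]) for j, slot in enumerate(CONNECTION_SLOTS)]
        conns = tuple(
            ConnectionSpec(s, d, o, float(w)) for (s, d, o), w in items if w != 0.0
        )
        return cls(n_levels, conns, activation_x, activation_y)

    def weight_vector(self) -> np.ndarray:
        """The 12-vector of connection weights in ``CONNECTION_SLOTS`` order."""
        vec = np.zeros(12)
        for c in self.connections:
            vec[SLOT_INDEX[c.slot]] = c.weight
        return vec

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_levels": self.n_levels,
                "activation_x": self.activation_x,
                "activation_y": self.activation_y,
                "connections": [
                    {
                        "src": c.source_role,
                        "dst": c.target_role,
                        "offset": c.level_offset,
                        "w": c.weight,
                    }
                    for c in self.connections
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        obj = json.loads(text)
        conns = tuple(
            ConnectionSpec(c["src"], c["dst"], int(c["offset"]), float(c["w"]))
            for c in obj.get("connections", ())
        )
        return cls(
            n_levels=int(obj.get("n_levels", 10)),
            connections=conns,
            activation_x=obj.get("activation_x", "linear"),
            activation_y=obj.get("activation_y", "linear"),
        )


@dataclass
class SimulationTrace:
    """Per-level, per-role activity over time.

    ``values`` has shape (n_levels, 2, n_samples); role 0 is the observable
    x unit, role 1 the hidden y unit.  ``stable`` is False when any sample
    is non-finite or exceeds ``STABILITY_LIMIT`` in magnitude.
    """

    values: np.ndarray
    stable: bool
    input: StepInput

    @property
    def x(self) -> np.ndarray:
        """Observable-unit activity, shape (n_levels, n_samples)."""
        return self.values[:, 0, :]

    @property
    def y(self) -> np.ndarray:
        """Hidden-unit activity, shape (n_levels, n_samples)."""
        return self.values[:, 1, :]


def step_state(
    net: NetworkSpec,
    state: np.ndarray,
    input_value: float,
    input_roles: str = "xy",
) -> np.ndarray:
    """Advance the network state one sample (synchronous update).

    ``state`` has shape (n_levels, 2).  Every unit's next activity is its
    activation applied to the weighted sum of its incoming connections
    evaluated on the time-t snapshot.  The external input is the activity of
    a virtual level 0 whose roles named in ``input_roles`` carry
    ``input_value``; it reaches level 1 through the network's feedforward
    connections.
    """
    state = np.asarray(state, dtype=float)
    L = net.n_levels
    if state.shape != (L, 2):
        raise ValueError(f"state must have shape ({L}, 2)")
    acc = np.zeros((L, 2))
    for c in net.connections:
        s = ROLE_INDEX[c.source_role]
        d = ROLE_INDEX[c.target_role]
        if c.level_offset == 0:
            src_act = state[:, s]
        elif c.level_offset == 1:
            # target level i receives from level i-1; level 1 from the input.
            src_act = np.empty(L)
            src_act[1:] = state[:-1, s]
            src_act[0] = input_value if c.source_role in input_roles else 0.0
        else:
            # feedback: target level i receives from level i+1; the top level
            # has none above it, and feedback out of level 1 is discarded.
            src_act = np.empty(L)
            src_act[:-1] = state[1:, s]
            src_act[-1] = 0.0
        acc[:, d] += c.weight * src_act
    nxt = np.empty_like(acc)
    nxt[:, 0] = activation_function(net.activation_x)(acc[:, 0])
    nxt[:, 1] = activation_function(net.activation_y)(acc[:, 1])
    return nxt


def simulate(
    net: NetworkSpec,
    inp: StepInput | None = None,
    input_roles: str = "xy",
) -> SimulationTrace:
    """Simulate a network from a zero initial state under a step input."""
    if inp is None:
        inp = StepInput()
    values = np.zeros((net.n_levels, 2, inp.n_samples))
    state = values[:, :, 0].copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(inp.n_samples - 1):
            state = step_state(net, state, inp.drive(t), input_roles)
            values[:, :, t + 1] = state
    finite = np.isfinite(values).all()
    stable = bool(finite and np.abs(values).max() <= STABILITY_LIMIT)
    return SimulationTrace(values=values, stable=stable, input=inp)
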