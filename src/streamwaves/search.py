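"""Architecture search over hierarchical dynamical systems.

An *architecture* is the set of models whose 12 connection types share the
same signs (-1, 0, +1); its *complexity* is the number of present
(nonzero) connections.  The search enumerates models of increasing
complexity — every k-subset of connection types, crossed with a weight
grid per present connection and with the 4 x 4 activation pairs — and
keeps the models whose simulated observable units reproduce the
traveling-wave phenomenology of evoked responses:

1. *onset*: every level's x unit rises monotonically to a positive peak
   before the input switches off;
2. *offset*: every level's x unit dips below zero and then relaxes
   monotonically back toward zero;
3. *increasing maintenance*: the half-life of the peak (samples until the
   activity first falls to half its maximum) strictly increases across
   levels, i.e. the waves widen as they travel up the hierarchy.  A
   non-strict comparison would admit pure delay lines, whose
   constant-width waves are exactly the phenomenology the criteria are
   meant to exclude.

The search stops at the smallest complexity with at least one valid
model, after evaluating all models at that complexity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence

import numpy as np

from .dynamics import (
    CONNECTION_SLOTS,
    STABILITY_LIMIT,
    NetworkSpec,
    SimulationTrace,
    StepInput,
    activation_function,
)

__all__ = [
    "MONOTONE_TOL",
    "OnsetVerdict",
    "OffsetVerdict",
    "LevelReport",
    "ValidityReport",
    "SearchResult",
    "detect_onset",
    "detect_offset",
    "half_life",
    "validate_model",
    "enumerate_architectures",
    "complexity",
    "is_leaf_x",
    "simulate_batch",
    "validate_batch",
    "search_min_complexity",
]

#: Tolerance for the monotonicity comparisons in the onset/offset/half-life
#: criteria ("non-decreasing" means every step >= -MONOTONE_TOL).
MONOTONE_TOL = 1e-9

_X_SOURCE = tuple(j for j, (s, _, _) in enumerate(CONNECTION_SLOTS) if s == "x")


def _input_carrier_slots(input_roles: str) -> tuple[int, ...]:
    """Feedforward slots through which the external input can enter level 1."""
    return tuple(
        j
        for j, (src, _, off) in enumerate(CONNECTION_SLOTS)
        if off == 1 and src in input_roles
    )


# ---------------------------------------------------------------------------
# Phenomenology criteria on a single series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OnsetVerdict:
    has_onset: bool
    t_M: int
    M: float


@dataclass(frozen=True)
class OffsetVerdict:
    has_offset: bool
    t_m: int
    m: float


def detect_onset(series: np.ndarray, inp: StepInput) -> OnsetVerdict:
    """Check for a transient onset response.

    The unit passes when its maximum ``M`` (first index ``t_M``) is
    positive, is reached before the input switches off, and the series is
    non-decreasing from ``on_start`` to ``t_M``.
    """
    s = np.asarray(series, dtype=float)
    t_M = int(np.argmax(s))
    M = float(s[t_M])
    ok = M > 0 and t_M < inp.on_end
    if ok and t_M > inp.on_start:
        rise = np.diff(s[inp.on_start : t_M + 1])
        ok = bool((rise >= -MONOTONE_TOL).all())
    return OnsetVerdict(has_onset=bool(ok), t_M=t_M, M=M)


def detect_offset(series: np.ndarray, inp: StepInput) -> OffsetVerdict:
    """Check for a transient offset rebound.

    The unit passes when its minimum ``m`` (first index ``t_m``) is
    negative and the series relaxes back toward zero from ``t_m`` to the
    final sample: non-decreasing throughout and strictly above ``m`` at
    the end (a response frozen at its minimum has not relaxed).
    """
    s = np.asarray(series, dtype=float)
    t_m = int(np.argmin(s))
    m = float(s[t_m])
    ok = m < 0 and t_m < s.size - 1
    if ok:
        tail = np.diff(s[t_m:])
        ok = bool((tail >= -MONOTONE_TOL).all()) and s[-1] > m + MONOTONE_TOL
    return OffsetVerdict(has_offset=bool(ok), t_m=t_m, m=m)


def half_life(
    series: np.ndarray, onset: OnsetVerdict, offset: OffsetVerdict
) -> int | None:
    """Samples from the peak until activity first falls to half the peak.

    Defined only when the unit has both an onset and an offset and decays
    monotonically (non-increasing) between the peak and the minimum;
    returns ``None`` otherwise.  The crossing is the first sample at or
    after ``t_M`` whose value is <= M/2, with no interpolation.
    """
    if not (onset.has_onset and offset.has_offset):
        return None
    s = np.asarray(series, dtype=float)
    t_M, t_m = onset.t_M, offset.t_m
    if t_m < t_M:
        return None
    decay = np.diff(s[t_M : t_m + 1])
    if not (decay <= MONOTONE_TOL).all():
        return None
    below = np.nonzero(s[t_M:] <= onset.M / 2.0)[0]
    if below.size == 0:
        return None
    return int(below[0])


@dataclass(frozen=True)
class LevelReport:
    onset: OnsetVerdict
    offset: OffsetVerdict
    t_h: int | None


@dataclass(frozen=True)
class ValidityReport:
    """Per-level traveling-wave verdicts for the observable units."""

    levels: tuple[LevelReport, ...]
    stable: bool
    valid: bool

    @property
    def half_lives(self) -> tuple[int | None, ...]:
        return tuple(lv.t_h for lv in self.levels)


def validate_model(trace: SimulationTrace, inp: StepInput | None = None) -> ValidityReport:
    """Apply the onset / offset / increasing-maintenance criteria.

    Only the observable x units are constrained; hidden y units may have
    any dynamics.  A model is valid when every level passes all three
    criteria and half-lives strictly increase with level.  Unstable
    traces are invalid.
    """
    if inp is None:
        inp = trace.input
    levels = []
    for series in trace.x:
        on = detect_onset(series, inp)
        off = detect_offset(series, inp)
        levels.append(LevelReport(on, off, half_life(series, on, off)))
    ths = [lv.t_h for lv in levels]
    valid = (
        trace.stable
        and all(lv.onset.has_onset and lv.offset.has_offset for lv in levels)
        and all(th is not None for th in ths)
        and all(b > a for a, b in zip(ths, ths[1:]))
    )
    return ValidityReport(levels=tuple(levels), stable=trace.stable, valid=bool(valid))


# ---------------------------------------------------------------------------
# Architecture enumeration
# ---------------------------------------------------------------------------


def enumerate_architectures() -> Iterator[tuple[int, ...]]:
    """Yield every sign pattern over the 12 connection types (3^12 total)."""
    yield from itertools.product((-1, 0, 1), repeat=12)


def complexity(pattern: Sequence[int]) -> int:
    """Number of present (nonzero) connections in a sign pattern."""
    return int(np.count_nonzero(np.asarray(pattern)))


def is_leaf_x(pattern: Sequence[int]) -> bool:
    """True when the x units have no outgoing connections (epiphenomenal)."""
    return all(pattern[j] == 0 for j in _X_SOURCE)


# ---------------------------------------------------------------------------
# Vectorized batch simulation
# ---------------------------------------------------------------------------


def simulate_batch(
    weights: np.ndarray,
    activation_x: str,
    activation_y: str,
    n_levels: int = 10,
    inp: StepInput | None = None,
    input_roles: str = "xy",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many models at once.

    ``weights`` has shape (B, 12) in ``CONNECTION_SLOTS`` order.  Returns
    the observable traces (B, n_levels, n_samples) and a boolean stability
    flag per model.  Per model, results equal :func:`streamwaves.dynamics.simulate`
    exactly (same synchronous update, same input coupling).
    """
    if inp is None:
        inp = StepInput()
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[1] != 12:
        raise ValueError("weights must have shape (B, 12)")
    B, L, T = W.shape[0], n_levels, inp.n_samples
    fx = activation_function(activation_x)
    fy = activation_function(activation_y)
    active = [j for j in range(12) if np.any(W[:, j])]
    sx = np.zeros((B, L))
    sy = np.zeros((B, L))
    xtr = np.zeros((B, L, T))
    maxabs = np.zeros(B)
    state = {"x": None, "y": None}
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(T - 1):
            u = inp.drive(t)
            state["x"], state["y"] = sx, sy
            acc_x = np.zeros((B, L))
            acc_y = np.zeros((B, L))
            for j in active:
                src, dst, off = CONNECTION_SLOTS[j]
                w = W[:, j]
                src_state = state[src]
                if off == 0:
                    a = src_state
                elif off == 1:
                    a = np.empty((B, L))
                    a[:, 1:] = src_state[:, :-1]
                    a[:, 0] = u if src in input_roles else 0.0
                else:
                    a = np.empty((B, L))
                    a[:, :-1] = src_state[:, 1:]
                    a[:, -1] = 0.0
                if dst == "x":
                    acc_x += w[:, None] * a
                else:
                    acc_y += w[:, None] * a
            sx = fx(acc_x)
            sy = fy(acc_y)
            xtr[:, :, t + 1] = sx
            np.maximum(
                maxabs,
                np.maximum(np.abs(sx).max(axis=1), np.abs(sy).max(axis=1)),
                out=maxabs,
            )
    with np.errstate(invalid="ignore"):
        stable = np.isfinite(maxabs) & (maxabs <= STABILITY_LIMIT)
    return xtr, stable


def validate_batch(
    xtraces: np.ndarray,
    stable: np.ndarray,
    inp: StepInput,
) -> dict[str, np.ndarray]:
    """Vectorized traveling-wave validity check.

    ``xtraces`` has shape (B, n_levels, n_samples).  Returns per-model
    arrays: ``valid`` (B,), ``half_lives`` (B, n_levels; -1 where
    undefined).  Semantics match :func:`validate_model` level by level.
    """
    s = np.asarray(xtraces)
    B, L, T = s.shape
    with np.errstate(invalid="ignore"):
        d = np.diff(s, axis=-1)  # step t -> t+1 lives at index t
        tgrid = np.arange(T - 1)

        t_M = np.argmax(s, axis=-1)  # first maximum
        M = np.take_along_axis(s, t_M[..., None], axis=-1)[..., 0]
        bad_rise = (d < -MONOTONE_TOL) & (tgrid >= inp.on_start) & (
            tgrid < t_M[..., None]
        )
        onset_ok = (M > 0) & (t_M < inp.on_end) & ~bad_rise.any(axis=-1)

        t_m = np.argmin(s, axis=-1)  # first minimum
        m = np.take_along_axis(s, t_m[..., None], axis=-1)[..., 0]
        bad_tail = (d < -MONOTONE_TOL) & (tgrid >= t_m[..., None])
        offset_ok = (
            (m < 0)
            & (t_m < T - 1)
            & ~bad_tail.any(axis=-1)
            & (s[..., -1] > m + MONOTONE_TOL)
        )

        bad_decay = (d > MONOTONE_TOL) & (tgrid >= t_M[..., None]) & (
            tgrid < t_m[..., None]
        )
        decay_ok = (t_m >= t_M) & ~bad_decay.any(axis=-1)

        below = (np.arange(T) >= t_M[..., None]) & (s <= M[..., None] / 2.0)
        has_cross = below.any(axis=-1)
        t_h = np.argmax(below, axis=-1) - t_M

        level_ok = onset_ok & offset_ok & decay_ok & has_cross
        th_mono = (np.diff(t_h, axis=1) > 0).all(axis=1) if L > 1 else np.ones(B, bool)
        valid = np.asarray(stable, bool) & level_ok.all(axis=1) & th_mono
    half_lives = np.where(level_ok, t_h, -1)
    return {"valid": valid, "half_lives": half_lives}


# ---------------------------------------------------------------------------
# Minimal-complexity search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Exemplar:
    """One concrete valid model representing a sign pattern."""

    weights: tuple[float, ...]
    activation_x: str
    activation_y: str

    def to_network(self, n_levels: int = 10) -> NetworkSpec:
        return NetworkSpec.from_weights(
            self.weights, n_levels, self.activation_x, self.activation_y
        )


@dataclass
class SearchResult:
    """Outcome of the minimal-complexity search.

    ``architectures`` are the valid sign patterns at complexity
    ``k_min`` (an architecture is exactly a sign pattern over the 12
    connection types); ``leaf_x_patterns`` tags those whose x units have
    no outgoing connections (epiphenomenal observables).
    """

    found: bool
    k_min: int | None
    architectures: tuple[tuple[int, ...], ...]
    exemplars: dict[tuple[int, ...], Exemplar]
    leaf_x_patterns: tuple[tuple[int, ...], ...]
    models_evaluated: int
    models_simulated: int
    params: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "found": self.found,
            "k_min": self.k_min,
            "architectures": [list(p) for p in self.architectures],
            "exemplars": {
                ",".join(map(str, p)): {
                    "weights": list(e.weights),
                    "activation_x": e.activation_x,
                    "activation_y": e.activation_y,
                }
                for p, e in self.exemplars.items()
            },
            "leaf_x_patterns": [list(p) for p in self.leaf_x_patterns],
            "models_evaluated": self.models_evaluated,
            "models_simulated": self.models_simulated,
            "params": self.params,
        }


def _grid_blocks(subset: tuple[int, ...], grid: np.ndarray) -> np.ndarray:
    """All weight assignments for one slot subset, as (g^k, 12) vectors."""
    k = len(subset)
    combos = np.array(list(itertools.product(grid, repeat=k)), dtype=float)
    block = np.zeros((combos.shape[0], 12))
    block[:, list(subset)] = combos
    return block


def search_min_complexity(
    weight_grid: Sequence[float],
    max_k: int = 6,
    *,
    n_levels: int = 10,
    inp: StepInput | None = None,
    input_roles: str = "xy",
    batch_size: int = 16384,
) -> SearchResult:
    """Find the minimal number of connections yielding valid traveling waves.

    For k = 1, 2, ... every model — k-subset of the 12 connection types,
    one grid value per present connection, one of the 16 activation pairs
    — is evaluated; the search stops at the first complexity with at least
    one valid model, after finishing that complexity level.  The result is
    a pure function of its arguments (no randomness).

    Subsets with no feedforward connection able to carry the external
    input provably simulate to an all-zero (invalid) trace and are counted
    as evaluated without being simulated.
    """
    if inp is None:
        inp = StepInput()
    grid = np.asarray(weight_grid, dtype=float)
    if grid.size == 0 or np.any(grid == 0) or np.any(np.abs(grid) > 1):
        raise ValueError("weight grid values must be nonzero and within [-1, 1]")
    if not 1 <= max_k <= 12:
        raise ValueError("max_k must be in 1..12")
    g = grid.size
    carriers = set(_input_carrier_slots(input_roles))

    act_pairs = [(ax, ay) for ax in ("linear", "relu", "satrelu", "satlin")
                 for ay in ("linear", "relu", "satrelu", "satlin")]
    models_evaluated = 0
    models_simulated = 0
    exemplars: dict[tuple[int, ...], Exemplar] = {}

    for k in range(1, max_k + 1):
        subsets = [
            sub
            for sub in itertools.combinations(range(12), k)
            if carriers.intersection(sub)
        ]
        models_evaluated += comb(12, k) * g**k * 16
        blocks = [_grid_blocks(sub, grid) for sub in subsets]
        for ax, ay in act_pairs:
            pending: list[np.ndarray] = []
            n_pending = 0
            for block in blocks:
                pending.append(block)
                n_pending += block.shape[0]
                if n_pending >= batch_size:
                    models_simulated += _flush(
                        pending, ax, ay, n_levels, inp, input_roles, exemplars
                    )
                    pending, n_pending = [], 0
            if pending:
                models_simulated += _flush(
                    pending, ax, ay, n_levels, inp, input_roles, exemplars
                )
        if exemplars:
            patterns = tuple(sorted(exemplars))
            return SearchResult(
                found=True,
                k_min=k,
                architectures=patterns,
                exemplars=dict(exemplars),
                leaf_x_patterns=tuple(p for p in patterns if is_leaf_x(p)),
                models_evaluated=models_evaluated,
                models_simulated=models_simulated,
                params=_search_params(grid, max_k, n_levels, inp, input_roles),
            )
    return SearchResult(
        found=False,
        k_min=None,
        architectures=(),
        exemplars={},
        leaf_x_patterns=(),
        models_evaluated=models_evaluated,
        models_simulated=models_simulated,
        params=_search_params(grid, max_k, n_levels, inp, input_roles),
    )


def _flush(
    pending: list[np.ndarray],
    ax: str,
    ay: str,
    n_levels: int,
    inp: StepInput,
    input_roles: str,
    exemplars: dict[tuple[int, ...], Exemplar],
) -> int:
    W = np.vstack(pending)
    xtr, stable = simulate_batch(W, ax, ay, n_levels, inp, input_roles)
    res = validate_batch(xtr, stable, inp)
    for i in np.nonzero(res["valid"])[0]:
        pattern = tuple(int(v) for v in np.sign(W[i]))
        exemplars.setdefault(
            pattern, Exemplar(tuple(float(v) for v in W[i]), ax, ay)
        )
    return W.shape[0]


def _search_params(grid, max_k, n_levels, inp, input_roles) -> dict:
    return {
        "weight_grid": [float(v) for v in grid],
        "max_k": int(max_k),
        "n_levels": int(n_levels),
        "n_samples": inp.n_samples,
        "on_start": inp.on_start,
        "on_end": inp.on_end,
        "input_roles": input_roles,
    }
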