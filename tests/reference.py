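"""Independent scalar-loop reference implementations used as test oracles.

Deliberately written with plain Python loops and dictionaries, sharing no
code with the package's vectorized implementations.
"""

from __future__ import annotations


def ref_activation(kind: str, z: float) -> float:
    if kind == "linear":
        return z
    if kind == "relu":
        return max(z, 0.0)
    if kind == "satrelu":
        return min(max(z, 0.0), 1.0)
    if kind == "satlin":
        return min(max(z, -1.0), 1.0)
    raise ValueError(kind)


def ref_simulate(
    weights: dict,
    n_levels: int,
    activation_x: str,
    activation_y: str,
    n_samples: int,
    on_start: int,
    on_end: int,
    amplitude: float = 1.0,
    input_roles: str = "xy",
):
    """Simulate unit by unit, connection by connection.

    ``weights`` maps (source_role, target_role, level_offset) to a float.
    Returns a nested list ``trace[level][role][t]`` with role 0 = x, 1 = y.
    """
    trace = [[[0.0] * n_samples, [0.0] * n_samples] for _ in range(n_levels)]
    state = {(lvl, role): 0.0 for lvl in range(1, n_levels + 1) for role in "xy"}
    for t in range(n_samples - 1):
        drive = amplitude if on_start <= t < on_end else 0.0
        nxt = {}
        for lvl in range(1, n_levels + 1):
            for role in "xy":
                total = 0.0
                for (src, dst, off), w in weights.items():
                    if dst != role:
                        continue
                    src_level = lvl - off
                    if src_level == 0:
                        val = drive if (off == 1 and src in input_roles) else 0.0
                    elif 1 <= src_level <= n_levels:
                        val = state[(src_level, src)]
                    else:
                        val = 0.0
                    total += w * val
                fn = activation_x if role == "x" else activation_y
                nxt[(lvl, role)] = ref_activation(fn, total)
        state = nxt
        for lvl in range(1, n_levels + 1):
            trace[lvl - 1][0][t + 1] = state[(lvl, "x")]
            trace[lvl - 1][1][t + 1] = state[(lvl, "y")]
    return trace
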