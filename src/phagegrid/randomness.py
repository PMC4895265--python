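"""RNG discipline and integer-rounding helpers.

Every stochastic phase draws from a counter-based substream keyed by
(seed, generation, phase, node index), so results never depend on the
iteration order of nodes.  Deterministic mode replaces random draws with
rounded expectations and largest-remainder apportionment, which makes
conservation exact and runs bitwise reproducible without any RNG.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

# Phase indices used to key RNG substreams (stable across releases).
PHASE_GROWTH = 3
PHASE_MUTATION = 4
PHASE_HGT = 5
PHASE_LOSS = 6
PHASE_INFECTION = 7
PHASE_FLOW = 8
PHASE_DIFFUSION = 9
PHASE_CHEMOTAXIS = 10


_MASK64 = 0xFFFFFFFFFFFFFFFF


def _mix64(x: int) -> int:
    """splitmix64 finalizer: disperses counter keys into PCG64 state."""
    x &= _MASK64
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & _MASK64
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & _MASK64
    return x ^ (x >> 31)


# One reusable bit generator: substream() reseeds it from the key, which
# is an order of magnitude cheaper than building a SeedSequence per call.
_SHARED_BG = np.random.PCG64(0)
_SHARED_GEN = np.random.Generator(_SHARED_BG)


def _key_state(seed: int, generation: int, phase: int, node_index: int
               ) -> dict:
    a = _mix64(seed * 0x9E3779B97F4A7C15 + 0x632BE59BD9B4E019)
    b = _mix64(a ^ _mix64(generation + 0x9E3779B97F4A7C15))
    c = _mix64(b ^ _mix64(phase + 0xC2B2AE3D27D4EB4F))
    d = _mix64(c ^ _mix64(node_index + 0x165667B19E3779F9))
    return {"bit_generator": "PCG64",
            "state": {"state": (a << 64) | b, "inc": ((c << 64) | d) | 1},
            "has_uint32": 0, "uinteger": 0}


def substream(seed: int, generation: int, phase: int, node_index: int = 0,
              fresh: bool = False) -> np.random.Generator:
    """Generator for one (seed, generation, phase, node) substream.

    By default the returned generator is a shared object reseeded in
    place — valid until the next ``substream`` call, which is how the
    engine consumes it (each phase finishes its draws for a node before
    requesting the next substream).  Pass ``fresh=True`` for an
    independent generator with the same stream.
    """
    state = _key_state(seed, generation, phase, node_index)
    if fresh:
        bg = np.random.PCG64(0)
        bg.state = state
        return np.random.Generator(bg)
    _SHARED_BG.state = state
    return _SHARED_GEN


def draw_count(expected: float, rng: Optional[np.random.Generator],
               deterministic: bool) -> int:
    """Poisson draw of an event count, or its rounded expectation."""
    if expected <= 0:
        return 0
    if deterministic or rng is None:
        return int(round(expected))
    return int(rng.poisson(expected))


def draw_binomial(n: int, p: float, rng: Optional[np.random.Generator],
                  deterministic: bool) -> int:
    """Binomial(n, p) draw, or the rounded expectation n*p."""
    if n <= 0 or p <= 0:
        return 0
    p = min(p, 1.0)
    if deterministic or rng is None:
        return min(n, int(round(n * p)))
    return int(rng.binomial(n, p))


def largest_remainder(targets: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer units to real-valued targets.

    Floors each target, then hands remaining units to the largest
    fractional parts (ties to the lowest index, for determinism).
    """
    floors = [int(np.floor(t)) for t in targets]
    short = total - sum(floors)
    if short > 0:
        order = sorted(range(len(targets)),
                       key=lambda i: (floors[i] - targets[i], i))
        for i in order[:short]:
            floors[i] += 1
    elif short < 0:  # defensive; occurs only with inconsistent inputs
        order = sorted(range(len(targets)),
                       key=lambda i: (targets[i] - floors[i], i))
        for i in order[:-short]:
            if floors[i] > 0:
                floors[i] -= 1
    return floors


def split_counts(n: int, fractions: Sequence[float],
                 rng: Optional[np.random.Generator],
                 deterministic: bool) -> list[int]:
    """Split ``n`` integer units across bins with the given fractions.

    Fractions must sum to 1 (within float tolerance).  Deterministic mode
    uses largest-remainder rounding; stochastic mode draws a multinomial.
    """
    if n <= 0:
        return [0] * len(fractions)
    if deterministic or rng is None:
        return largest_remainder([n * f for f in fractions], n)
    return list(rng.multinomial(n, np.asarray(fractions, dtype=float)))
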