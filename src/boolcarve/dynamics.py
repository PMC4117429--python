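"""Boolean network dynamics: synchronous, asynchronous, and stochastic-input.

Synchronous semantics update every regulated node simultaneously from the
previous state; input nodes hold their clamp value at every step, so the
deterministic map over the free (regulated) coordinates fully determines the
trajectory. Because the state space is finite, every synchronous trajectory
ends in a fixed point or limit cycle; `run_to_cycle` detects the first
repeated state exactly via hashing.

States are exposed as tuples of 0/1 in network node order; internally a
state is packed into a single integer whose comparison order equals the
lexicographic order of the tuple (node 0 is the most significant bit), so
integer minima coincide with lexicographic minima downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BooleanNetwork, State


class HorizonExceededError(RuntimeError):
    """No repeated state found within the step budget."""

    def __init__(self, max_steps: int, initial_state=None):
        self.max_steps = max_steps
        self.initial_state = initial_state
        super().__init__(
            f"no cycle detected within {max_steps} steps"
            + (f" from initial state {initial_state}" if initial_state is not None else "")
        )


@dataclass
class Trajectory:
    """A synchronous run split into its transient prefix and repeating cycle."""

    transient: list[State]
    cycle: list[State]


@dataclass
class StochasticRunResult:
    """Per-node mean activity over the measurement window, plus the coarse
    three-level category used for input-output response maps."""

    activities: dict[str, float]
    categories: dict[str, int]


def categorize_activity(activity: float) -> int:
    """Map a 0-1 activity to the coarse category: whole-percent 0-9 -> 0,
    10-29 -> 1, 30-100 -> 2."""
    pct = round(activity * 100)
    if pct <= 9:
        return 0
    if pct <= 29:
        return 1
    return 2


class CompiledNetwork:
    """Integer-packed synchronous update function for one network.

    Bit ``n - 1 - i`` of the packed integer holds node ``i``, so the integer
    ordering of packed states equals lexicographic ordering of state tuples.
    """

    def __init__(self, net: BooleanNetwork):
        self.net = net
        self.n = net.n_nodes
        n = self.n
        self._pos = [n - 1 - i for i in range(n)]
        self.clamp_mask = 0
        self.clamp_bits = 0
        funcs = []
        for i, node in enumerate(net.nodes):
            table = net.tables.get(node)
            bit = 1 << (n - 1 - i)
            if table is None:
                self.clamp_mask |= bit
                if net.clamp.get(node, 0):
                    self.clamp_bits |= bit
                funcs.append(None)
            else:
                in_pos = tuple(n - 1 - net.index(u) for u in table.inputs)
                outputs_int = 0
                for idx, b in enumerate(table.outputs):
                    outputs_int |= b << idx
                funcs.append((bit, in_pos, outputs_int))
        self.funcs = funcs

    # -- packing -----------------------------------------------------------
    def pack(self, state: State) -> int:
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != node count {self.n}")
        s = 0
        for v in state:
            s = (s << 1) | (v & 1)
        return s

    def unpack(self, s: int) -> State:
        n = self.n
        return tuple((s >> (n - 1 - i)) & 1 for i in range(n))

    def apply_clamps(self, s: int) -> int:
        return (s & ~self.clamp_mask) | self.clamp_bits

    # -- stepping ----------------------------------------------------------
    def step(self, s: int) -> int:
        out = self.clamp_bits
        for f in self.funcs:
            if f is None:
                continue
            bit, in_pos, outputs_int = f
            idx = 0
            for p in in_pos:
                idx = (idx << 1) | ((s >> p) & 1)
            if (outputs_int >> idx) & 1:
                out |= bit
        return out

    def cycle_from(self, s: int, max_steps: int) -> tuple[list[int], list[int]]:
        """Packed transient and cycle via first-repeat hashing."""
        seen: dict[int, int] = {}
        path: list[int] = []
        cur = s
        for _ in range(max_steps + 1):
            if cur in seen:
                i = seen[cur]
                return path[:i], path[i:]
            seen[cur] = len(path)
            path.append(cur)
            cur = self.step(cur)
        raise HorizonExceededError(max_steps, self.unpack(s))

    def attractor_key(
        self, s: int, max_steps: int, cache: dict[int, tuple[int, ...]] | None = None
    ) -> tuple[int, ...]:
        """Canonical packed cycle reached from ``s``; optional memo cache
        shared across calls on the same network."""
        if cache is None:
            return canonical_ints(self.cycle_from(s, max_steps)[1])
        path = []
        cur = s
        seen: dict[int, int] = {}
        for _ in range(max_steps + 1):
            hit = cache.get(cur)
            if hit is not None:
                for st in path:
                    cache[st] = hit
                return hit
            if cur in seen:
                key = canonical_ints(path[seen[cur]:])
                for st in path:
                    cache[st] = key
                return key
            seen[cur] = len(path)
            path.append(cur)
            cur = self.step(cur)
        raise HorizonExceededError(max_steps, self.unpack(s))


def canonical_ints(cycle: list[int]) -> tuple[int, ...]:
    """Rotate a packed cycle so it starts at its minimal state (states in a
    cycle are distinct, so this is the lexicographically minimal rotation)."""
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def compile_network(net: BooleanNetwork) -> CompiledNetwork:
    """Build (and cache on the network object) the packed update function."""
    compiled = getattr(net, "_compiled", None)
    if compiled is None:
        compiled = CompiledNetwork(net)
        net._compiled = compiled
    return compiled


# ---------------------------------------------------------------------------
# public stepping API (tuple states)
# ---------------------------------------------------------------------------

def step_sync(net: BooleanNetwork, state: State) -> State:
    """One simultaneous update of all regulated nodes; clamps conserved."""
    c = compile_network(net)
    return c.unpack(c.step(c.apply_clamps(c.pack(state))))


def step_async(net: BooleanNetwork, state: State, rng: np.random.Generator) -> State:
    """One asynchronous sweep: every regulated node updated once, in a fresh
    uniformly random order, each seeing the partially updated state."""
    c = compile_network(net)
    s = c.apply_clamps(c.pack(state))
    regulated = [f for f in c.funcs if f is not None]
    for j in rng.permutation(len(regulated)):
        bit, in_pos, outputs_int = regulated[j]
        idx = 0
        for p in in_pos:
            idx = (idx << 1) | ((s >> p) & 1)
        if (outputs_int >> idx) & 1:
            s |= bit
        else:
            s &= ~bit
    return c.unpack(s)


def run_to_cycle(net: BooleanNetwork, state: State, max_steps: int = 10_000) -> Trajectory:
    """Iterate synchronously until the first repeated state and split the
    visited sequence into transient and cycle.

    Raises :class:`HorizonExceededError` if no repeat occurs within
    ``max_steps`` states (never truncates silently).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    c = compile_network(net)
    transient, cycle = c.cycle_from(c.apply_clamps(c.pack(state)), max_steps)
    return Trajectory([c.unpack(s) for s in transient], [c.unpack(s) for s in cycle])


def stochastic_input_run(
    net: BooleanNetwork,
    input_probs: dict[str, float],
    total_steps: int = 1_000,
    window: int = 100,
    rng: np.random.Generator | int | None = None,
    initial_state: State | None = None,
) -> StochasticRunResult:
    """Percentage-ON input protocol.

    At every step each input node is independently set ON with its given
    probability (unlisted inputs keep their clamp), then one synchronous
    update is applied. Activities are the per-node mean over the final
    ``window`` states; categories use the coarse 0/1/2 ranges.
    """
    for node, p in input_probs.items():
        if node not in net.input_nodes:
            raise ValueError(f"{node!r} is not an input node")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid probability {p} for {node!r}")
    if window > total_steps:
        raise ValueError("window must not exceed total_steps")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = compile_network(net)
    s = c.apply_clamps(c.pack(initial_state)) if initial_state is not None else c.clamp_bits
    stoch = [(1 << (c.n - 1 - net.index(u)), p) for u, p in input_probs.items()]
    counts = np.zeros(c.n, dtype=np.int64)
    for t in range(total_steps):
        for bit, p in stoch:
            if rng.random() < p:
                s |= bit
            else:
                s &= ~bit
        s = ((c.step(s)) & ~c.clamp_mask) | (s & c.clamp_mask)
        if t >= total_steps - window:
            for i in range(c.n):
                counts[i] += (s >> (c.n - 1 - i)) & 1
    activities = {node: counts[i] / window for i, node in enumerate(net.nodes)}
    categories = {node: categorize_activity(a) for node, a in activities.items()}
    return StochasticRunResult(activities, categories)
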