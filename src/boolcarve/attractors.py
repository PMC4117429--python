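"""Attractor landscapes: sampled estimation, exact enumeration, basins.

The attractor landscape of a synchronous Boolean network is the set of its
attractors (fixed points and limit cycles) together with the sizes of their
basins of attraction. For large networks the landscape is estimated from
uniformly sampled initial states over the free (regulated) coordinates; for
small networks it can be enumerated exactly. The attractor with the largest
basin is the *primary attractor* — the dominant, nominal state of the
system.

Attractors are identified by a canonical cyclic form: the rotation of the
cycle whose state sequence is lexicographically minimal. Two attractors are
equal iff their canonical sequences are identical (full-dimension, exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CompiledNetwork, canonical_ints, compile_network
from .model import BooleanNetwork, State


@dataclass(frozen=True)
class Attractor:
    """A canonical cyclic state sequence with its estimated basin."""

    states: tuple[State, ...]
    basin_count: int
    basin_fraction: float

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1


@dataclass
class AttractorLandscape:
    nodes: tuple[str, ...]
    attractors: list[Attractor]
    sample_size: int
    seed: int | None
    primary_index: int
    mode: str  # "sampled" | "exact"

    @property
    def primary(self) -> Attractor:
        return self.attractors[self.primary_index]

    def basin_fractions(self) -> dict[tuple[State, ...], float]:
        return {a.states: a.basin_fraction for a in self.attractors}


def canonical_cycle(states: list[State] | tuple[State, ...]) -> tuple[State, ...]:
    """Rotation-invariant canonical form of a cycle of distinct states."""
    states = list(states)
    i = states.index(min(states))
    return tuple(states[i:] + states[:i])


def _free_positions(net: BooleanNetwork, c: CompiledNetwork) -> list[int]:
    return [c.n - 1 - net.index(v) for v in net.free_nodes]


def _landscape_from_counts(
    net: BooleanNetwork,
    c: CompiledNetwork,
    counts: dict[tuple[int, ...], int],
    sample_size: int,
    seed: int | None,
    mode: str,
) -> AttractorLandscape:
    attractors = []
    for key in sorted(counts):
        n_hits = counts[key]
        states = tuple(c.unpack(s) for s in key)
        attractors.append(Attractor(states, n_hits, n_hits / sample_size))
    best = max(a.basin_count for a in attractors)
    # tie-break: lexicographically smallest canonical sequence (sorted order)
    primary_index = next(
        i for i, a in enumerate(attractors) if a.basin_count == best
    )
    return AttractorLandscape(net.nodes, attractors, sample_size, seed, primary_index, mode)


def find_attractors(
    net: BooleanNetwork,
    n_samples: int = 10_000,
    seed: int | None = 0,
    max_steps: int = 10_000,
    exhaustive: bool = False,
) -> AttractorLandscape:
    """Estimate the landscape from random initial states.

    Initial states are uniform over assignments of the free nodes, with
    clamped inputs held at their clamp values; each is run to its cycle and
    attractors are pooled by canonical form. With ``exhaustive=True`` every
    free assignment is visited exactly once instead (feasible for small
    networks), yielding exact basin counts through the sampling code path.
    """
    c = compile_network(net)
    free = _free_positions(net, c)
    if not free:
        raise ValueError("network has no free (regulated) nodes")
    counts: dict[tuple[int, ...], int] = {}
    cache: dict[int, tuple[int, ...]] = {}
    if exhaustive:
        n_samples = 2 ** len(free)
        states = range(n_samples)
        def packed(i):
            s = c.clamp_bits
            for j, p in enumerate(free):
                if (i >> j) & 1:
                    s |= 1 << p
            return s
        draws = (packed(i) for i in states)
    else:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=(n_samples, len(free)), dtype=np.uint8)
        def packed_row(row):
            s = c.clamp_bits
            for p, b in zip(free, row):
                if b:
                    s |= 1 << p
            return s
        draws = (packed_row(row) for row in bits)
    for s0 in draws:
        key = c.attractor_key(s0, max_steps, cache)
        counts[key] = counts.get(key, 0) + 1
    return _landscape_from_counts(
        net, c, counts, n_samples, None if exhaustive else seed,
        "exact" if exhaustive else "sampled",
    )


def enumerate_attractors(net: BooleanNetwork, cap: int = 20) -> AttractorLandscape:
    """Exact landscape by full state-graph traversal.

    Independent of the trajectory-walking estimator: builds the complete
    successor map over all free-node assignments, finds the recurrent states
    by iteratively peeling states with no remaining predecessor, extracts
    cycles, and sizes each basin by reverse breadth-first search.
    """
    c = compile_network(net)
    free = _free_positions(net, c)
    f = len(free)
    if f == 0:
        raise ValueError("network has no free (regulated) nodes")
    if f > cap:
        raise ValueError(f"{f} free nodes exceeds enumeration cap {cap}")

    def pack_free(i: int) -> int:
        s = c.clamp_bits
        for j, p in enumerate(free):
            if (i >> j) & 1:
                s |= 1 << p
        return s

    def unpack_free(s: int) -> int:
        i = 0
        for j, p in enumerate(free):
            if (s >> p) & 1:
                i |= 1 << j
        return i

    size = 2**f
    succ = np.empty(size, dtype=np.int64)
    for i in range(size):
        succ[i] = unpack_free(c.step(pack_free(i)))

    # peel non-recurrent states: repeatedly drop states with zero in-degree
    indeg = np.bincount(succ, minlength=size)
    stack = [i for i in range(size) if indeg[i] == 0]
    alive = np.ones(size, dtype=bool)
    while stack:
        i = stack.pop()
        alive[i] = False
        j = succ[i]
        indeg[j] -= 1
        if indeg[j] == 0:
            stack.append(int(j))

    # recurrent states form disjoint cycles
    preds: list[list[int]] = [[] for _ in range(size)]
    for i in range(size):
        preds[succ[i]].append(i)
    visited = np.zeros(size, dtype=bool)
    counts: dict[tuple[int, ...], int] = {}
    for i in range(size):
        if not alive[i] or visited[i]:
            continue
        cycle = []
        j = i
        while not visited[j]:
            visited[j] = True
            cycle.append(j)
            j = int(succ[j])
        key = canonical_ints([pack_free(x) for x in cycle])
        # basin: reverse BFS from cycle states through non-recurrent preds
        basin = 0
        frontier = list(cycle)
        on_cycle = set(cycle)
        seen = set(cycle)
        while frontier:
            x = frontier.pop()
            basin += 1
            for p in preds[x]:
                if p not in seen and p not in on_cycle:
                    seen.add(p)
                    frontier.append(p)
        counts[key] = basin
    return _landscape_from_counts(net, c, counts, size, None, "exact")


def primary(landscape: AttractorLandscape) -> Attractor:
    """Attractor with the maximal basin; ties broken by lexicographically
    smallest canonical sequence."""
    if not landscape.attractors:
        raise ValueError("empty landscape")
    return landscape.primary


def sample_basin_states(
    net: BooleanNetwork,
    target: Attractor,
    n: int,
    seed: int | None = 0,
    max_steps: int = 10_000,
    acceptance_floor: float = 1e-3,
    probe: int = 10_000,
) -> list[State]:
    """Rejection-sample ``n`` uniform free-node states whose trajectories end
    in ``target``; fails explicitly if the acceptance rate over an initial
    probe falls below ``acceptance_floor``."""
    c = compile_network(net)
    free = _free_positions(net, c)
    rng = np.random.default_rng(seed)
    key = canonical_ints([c.pack(s) for s in target.states])
    cache: dict[int, tuple[int, ...]] = {}
    kept: list[State] = []
    tried = 0
    while len(kept) < n:
        bits = rng.integers(0, 2, size=len(free), dtype=np.uint8)
        s0 = c.clamp_bits
        for p, b in zip(free, bits):
            if b:
                s0 |= 1 << p
        tried += 1
        if c.attractor_key(s0, max_steps, cache) == key:
            kept.append(c.unpack(s0))
        if tried >= probe and len(kept) / tried < acceptance_floor:
            raise RuntimeError(
                f"basin acceptance rate {len(kept) / tried:.2e} below floor "
                f"{acceptance_floor:.2e} after {tried} draws"
            )
    return kept


def compare_landscapes(a: AttractorLandscape, b: AttractorLandscape) -> dict:
    """Match attractors by canonical form and compare basin fractions.

    Returns shared attractor count, per-attractor basin-fraction pairs
    (unmatched attractors paired with 0), and the L1 distance between the
    basin-fraction vectors (0 for identical landscapes, 2 for disjoint
    attractor sets).
    """
    if a.nodes != b.nodes:
        raise ValueError("landscapes are over different node universes")
    fa, fb = a.basin_fractions(), b.basin_fractions()
    keys = sorted(set(fa) | set(fb))
    pairs = {k: (fa.get(k, 0.0), fb.get(k, 0.0)) for k in keys}
    shared = sum(1 for k in keys if k in fa and k in fb)
    l1 = sum(abs(x - y) for x, y in pairs.values())
    return {"shared": shared, "pairs": pairs, "l1": l1}
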