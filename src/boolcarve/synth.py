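"""Synthetic Boolean network generator and canonical fixtures.

Random networks in the Kauffman style: each regulated node draws its
regulators from a configurable in-degree distribution (fixed k, Poisson, or
truncated power law) and fills its truth-table rows i.i.d. Bernoulli(p).
Feedback loops can be *planted*: the loop nodes are wired first as copy
gates (each node simply copies its predecessor and takes no further
regulators), which guarantees the loop survives as a dynamical limit cycle —
purely random tables frequently collapse to fixed points, which would starve
decomposition studies of a nontrivial primary attractor.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BooleanNetwork, LogicTable


@dataclass
class SynthSpec:
    """Recipe for one random network.

    ``degree`` is ``("fixed", k)``, ``("poisson", lam)`` or
    ``("powerlaw", alpha, cap)``; ``bias`` is the probability that a truth
    table row outputs 1; ``planted_loops`` lists (length, count) pairs.
    """

    n_nodes: int
    n_inputs: int = 1
    degree: tuple = ("fixed", 2)
    bias: float = 0.5
    planted_loops: list[tuple[int, int]] = field(default_factory=list)
    seed: int | None = 0

    def __post_init__(self):
        if self.n_inputs >= self.n_nodes:
            raise ValueError("n_inputs must be smaller than n_nodes")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [0, 1]")
        n_loop = sum(length * count for length, count in self.planted_loops)
        if any(length < 1 for length, _ in self.planted_loops):
            raise ValueError("loop length must be >= 1")
        if n_loop > self.n_nodes - self.n_inputs:
            raise ValueError("planted loops need more nodes than available")


def _draw_degree(rng: np.random.Generator, degree: tuple, max_k: int) -> int:
    kind = degree[0]
    if kind == "fixed":
        k = int(degree[1])
    elif kind == "poisson":
        k = int(rng.poisson(degree[1]))
    elif kind == "powerlaw":
        alpha, cap = float(degree[1]), int(degree[2]) if len(degree) > 2 else max_k
        support = np.arange(1, min(cap, max_k) + 1)
        weights = support.astype(float) ** (-alpha)
        cdf = np.cumsum(weights / weights.sum())
        k = int(support[np.searchsorted(cdf, rng.random())])
    else:
        raise ValueError(f"unknown degree distribution {kind!r}")
    return max(0, min(k, max_k))


def generate(spec: SynthSpec) -> BooleanNetwork:
    """Generate one network from the recipe (fully seeded)."""
    rng = np.random.default_rng(spec.seed)
    n_reg = spec.n_nodes - spec.n_inputs
    inputs = [f"I{i}" for i in range(spec.n_inputs)]
    regulated = [f"N{i}" for i in range(n_reg)]
    nodes = inputs + regulated

    tables: dict[str, LogicTable] = {}
    pool = list(regulated)
    for length, count in spec.planted_loops:
        for _ in range(count):
            loop = pool[:length]
            pool = pool[length:]
            for i, v in enumerate(loop):
                pred = loop[(i - 1) % length]
                tables[v] = LogicTable(v, (pred,), (0, 1))
    for v in pool:
        k = _draw_degree(rng, spec.degree, spec.n_nodes)
        if k == 0:
            tables[v] = LogicTable(v, (), (int(rng.random() < spec.bias),))
            continue
        regs = rng.choice(len(nodes), size=k, replace=False)
        regs = tuple(nodes[i] for i in sorted(regs))
        outputs = tuple(int(rng.random() < spec.bias) for _ in range(2**k))
        tables[v] = LogicTable(v, regs, outputs)
    return BooleanNetwork(nodes, tables)


FIXTURE_NAMES = ("TOY3", "TRIAD", "FFWD5", "REDUNDANT4")


def fixture(name: str) -> BooleanNetwork:
    """Bit-exact canonical fixtures used across the test-bed.

    TOY3
        Nodes A, B, C; A is an input clamped OFF; f_B = A OR C, f_C = B.
        Holds a 2-cycle attractor sustained by the B-C feedback; the edge
        (A, B) is dynamically silent under the clamp.
    TRIAD
        Three copy gates in a directed 3-cycle (no inputs); four attractors
        (two fixed points, two 3-cycles) with basins 1, 1, 3, 3.
    FFWD5
        Five-node feed-forward copy chain with the source clamped OFF; a
        single all-OFF fixed point attracts everything.
    REDUNDANT4
        Input A plus a B-C copy 2-cycle driving a readout D with
        f_D(A, C) = C: the edge (A, D) is locally redundant (fictitious)
        while (C, D) is locally essential yet only matters dynamically
        through the full-dimensional primary cycle.
    """
    if name == "TOY3":
        return BooleanNetwork(
            ["A", "B", "C"],
            {
                "B": LogicTable("B", ("A", "C"), (0, 1, 1, 1)),
                "C": LogicTable("C", ("B",), (0, 1)),
            },
        )
    if name == "TRIAD":
        return BooleanNetwork(
            ["X", "Y", "Z"],
            {
                "X": LogicTable("X", ("Z",), (0, 1)),
                "Y": LogicTable("Y", ("X",), (0, 1)),
                "Z": LogicTable("Z", ("Y",), (0, 1)),
            },
        )
    if name == "FFWD5":
        nodes = ["A", "B", "C", "D", "E"]
        tables = {
            v: LogicTable(v, (nodes[i - 1],), (0, 1))
            for i, v in enumerate(nodes)
            if i > 0
        }
        return BooleanNetwork(nodes, tables)
    if name == "REDUNDANT4":
        return BooleanNetwork(
            ["A", "B", "C", "D"],
            {
                "B": LogicTable("B", ("C",), (0, 1)),
                "C": LogicTable("C", ("B",), (0, 1)),
                "D": LogicTable("D", ("A", "C"), (0, 1, 0, 1)),
            },
        )
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
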