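"""Core data model for Boolean regulatory networks.

A Boolean network is a directed graph ``G = (V, E, L)``: a set of nodes, a
set of directed edges, and one logic (truth) table per regulated node. Nodes
with no incoming edge are *input nodes* (e.g. ligands of a signaling
network); they carry no table and are clamped to a fixed value at every time
step (OFF by default, modelling the nominal no-stimulus condition).

A network state is the collective binary vector of all node values, in
network node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

State = tuple[int, ...]
Edge = tuple[str, str]


class NetworkFormatError(ValueError):
    """Malformed network text; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class LogicTable:
    """Truth table of one regulated node.

    ``outputs`` has one entry per combination of input values, indexed by the
    input tuple read as a binary number with ``inputs[0]`` as the most
    significant bit. A table with zero inputs is a constant node.
    """

    target: str
    inputs: tuple[str, ...]
    outputs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(int(b) for b in self.outputs))
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError(f"duplicate inputs in table for {self.target!r}")
        if len(self.outputs) != 2 ** len(self.inputs):
            raise ValueError(
                f"table for {self.target!r}: {len(self.outputs)} outputs for "
                f"{len(self.inputs)} inputs (expected {2 ** len(self.inputs)})"
            )
        if any(b not in (0, 1) for b in self.outputs):
            raise ValueError(f"non-binary output in table for {self.target!r}")

    @property
    def k(self) -> int:
        return len(self.inputs)

    def row_index(self, bits: Sequence[int]) -> int:
        idx = 0
        for b in bits:
            idx = (idx << 1) | (b & 1)
        return idx

    def evaluate(self, bits: Sequence[int]) -> int:
        """Output for the given input values (ordered as ``self.inputs``)."""
        if len(bits) != self.k:
            raise ValueError(f"expected {self.k} input bits, got {len(bits)}")
        return self.outputs[self.row_index(bits)]

    def reduce(self, input_id: str, value: int) -> "LogicTable":
        """Project the table by fixing one input to ``value``.

        Returns a ``(k-1)``-input table over the remaining inputs in their
        original order. Fixing commutes: the order of successive reductions
        does not matter.
        """
        if input_id not in self.inputs:
            raise KeyError(f"{input_id!r} is not an input of {self.target!r}")
        pos = self.inputs.index(input_id)
        rest = self.inputs[:pos] + self.inputs[pos + 1 :]
        outputs = []
        for idx in range(2 ** len(rest)):
            bits = [(idx >> (len(rest) - 1 - i)) & 1 for i in range(len(rest))]
            bits.insert(pos, value)
            outputs.append(self.evaluate(bits))
        return LogicTable(self.target, rest, tuple(outputs))

    def is_fictitious(self, input_id: str) -> bool:
        """True iff the output never depends on ``input_id`` (l_0 = l_1)."""
        return self.reduce(input_id, 0).outputs == self.reduce(input_id, 1).outputs


class BooleanNetwork:
    """Directed graph plus per-node logic tables and input-node clamps.

    Parameters
    ----------
    nodes
        All node ids, in the order used for state vectors.
    tables
        One :class:`LogicTable` per regulated node (keyed by target). Nodes
        absent from ``tables`` are input nodes.
    clamp
        Fixed value per input node; defaults to 0 (OFF) for every input node.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        tables: Mapping[str, LogicTable] | Iterable[LogicTable],
        clamp: Mapping[str, int] | None = None,
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        if not isinstance(tables, Mapping):
            tables = {t.target: t for t in tables}
        self.tables: dict[str, LogicTable] = dict(tables)
        for target, table in self.tables.items():
            if table.target != target:
                raise ValueError(f"table keyed {target!r} targets {table.target!r}")
            if target not in self.nodes:
                raise ValueError(f"table for undeclared node {target!r}")
            for u in table.inputs:
                if u not in self.nodes:
                    raise ValueError(f"table for {target!r} references undeclared node {u!r}")
        inputs = tuple(n for n in self.nodes if n not in self.tables)
        self.clamp: dict[str, int] = {n: 0 for n in inputs}
        if clamp:
            for n, v in clamp.items():
                if n not in self.clamp:
                    raise ValueError(f"clamp on non-input node {n!r}")
                self.clamp[n] = int(v)
        self._index = {n: i for i, n in enumerate(self.nodes)}

    # -- accessors ---------------------------------------------------------
    @property
    def input_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.tables)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Nodes whose state is not clamped (all regulated nodes)."""
        return tuple(n for n in self.nodes if n in self.tables)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(
            (u, v) for v, t in self.tables.items() for u in t.inputs
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(t.k for t in self.tables.values())

    def index(self, node: str) -> int:
        return self._index[node]

    def with_table(self, table: LogicTable) -> "BooleanNetwork":
        """Copy of the network with one table replaced (node set unchanged)."""
        tables = dict(self.tables)
        tables[table.target] = table
        clamp = {n: v for n, v in self.clamp.items() if n not in tables}
        return BooleanNetwork(self.nodes, tables, clamp)

    def with_clamp(self, **values: int) -> "BooleanNetwork":
        clamp = dict(self.clamp)
        clamp.update(values)
        return BooleanNetwork(self.nodes, self.tables, clamp)

    def __eq__(self, other):
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.tables == other.tables
            and self.clamp == other.clamp
        )

    def __repr__(self):
        return (
            f"BooleanNetwork({self.n_nodes} nodes, {self.n_edges} edges, "
            f"{len(self.input_nodes)} inputs)"
        )


def validate_network(
    net: BooleanNetwork, declared_edges: Iterable[Edge] | None = None
) -> list[str]:
    """Report every structural invariant violation (empty list = valid).

    Checks edge/table consistency, table lengths, binary outputs, and that
    exactly the table-less nodes are clamped inputs. Constant (0-input)
    tables are legal regulated nodes, not inputs. When ``declared_edges`` is
    given (e.g. an edge list read alongside the tables) it is cross-checked
    against the edges implied by the tables.
    """
    report: list[str] = []
    for target, table in net.tables.items():
        if len(table.outputs) != 2 ** table.k:
            report.append(f"table length: {target} has {len(table.outputs)} rows for k={table.k}")
        for u in table.inputs:
            if u not in net.nodes:
                report.append(f"edge/table mismatch: {target} lists undeclared input {u}")
    from_tables = {(u, v) for v, t in net.tables.items() for u in t.inputs}
    declared = set(declared_edges) if declared_edges is not None else from_tables
    for e in from_tables - declared:
        report.append(f"edge/table mismatch: table input without edge {e}")
    for e in declared - from_tables:
        report.append(f"edge/table mismatch: edge without table input {e}")
    for n in net.input_nodes:
        if n not in net.clamp:
            report.append(f"input node {n} has no clamp value")
        if any(n == t for (_, t) in declared):
            report.append(f"input node {n} has incoming edges")
    return report
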