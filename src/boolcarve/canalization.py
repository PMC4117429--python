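"""Canalizing-function analysis and redundant-link identification.

A Boolean function is canalizing in an input u if some value of u alone
forces the output regardless of all other inputs. A *redundant* input is one
that exact two-level minimization eliminates entirely: it appears in no
prime implicant of the minimal disjunctive cover of the function nor of its
complement. (For exact minimization this coincides with the input being
fictitious — a function that genuinely depends on an input cannot be covered
without it — so redundancy here is a purely local, dynamics-free property of
the table.)

Minimization uses the exact Quine-McCluskey procedure as implemented by
``sympy.logic.SOPform``; table widths in logical signaling models are small,
so no heuristic minimizer is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy
from sympy.logic import SOPform

from .decomposition import Decomposition
from .model import BooleanNetwork, Edge, LogicTable


@dataclass
class CanalizationProfile:
    node: str
    canalizing_inputs: list[tuple[str, int, int]]
    redundant_inputs: list[str]


def canalizing_inputs(table: LogicTable) -> list[tuple[str, int, int]]:
    """All triples (input, canalizing value, forced output), verified
    exhaustively: the output equals the forced value on every row where the
    input takes the canalizing value."""
    if table.k < 1:
        raise ValueError("canalization undefined for a constant node")
    triples = []
    for pos, u in enumerate(table.inputs):
        for a in (0, 1):
            rows = [
                b
                for idx, b in enumerate(table.outputs)
                if ((idx >> (table.k - 1 - pos)) & 1) == a
            ]
            if len(set(rows)) == 1:
                triples.append((u, a, rows[0]))
    return triples


def redundant_inputs(table: LogicTable, minimization_cap: int = 16) -> list[str]:
    """Inputs absent from every prime implicant of the exact minimal
    two-level cover of the function and of its complement."""
    if table.k > minimization_cap:
        raise ValueError(
            f"table width {table.k} exceeds minimization cap {minimization_cap}"
        )
    if table.k == 0:
        return []
    syms = sympy.symbols([f"x{i}" for i in range(table.k)])
    minterms_on = []
    minterms_off = []
    for idx, b in enumerate(table.outputs):
        bits = [(idx >> (table.k - 1 - i)) & 1 for i in range(table.k)]
        (minterms_on if b else minterms_off).append(bits)
    used: set = set()
    for minterms in (minterms_on, minterms_off):
        expr = SOPform(syms, minterms) if minterms else sympy.false
        used |= {s for s in expr.free_symbols}
    return [u for i, u in enumerate(table.inputs) if syms[i] not in used]


def profile(net: BooleanNetwork, node: str) -> CanalizationProfile:
    table = net.tables[node]
    return CanalizationProfile(node, canalizing_inputs(table), redundant_inputs(table))


def redundant_links(net: BooleanNetwork, minimization_cap: int = 16) -> frozenset[Edge]:
    """Edges whose source is a redundant input of the target's table; a
    purely local property independent of clamps, dynamics and seeds."""
    out = set()
    for v, table in net.tables.items():
        for u in redundant_inputs(table, minimization_cap):
            out.add((u, v))
    return frozenset(out)


def compare_redundant_vs_decomposition(
    net: BooleanNetwork, decomposition: Decomposition
) -> dict:
    """Set overlap between locally redundant links and the dynamical
    core/neighbor partition."""
    if decomposition.edges != net.edges:
        raise ValueError("decomposition covers a different edge universe")
    red = redundant_links(net)
    return {
        "n_redundant": len(red),
        "n_redundant_core": len(red & decomposition.core_edges),
        "n_redundant_neighbor": len(red & decomposition.neighbor_edges),
    }
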