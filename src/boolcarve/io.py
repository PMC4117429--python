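"""Readers and writers for logical-network text formats.

Two dialects are supported:

``truthtable_csv``
    One block per regulated node. A header line ``node,<input ids...>``
    followed by ``2^k`` rows ``bit,...,bit,output`` giving the output for
    each input combination (rows may appear in any order; each combination
    exactly once). ``#`` starts a comment. The directive comment
    ``# clamp: NODE=1`` overrides an input node's clamp value.

``expr``
    One line per regulated node, ``target = <expression>`` over the
    operators ``AND``/``OR``/``NOT`` (equivalently ``&``/``|``/``!``) with
    parentheses. Tables are compiled by exhaustive evaluation. Nodes that
    are referenced but never assigned become input nodes (clamped 0).

Neither dialect lists input nodes explicitly: a node with no table is an
input node and is clamped OFF unless a clamp directive (or the programmatic
API) says otherwise.
"""

from __future__ import annotations

import io as _io
import re
from typing import IO, Iterable

from .model import BooleanNetwork, Edge, LogicTable, NetworkFormatError

FORMATS = ("truthtable_csv", "expr")


def parse_network(text: str | IO[str], format: str = "truthtable_csv") -> BooleanNetwork:
    """Parse a Boolean network from text in the named dialect."""
    if hasattr(text, "read"):
        text = text.read()
    if format == "truthtable_csv":
        return _parse_truthtable_csv(text)
    if format == "expr":
        return _parse_expr(text)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def write_network(net: BooleanNetwork, format: str = "truthtable_csv") -> str:
    """Serialize a network; ``parse_network(write_network(net))`` round-trips
    nodes, edges, tables and clamps exactly (expr output only for networks
    whose tables were compiled from expressions is not required — the
    truth-table dialect is the lossless one and expr emission uses a
    disjunctive normal form)."""
    if format == "truthtable_csv":
        return _write_truthtable_csv(net)
    if format == "expr":
        return _write_expr(net)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_network(path, format: str = "truthtable_csv") -> BooleanNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_network(fh, format)


def save_network(net: BooleanNetwork, path, format: str = "truthtable_csv") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_network(net, format))


# ---------------------------------------------------------------------------
# truth-table CSV dialect
# ---------------------------------------------------------------------------

def _parse_truthtable_csv(text: str) -> BooleanNetwork:
    lines = text.splitlines()
    tables: dict[str, LogicTable] = {}
    clamps: dict[str, int] = {}
    order: list[str] = []
    declared_order: list[str] = []

    def note_node(n: str):
        if n not in order:
            order.append(n)

    i = 0
    while i < len(lines):
        lineno = i + 1
        raw = lines[i]
        stripped = raw.strip()
        i += 1
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = re.match(r"#\s*clamp:\s*(\S+)\s*=\s*([01])\s*$", stripped)
            if m:
                clamps[m.group(1)] = int(m.group(2))
            m = re.match(r"#\s*nodes:\s*(\S.*)$", stripped)
            if m:
                for nn in m.group(1).split(","):
                    if nn.strip():
                        declared_order.append(nn.strip())
            m = re.match(r"#\s*node:\s*(\S+)\s*$", stripped)
            if m:
                note_node(m.group(1))
            continue
        fields = [f.strip() for f in stripped.split(",")]
        target, inputs = fields[0], fields[1:]
        if not target:
            raise NetworkFormatError("empty node id in header", lineno)
        if target in tables:
            raise NetworkFormatError(f"duplicate node {target!r}", lineno)
        k = len(inputs)
        rows: dict[int, int] = {}
        for r in range(2**k):
            while i < len(lines) and (not lines[i].strip() or lines[i].strip().startswith("#")):
                i += 1
            if i >= len(lines):
                raise NetworkFormatError(
                    f"table for {target!r}: expected {2**k} rows, got {r}", lineno
                )
            row_lineno = i + 1
            row = [f.strip() for f in lines[i].split(",")]
            i += 1
            if len(row) != k + 1:
                raise NetworkFormatError(
                    f"table row for {target!r} has {len(row)} fields, expected {k + 1}",
                    row_lineno,
                )
            try:
                bits = [int(b) for b in row]
            except ValueError:
                raise NetworkFormatError(
                    f"non-binary symbol in table row for {target!r}", row_lineno
                ) from None
            if any(b not in (0, 1) for b in bits):
                raise NetworkFormatError(
                    f"non-binary output symbol in table row for {target!r}", row_lineno
                )
            idx = 0
            for b in bits[:-1]:
                idx = (idx << 1) | b
            if idx in rows:
                raise NetworkFormatError(
                    f"duplicate input combination in table for {target!r}", row_lineno
                )
            rows[idx] = bits[-1]
        note_node(target)
        for u in inputs:
            note_node(u)
        try:
            tables[target] = LogicTable(
                target, tuple(inputs), tuple(rows[j] for j in range(2**k))
            )
        except ValueError as exc:
            raise NetworkFormatError(str(exc), lineno) from None
    if declared_order and set(declared_order) >= set(order):
        order = declared_order
    net = BooleanNetwork(order, tables)
    for n, v in clamps.items():
        if n not in net.clamp:
            raise NetworkFormatError(f"clamp directive for non-input node {n!r}")
    return net.with_clamp(**clamps) if clamps else net


def _write_truthtable_csv(net: BooleanNetwork) -> str:
    out = _io.StringIO()
    out.write("# nodes: " + ",".join(net.nodes) + "\n")
    for n in net.input_nodes:
        if net.clamp.get(n, 0) != 0:
            out.write(f"# clamp: {n}={net.clamp[n]}\n")
    first = True
    for n in net.nodes:
        t = net.tables.get(n)
        if t is None:
            continue
        if not first:
            out.write("\n")
        first = False
        out.write(",".join((t.target,) + t.inputs) + "\n")
        for idx in range(2**t.k):
            bits = [(idx >> (t.k - 1 - j)) & 1 for j in range(t.k)]
            out.write(",".join(str(b) for b in bits + [t.outputs[idx]]) + "\n")
    # input nodes that appear in no table (fully isolated) would be lost;
    # record them so the node set round-trips
    referenced = {u for t in net.tables.values() for u in t.inputs} | set(net.tables)
    for n in net.nodes:
        if n not in referenced:
            out.write(f"# node: {n}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# expression dialect
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<and>AND\b|&&?|\*)|(?P<or>OR\b|\|\|?|\+)|(?P<not>NOT\b|!|~)"
    r"|(?P<lp>\()|(?P<rp>\))|(?P<const>[01]\b)|(?P<name>[A-Za-z_][\w.\-]*))"
)


class _ExprParser:
    """Recursive-descent parser; precedence NOT > AND > OR."""

    def __init__(self, text: str, lineno: int):
        self.tokens = self._tokenize(text, lineno)
        self.pos = 0
        self.lineno = lineno
        self.names: list[str] = []

    def _tokenize(self, text: str, lineno: int):
        tokens, i = [], 0
        while i < len(text):
            if text[i].isspace():
                i += 1
                continue
            m = _TOKEN_RE.match(text, i)
            if not m or m.start() != i:
                raise NetworkFormatError(f"bad token at {text[i:]!r}", lineno)
            kind = m.lastgroup
            tokens.append((kind, m.group(kind)))
            i = m.end()
        return tokens

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self.pos != len(self.tokens):
            raise NetworkFormatError("trailing tokens in expression", self.lineno)
        return node

    def _or(self):
        left = self._and()
        while self._peek() == "or":
            self._next()
            left = ("or", left, self._and())
        return left

    def _and(self):
        left = self._unary()
        while self._peek() == "and":
            self._next()
            left = ("and", left, self._unary())
        return left

    def _unary(self):
        kind = self._peek()
        if kind == "not":
            self._next()
            return ("not", self._unary())
        if kind == "lp":
            self._next()
            inner = self._or()
            if self._peek() != "rp":
                raise NetworkFormatError("unbalanced parentheses", self.lineno)
            self._next()
            return inner
        if kind == "const":
            return ("const", int(self._next()[1]))
        if kind == "name":
            name = self._next()[1]
            if name not in self.names:
                self.names.append(name)
            return ("var", name)
        raise NetworkFormatError("expected operand", self.lineno)


def _eval_ast(ast, env: dict[str, int]) -> int:
    op = ast[0]
    if op == "var":
        return env[ast[1]]
    if op == "const":
        return ast[1]
    if op == "not":
        return 1 - _eval_ast(ast[1], env)
    if op == "and":
        return _eval_ast(ast[1], env) & _eval_ast(ast[2], env)
    return _eval_ast(ast[1], env) | _eval_ast(ast[2], env)


def _parse_expr(text: str) -> BooleanNetwork:
    tables: dict[str, LogicTable] = {}
    clamps: dict[str, int] = {}
    order: list[str] = []
    declared_order: list[str] = []

    def note(n):
        if n not in order:
            order.append(n)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = re.match(r"#\s*clamp:\s*(\S+)\s*=\s*([01])\s*$", stripped)
            if m:
                clamps[m.group(1)] = int(m.group(2))
            m = re.match(r"#\s*nodes:\s*(\S.*)$", stripped)
            if m:
                for nn in m.group(1).split(","):
                    if nn.strip():
                        declared_order.append(nn.strip())
            m = re.match(r"#\s*node:\s*(\S+)\s*$", stripped)
            if m:
                note(m.group(1))
            continue
        if "=" not in stripped:
            raise NetworkFormatError("expected 'target = expression'", lineno)
        target, expr = stripped.split("=", 1)
        target = target.strip()
        if not target:
            raise NetworkFormatError("empty target node id", lineno)
        if target in tables:
            raise NetworkFormatError(f"duplicate node {target!r}", lineno)
        parser = _ExprParser(expr, lineno)
        ast = parser.parse()
        inputs = tuple(parser.names)
        note(target)
        for u in inputs:
            note(u)
        outputs = []
        for idx in range(2 ** len(inputs)):
            env = {
                u: (idx >> (len(inputs) - 1 - j)) & 1 for j, u in enumerate(inputs)
            }
            outputs.append(_eval_ast(ast, env))
        tables[target] = LogicTable(target, inputs, tuple(outputs))
    if declared_order and set(declared_order) >= set(order):
        order = declared_order
    net = BooleanNetwork(order, tables)
    for n in clamps:
        if n not in net.clamp:
            raise NetworkFormatError(f"clamp directive for non-input node {n!r}")
    return net.with_clamp(**clamps) if clamps else net


def _write_expr(net: BooleanNetwork) -> str:
    """Emit each table as a disjunctive normal form expression."""
    out = _io.StringIO()
    out.write("# nodes: " + ",".join(net.nodes) + "\n")
    for n in net.input_nodes:
        if net.clamp.get(n, 0) != 0:
            out.write(f"# clamp: {n}={net.clamp[n]}\n")
    for n in net.nodes:
        t = net.tables.get(n)
        if t is None:
            continue
        terms = []
        for idx, bit in enumerate(t.outputs):
            if not bit:
                continue
            lits = []
            for j, u in enumerate(t.inputs):
                v = (idx >> (t.k - 1 - j)) & 1
                lits.append(u if v else f"!{u}")
            terms.append(" & ".join(lits) if lits else "1")
        if terms:
            expr = " | ".join(f"({term})" for term in terms)
        elif t.inputs:
            # constant-0 table: keep inputs referenced so edges round-trip
            expr = "0 & " + " & ".join(t.inputs)
        else:
            expr = "0"
        out.write(f"{n} = {expr}\n")
    referenced = {u for t in net.tables.values() for u in t.inputs} | set(net.tables)
    for n in net.nodes:
        if n not in referenced:
            out.write(f"# node: {n}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# edge-class TSV
# ---------------------------------------------------------------------------

def write_edge_classes(
    edges: Iterable[Edge],
    classes: dict[Edge, str] | None = None,
) -> str:
    """Edge-list TSV ``source<TAB>target<TAB>class`` with class in
    {core, neighbor, unassigned}; edges sorted lexicographically."""
    classes = classes or {}
    out = _io.StringIO()
    for e in sorted(edges):
        cls = classes.get(e, "unassigned")
        if cls not in ("core", "neighbor", "unassigned"):
            raise ValueError(f"bad edge class {cls!r} for {e}")
        out.write(f"{e[0]}\t{e[1]}\t{cls}\n")
    return out.getvalue()


def read_edge_classes(text: str | IO[str]) -> dict[Edge, str]:
    if hasattr(text, "read"):
        text = text.read()
    result: dict[Edge, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise NetworkFormatError("expected source<TAB>target<TAB>class", lineno)
        result[(parts[0], parts[1])] = parts[2]
    return result
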