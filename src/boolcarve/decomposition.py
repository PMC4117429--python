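"""Decomposition of a Boolean network into evolvable core and robust neighbor.

The decomposition partitions the edge set by the effect of single-edge
deletion on the primary attractor. An edge whose deletion (anywhere along
the randomized reduction sequence) leaves every sampled basin state
converging to the original primary attractor belongs to the *robust
neighbor*; the minimal remaining sub-network — in which no further single
edge can be deleted without losing the primary attractor — is the
*evolvable core*.

Edge deletion is defined through the reduced logic table: removing edge
(v_i, v_j) replaces the table of v_j by its projection with the input v_i
fixed at a constant (0 by default, matching the nominal inputs-OFF
condition). Edges whose two projections coincide (l_0 = l_1, "insignificant"
edges) never influence the target and are removed up front; their deletion
provably leaves the full synchronous transition map bit-identical.

Procedure:

1. estimate the attractor landscape and identify the primary attractor;
2. sample initial states from the primary basin once, on the original
   network — the same panel is reused for every preservation test;
3. strip all insignificant edges;
4. screen the remaining edges: the candidate set holds every edge whose
   single deletion preserves the primary for all sampled states;
5. repeatedly draw a uniformly random candidate, re-test it on the current
   reduced network, delete it if the primary is still preserved, otherwise
   discard it; when the candidate set empties, rebuild it on the current
   network;
6. stop when a rebuild finds no deletable edge.

Two seeds govern all randomness: one for initial-state/basin sampling, one
for the deletion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .attractors import (
    Attractor,
    AttractorLandscape,
    canonical_cycle,
    find_attractors,
    sample_basin_states,
)
from .dynamics import HorizonExceededError, canonical_ints, compile_network
from .model import BooleanNetwork, Edge, LogicTable, State


# ---------------------------------------------------------------------------
# edge-level primitives
# ---------------------------------------------------------------------------

def reduced_table(table: LogicTable, input_id: str, value: int) -> LogicTable:
    """Logic table l_x: one input fixed at ``value`` and projected out."""
    return table.reduce(input_id, value)


def is_insignificant(net: BooleanNetwork, edge: Edge) -> bool:
    """True iff the edge's source never changes the target's output
    (the two reduced tables l_0 and l_1 coincide)."""
    u, v = edge
    if edge not in net.edges:
        raise KeyError(f"edge {edge} not in network")
    return net.tables[v].is_fictitious(u)


def delete_edge(net: BooleanNetwork, edge: Edge, value: int = 0) -> BooleanNetwork:
    """Network with the edge removed: the target's table is projected with
    the source input fixed at ``value``. Node set unchanged; deleting a
    node's last input leaves a 0-input constant node."""
    u, v = edge
    if edge not in net.edges:
        raise KeyError(f"edge {edge} not in network")
    return net.with_table(net.tables[v].reduce(u, value))


def preserves_primary(
    net_candidate: BooleanNetwork,
    basin_states: list[State],
    primary: Attractor,
    max_steps: int = 10_000,
    fraction: float = 1.0,
) -> bool:
    """True iff at least ``fraction`` (default: all) of the basin states
    reach a cycle canonically equal to ``primary`` in the candidate network.
    A horizon-exceeded trajectory counts as not preserved."""
    c = compile_network(net_candidate)
    key = canonical_ints([c.pack(s) for s in primary.states])
    cache: dict[int, tuple[int, ...]] = {}
    n = len(basin_states)
    allowed_misses = int(np.floor((1.0 - fraction) * n + 1e-9))
    misses = 0
    for s in basin_states:
        try:
            ok = c.attractor_key(c.apply_clamps(c.pack(s)), max_steps, cache) == key
        except HorizonExceededError:
            ok = False
        if not ok:
            misses += 1
            if misses > allowed_misses:
                return False
    return True


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    core_edges: frozenset[Edge]
    neighbor_edges: frozenset[Edge]
    provenance: dict[Edge, str]  # insignificant | candidate_deleted | retained
    deletion_order: list[Edge]
    seeds: dict[str, int | None]
    sample_size: int
    primary: Attractor = None
    landscape: AttractorLandscape = None

    @property
    def edges(self) -> frozenset[Edge]:
        return self.core_edges | self.neighbor_edges


@dataclass
class NodeScores:
    """Per-node fractions of incident edges in the core (evolvability) and
    neighbor (robustness); they sum to 1 for any node with incident edges."""

    evolvability: dict[str, float]
    robustness: dict[str, float]


def decompose(
    net: BooleanNetwork,
    n_samples: int = 10_000,
    seed_init: int | None = 0,
    seed_order: int | None = 0,
    max_steps: int = 10_000,
    deletion_value: int = 0,
    preserve_fraction: float = 1.0,
    landscape: AttractorLandscape | None = None,
) -> Decomposition:
    """Run the full randomized reduction and return the edge partition.

    ``seed_init`` drives initial-state and basin sampling; ``seed_order``
    drives the random deletion order. ``landscape`` may be supplied to reuse
    a previously estimated landscape (it must come from the same network).
    """
    if landscape is None:
        landscape = find_attractors(net, n_samples, seed_init, max_steps)
    prim = landscape.primary
    basin_states = sample_basin_states(
        net, prim, n_samples,
        seed=None if seed_init is None else seed_init + 1,
        max_steps=max_steps,
    )

    provenance: dict[Edge, str] = {}
    deletion_order: list[Edge] = []
    current = net

    # strip insignificant edges to fixpoint (projection can expose new ones)
    changed = True
    while changed:
        changed = False
        for e in sorted(current.edges):
            if is_insignificant(current, e):
                current = delete_edge(current, e, deletion_value)
                provenance[e] = "insignificant"
                deletion_order.append(e)
                changed = True

    rng = np.random.default_rng(seed_order)
    while True:
        candidates = [
            e
            for e in sorted(current.edges)
            if preserves_primary(
                delete_edge(current, e, deletion_value),
                basin_states, prim, max_steps, preserve_fraction,
            )
        ]
        if not candidates:
            break
        deleted_any = False
        while candidates:
            i = int(rng.integers(len(candidates)))
            e = candidates.pop(i)
            trial = delete_edge(current, e, deletion_value)
            if preserves_primary(trial, basin_states, prim, max_steps, preserve_fraction):
                current = trial
                provenance[e] = "candidate_deleted"
                deletion_order.append(e)
                deleted_any = True
        if not deleted_any:
            break

    core = frozenset(current.edges)
    neighbor = frozenset(net.edges - core)
    for e in core:
        provenance[e] = "retained"
    return Decomposition(
        core_edges=core,
        neighbor_edges=neighbor,
        provenance=provenance,
        deletion_order=deletion_order,
        seeds={"initial_state_seed": seed_init, "deletion_seed": seed_order},
        sample_size=n_samples,
        primary=prim,
        landscape=landscape,
    )


def node_scores(net: BooleanNetwork, decomposition: Decomposition) -> NodeScores:
    """Evolvability = fraction of a node's incident (in or out) edges that
    are core; robustness is the complement. Isolated nodes are absent."""
    evolvability: dict[str, float] = {}
    robustness: dict[str, float] = {}
    for v in net.nodes:
        incident = {e for e in net.edges if v in e}
        if not incident:
            continue
        n_core = len(incident & decomposition.core_edges)
        evolvability[v] = n_core / len(incident)
        robustness[v] = 1.0 - evolvability[v]
    return NodeScores(evolvability, robustness)


# ---------------------------------------------------------------------------
# verification / comparison / novelty
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    core_preserves: bool
    minimal: bool
    partition_ok: bool
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.core_preserves and self.minimal and self.partition_ok


def core_network(
    net: BooleanNetwork, decomposition: Decomposition, deletion_value: int = 0
) -> BooleanNetwork:
    """Original network with every neighbor edge deleted (projections
    commute, so the deletion order is irrelevant)."""
    current = net
    for e in sorted(decomposition.neighbor_edges):
        current = delete_edge(current, e, deletion_value)
    return current


def verify_decomposition(
    net: BooleanNetwork,
    decomposition: Decomposition,
    basin_states: list[State],
    max_steps: int = 10_000,
    deletion_value: int = 0,
) -> VerificationReport:
    """Check the definitional contracts of a decomposition:

    (a) the core sub-network preserves the primary for every basin state;
    (b) minimality — no single core edge can still be deleted;
    (c) core and neighbor partition the original edge set with consistent
        provenance.
    """
    failures: list[str] = []
    prim = decomposition.primary
    cn = core_network(net, decomposition, deletion_value)
    core_ok = preserves_primary(cn, basin_states, prim, max_steps)
    if not core_ok:
        failures.append("core network does not preserve the primary attractor")
    minimal = True
    for e in sorted(decomposition.core_edges):
        if preserves_primary(
            delete_edge(cn, e, deletion_value), basin_states, prim, max_steps
        ):
            minimal = False
            failures.append(f"core edge {e} is still deletable")
    partition_ok = True
    if decomposition.core_edges | decomposition.neighbor_edges != net.edges:
        partition_ok = False
        failures.append("core ∪ neighbor != original edge set")
    if decomposition.core_edges & decomposition.neighbor_edges:
        partition_ok = False
        failures.append("core ∩ neighbor nonempty")
    for e in decomposition.core_edges:
        if decomposition.provenance.get(e) != "retained":
            partition_ok = False
            failures.append(f"core edge {e} has provenance {decomposition.provenance.get(e)}")
    for e in decomposition.neighbor_edges:
        if decomposition.provenance.get(e) not in ("insignificant", "candidate_deleted"):
            partition_ok = False
            failures.append(
                f"neighbor edge {e} has provenance {decomposition.provenance.get(e)}"
            )
    return VerificationReport(core_ok, minimal, partition_ok, failures)


def decomposition_overlap_test(d1: Decomposition, d2: Decomposition) -> dict:
    """Agreement of two decompositions over the same edge universe.

    Returns the 2x2 core/neighbor contingency table, the (uncorrected)
    chi-square statistic with its one-sided p-value for positive
    association, and the Jaccard index of the two core sets.
    """
    if d1.edges != d2.edges:
        raise ValueError("decompositions cover different edge universes")
    a = len(d1.core_edges & d2.core_edges)
    b = len(d1.core_edges & d2.neighbor_edges)
    c = len(d1.neighbor_edges & d2.core_edges)
    d = len(d1.neighbor_edges & d2.neighbor_edges)
    table = np.array([[a, b], [c, d]])
    chi2, p_two = _chi2_2x2(table)
    # one-sided: small p only when agreement exceeds independence expectation
    n = table.sum()
    expected_a = table[0].sum() * table[:, 0].sum() / n if n else 0.0
    p_one = p_two / 2 if a >= expected_a else 1 - p_two / 2
    union = len(d1.core_edges | d2.core_edges)
    jaccard = len(d1.core_edges & d2.core_edges) / union if union else 1.0
    return {"table": table, "chi2": chi2, "p": p_one, "jaccard": jaccard}


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    if table.sum() == 0 or 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def perturbation_novelty(
    net: BooleanNetwork,
    decomposition: Decomposition,
    basin_states: list[State],
    landscape: AttractorLandscape | None = None,
    max_steps: int = 10_000,
    deletion_value: int = 0,
) -> dict:
    """Attractor novelty generated by single core-edge deletions.

    Each core edge is deleted from the original network and every basin
    state is re-run; attractors different from the original primary are
    collected per edge. The report gives the per-edge sets, the number of
    distinct non-primary attractors over all deletions, and the fraction of
    those absent from the original network's attractor list.
    """
    if not decomposition.core_edges:
        raise ValueError("decomposition has no core edges")
    if landscape is None:
        landscape = decomposition.landscape
    original = {a.states for a in landscape.attractors}
    c0 = compile_network(net)
    prim_key = tuple(decomposition.primary.states)
    per_edge: dict[Edge, set] = {}
    horizon_failures = 0
    for e in sorted(decomposition.core_edges):
        sub = delete_edge(net, e, deletion_value)
        c = compile_network(sub)
        cache: dict[int, tuple[int, ...]] = {}
        found: set = set()
        for s in basin_states:
            try:
                key = c.attractor_key(c.apply_clamps(c.pack(s)), max_steps, cache)
            except HorizonExceededError:
                horizon_failures += 1
                continue
            states = tuple(c.unpack(x) for x in key)
            if states != prim_key:
                found.add(states)
        per_edge[e] = found
    all_found = set().union(*per_edge.values()) if per_edge else set()
    novel = {a for a in all_found if a not in original}
    return {
        "per_edge": per_edge,
        "total_new_attractors": len(all_found),
        "fraction_novel": len(novel) / len(all_found) if all_found else 0.0,
        "horizon_failures": horizon_failures,
    }
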