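"""Gene-level scores, group enrichment, and correlation with gene properties.

Network nodes are mapped to genes (a node may map to several genes and a
gene may aggregate several nodes — protein complexes, isoform families). A
gene's evolvability/robustness score is the mean of the scores of the nodes
mapping to it. Group enrichment compares a gene group's mean score to the
universe mean (the *normalized* group score) and assesses it with a
permutation test that redraws random groups of the same size from the
universe; correlations with numeric gene properties (dN/dS evolutionary
rate, species broadness, ...) use Pearson's test with pairwise deletion of
missing values.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import NodeScores


@dataclass
class GeneScoreTable:
    """Gene-level scores plus optional properties and group memberships."""

    scores: pd.DataFrame  # index: gene; columns: evolvability, robustness
    node_map: dict[str, list[str]]  # gene -> contributing nodes
    properties: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene x property
    groups: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class EnrichmentResult:
    group: str
    which: str
    normalized_score: float
    p_value: float
    n_permutations: int
    group_size: int
    universe_size: int


def gene_scores(
    node_scores: NodeScores, mapping: Mapping[str, list[str] | str]
) -> GeneScoreTable:
    """Aggregate node scores to genes: a gene's score is the mean over the
    nodes that map to it; genes with no scored node are absent."""
    if not mapping:
        raise ValueError("empty node-to-gene mapping")
    node_map: dict[str, list[str]] = {}
    for node, genes in mapping.items():
        if isinstance(genes, str):
            genes = [genes]
        for g in genes:
            node_map.setdefault(g, []).append(node)
    rows = {}
    for g, nodes in node_map.items():
        evs = [node_scores.evolvability[n] for n in nodes if n in node_scores.evolvability]
        if not evs:
            continue
        rbs = [node_scores.robustness[n] for n in nodes if n in node_scores.robustness]
        rows[g] = {"evolvability": float(np.mean(evs)), "robustness": float(np.mean(rbs))}
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return GeneScoreTable(frame, {g: node_map[g] for g in frame.index})


def normalized_group_score(table: GeneScoreTable, group, which: str) -> float:
    """Group mean divided by universe mean of the chosen score."""
    genes = _group_genes(table, group)
    universe_mean = table.scores[which].mean()
    if universe_mean == 0:
        raise ZeroDivisionError("universe mean score is zero")
    return float(table.scores.loc[sorted(genes), which].mean() / universe_mean)


def _group_genes(table: GeneScoreTable, group) -> set[str]:
    if isinstance(group, str):
        members = table.groups.get(group)
        if members is None:
            raise KeyError(f"unknown group {group!r}")
    else:
        members = set(group)
    genes = members & set(table.genes)
    if not genes:
        raise ValueError("group has no genes in the score universe")
    return genes


def permutation_test(
    table: GeneScoreTable,
    group,
    which: str = "evolvability",
    n_perm: int = 100_000,
    seed=None,
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided permutation test of the group mean score.

    Random control groups of the same size are drawn without replacement
    from the score universe; the p-value uses the finite-sample +1
    correction, so it is bounded below by 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = _group_genes(table, group)
    scores = table.scores[which].to_numpy()
    n_universe, m = len(scores), len(genes)
    if m > n_universe:
        raise ValueError("group larger than universe")
    observed = float(table.scores.loc[sorted(genes), which].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n_universe, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n_universe))
        picks = np.argpartition(keys, m - 1, axis=1)[:, :m]
        means = scores[picks].mean(axis=1)
        if alternative == "greater":
            hits += int((means >= observed - 1e-12).sum())
        else:
            hits += int((means <= observed + 1e-12).sum())
        done += b
    p = (1 + hits) / (n_perm + 1)
    name = group if isinstance(group, str) else "<adhoc>"
    norm = normalized_group_score(table, group, which)
    return EnrichmentResult(name, which, norm, p, n_perm, m, n_universe)


def exact_permutation_p(
    scores: np.ndarray, group_size: int, observed_mean: float,
    alternative: str = "greater",
) -> float:
    """Exhaustive-enumeration tail probability over all equal-size groups
    (oracle for small universes; no finite-sample correction)."""
    means = [
        np.mean(c) for c in itertools.combinations(np.asarray(scores, float), group_size)
    ]
    means = np.array(means)
    if alternative == "greater":
        return float((means >= observed_mean - 1e-12).mean())
    return float((means <= observed_mean + 1e-12).mean())


def correlate(table: GeneScoreTable, property_name: str, which: str = "evolvability") -> dict:
    """Pearson correlation between a numeric gene property and the chosen
    score; genes missing the property are dropped pairwise."""
    if property_name not in table.properties.columns:
        raise KeyError(f"unknown property {property_name!r}")
    joined = table.scores[[which]].join(table.properties[[property_name]], how="inner")
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 genes with both values")
    x = joined[property_name].to_numpy()
    y = joined[which].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(joined)}


# ---------------------------------------------------------------------------
# annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(text: str | IO[str]) -> dict:
    """Parse the annotation TSV: one line per gene,
    ``gene<TAB>nodes(;)<TAB>prop:value(;)<TAB>groups(;)`` — later fields
    optional. Returns node->genes mapping, a property DataFrame, and group
    membership sets."""
    if hasattr(text, "read"):
        text = text.read()
    mapping: dict[str, list[str]] = {}
    props: dict[str, dict[str, float]] = {}
    groups: dict[str, set[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        gene = parts[0].strip()
        nodes = [n for n in re.split(r";", parts[1]) if n] if len(parts) > 1 else []
        for n in nodes:
            mapping.setdefault(n, []).append(gene)
        if len(parts) > 2 and parts[2].strip():
            for pair in parts[2].split(";"):
                if not pair.strip():
                    continue
                key, _, val = pair.partition(":")
                props.setdefault(gene, {})[key.strip()] = float(val)
        if len(parts) > 3 and parts[3].strip():
            for grp in parts[3].split(";"):
                if grp.strip():
                    groups.setdefault(grp.strip(), set()).add(gene)
    return {
        "mapping": mapping,
        "properties": pd.DataFrame.from_dict(props, orient="index"),
        "groups": groups,
    }


def annotate(table: GeneScoreTable, annotations: dict) -> GeneScoreTable:
    """Attach properties and groups parsed by :func:`read_annotations`."""
    return GeneScoreTable(
        table.scores, table.node_map, annotations["properties"], annotations["groups"]
    )
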