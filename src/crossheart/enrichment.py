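"""Gene-set over/under-representation by exact hypergeometric tests.

Given a selected gene list (the DEGs) and a background universe, each
module (GO term, pathway) is scored with one-sided hypergeometric tail
probabilities for over- and under-representation, and each family of
p-values is Benjamini-Hochberg adjusted separately — the convention of
ontology-tree enrichment tools that report each direction as its own
one-sided test.  An ontology DAG (is_a / part_of) can be used to propagate
gene annotations from descendants to ancestors before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crossheart")

__all__ = [
    "ModuleCollection",
    "read_gmt",
    "read_obo_parents",
    "propagate_annotations",
    "hypergeom_test",
    "bh_adjust",
    "enrich",
]


@dataclass
class ModuleCollection:
    """Named gene sets over one species' identifier space.

    ``parents`` optionally maps a term to its DAG parents (for annotation
    propagation).
    """

    modules: Dict[str, Set[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)
    parents: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.modules.items():
            if not members:
                raise ValueError(f"module {name!r} is empty")
            self.modules[name] = set(members)

    def __len__(self) -> int:
        return len(self.modules)

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.modules.items()})

    def write_gmt(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, members in self.modules.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path: str) -> ModuleCollection:
    """Read a GMT file: name TAB description TAB member ids.

    Duplicate members inside a module count once; a duplicated module name
    is an error.
    """
    modules: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >=3 tab-separated fields, got {len(fields)})"
                )
            name, desc, *members = fields
            if name in modules:
                raise ValueError(f"{path}:{lineno}: duplicated module name {name!r}")
            members = {m for m in members if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: module {name!r} has no members")
            modules[name] = members
            descriptions[name] = desc
    if not modules:
        raise ValueError(f"{path}: empty GMT file")
    return ModuleCollection(modules, descriptions)


def read_obo_parents(path: str) -> Dict[str, Set[str]]:
    """Parse an OBO ontology into a child -> parents relation, following
    is_a and part_of edges only."""
    import obonet

    graph = obonet.read_obo(path)
    parents: Dict[str, Set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of"):
            parents.setdefault(child, set()).add(parent)
    return parents


def propagate_annotations(
    modules: ModuleCollection,
    parents: Optional[Mapping[str, Iterable[str]]] = None,
) -> ModuleCollection:
    """Propagate members up the DAG: each term's set becomes the union over
    itself and all of its descendants (the true-path rule)."""
    import networkx as nx

    rel = parents if parents is not None else modules.parents
    g = nx.DiGraph()
    g.add_nodes_from(modules.modules)
    for child, ps in rel.items():
        for p in ps:
            g.add_edge(child, p)  # edge child -> parent
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise ValueError(
            f"ontology relation contains a cycle (edge {cycle[0][0]!r} -> "
            f"{cycle[0][1]!r})"
        )
    out = {k: set(v) for k, v in modules.modules.items()}
    # children precede parents in the topological order of child->parent edges
    for node in order:
        for parent in g.successors(node):
            out.setdefault(parent, set()).update(out.get(node, set()))
    out = {k: v for k, v in out.items() if v}
    return ModuleCollection(
        out, dict(modules.descriptions), {k: set(v) for k, v in rel.items()}
    )


def hypergeom_test(N: int, K: int, n: int, k: int) -> tuple:
    """Exact one-sided hypergeometric tails.

    Universe of N genes of which K carry the annotation; n genes selected,
    k of them annotated.  Returns (p_over, p_under) with
    p_over = P(X >= k) and p_under = P(X <= k) for
    X ~ Hypergeom(N, K, n).  Computed by exact summation (scipy's sf/cdf),
    no normal approximation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside attainable range "
            f"[{max(0, n + K - N)}, {min(K, n)}] for N={N} K={K} n={n}"
        )
    dist = stats.hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))
    p_under = float(dist.cdf(k))
    return min(p_over, 1.0), min(p_under, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped
    at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    selected: Set[str],
    universe: Set[str],
    modules: ModuleCollection,
    alpha: float = 0.05,
    min_module_size: int = 5,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of every module among the
    selected genes, against the universe background.

    Module members are intersected with the universe before counting;
    modules smaller than ``min_module_size`` after intersection are skipped
    (logged).  Over- and under-representation p-value families are BH
    adjusted separately; rows are flagged significant at q < alpha and the
    table is sorted by q_over.
    """
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(
            f"{len(stray)} selected genes outside the universe, e.g. "
            f"{sorted(stray)[:5]}"
        )
    N, n = len(universe), len(selected)
    rows = []
    skipped = 0
    for name, members in modules.modules.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < min_module_size:
            skipped += 1
            continue
        k = len(in_universe & selected)
        p_over, p_under = hypergeom_test(N, K, n, k)
        rows.append(
            {
                "module": name,
                "description": modules.descriptions.get(name, ""),
                "universe_size": N,
                "module_size": K,
                "selected_size": n,
                "overlap": k,
                "p_over": p_over,
                "p_under": p_under,
            }
        )
    if skipped:
        logger.info(
            "enrich: skipped %d modules with <%d members in the universe",
            skipped, min_module_size,
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "module", "description", "universe_size", "module_size",
            "selected_size", "overlap", "p_over", "p_under",
        ],
    )
    if len(table):
        table["q_over"] = bh_adjust(table["p_over"])
        table["q_under"] = bh_adjust(table["p_under"])
        table["significant_over"] = table["q_over"] < alpha
        table["significant_under"] = table["q_under"] < alpha
        table = table.sort_values(
            ["q_over", "module"], kind="stable"
        ).reset_index(drop=True)
    else:
        for col in ("q_over", "q_under"):
            table[col] = pd.Series(dtype=float)
        for col in ("significant_over", "significant_under"):
            table[col] = pd.Series(dtype=bool)
    return table
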