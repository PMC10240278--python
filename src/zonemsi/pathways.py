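"""Pathway ranking by betweenness-centrality hit mass and hypergeometric ORA.

Pathways are small undirected graphs whose nodes are compounds or reactions.
A pathway's score for a hit list is the fraction of total compound-node
relative betweenness centrality carried by the hit compounds, in [0, 1]
(reaction nodes shape the topology but are never hits).  Over-representation
is assessed with the exact hypergeometric upper tail against the union of
all pathway compounds as background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class Pathway:
    """One named pathway graph over compound/reaction nodes."""

    name: str
    graph: nx.Graph
    compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.compounds:
            self.compounds = {n for n, d in self.graph.nodes(data=True)
                              if d.get("type", "compound") == "compound"}
        if not self.compounds:
            raise ValueError(f"pathway {self.name!r} has no compound nodes")


@dataclass
class PathwaySet:
    """A named collection of pathways plus the ORA background."""

    pathways: dict[str, Pathway]

    @property
    def background(self) -> set[str]:
        """Union of participating compounds across all pathways."""
        out: set[str] = set()
        for p in self.pathways.values():
            out |= p.compounds
        return out


def load_pathways(path: str | Path | None = None) -> PathwaySet:
    """Load a pathway set from JSON (defaults to the packaged fixture).

    Expected JSON: a list of objects with ``name``, ``nodes`` (list of
    ``{"id": ..., "type": "compound"|"reaction"}``) and ``edges`` (list of
    ``[source, target]`` pairs).
    """
    if path is None:
        ref = resources.files("zonemsi.data").joinpath("pathways.json")
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    pathways: dict[str, Pathway] = {}
    for item in raw:
        name = item["name"]
        if name in pathways:
            raise ValueError(f"duplicate pathway name {name!r}")
        g = nx.Graph()
        for node in item["nodes"]:
            g.add_node(node["id"], type=node.get("type", "compound"))
        for a, b in item["edges"]:
            if a not in g or b not in g:
                raise ValueError(f"pathway {name!r}: edge ({a}, {b}) "
                                 "references unknown node")
            g.add_edge(a, b)
        pathways[name] = Pathway(name=name, graph=g)
    return PathwaySet(pathways=pathways)


def relative_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Relative node betweenness centrality in [0, 1].

    For each node v, the sum over unordered pairs s != v != t of the
    fraction of shortest s–t paths through v, divided by the maximal pair
    count (N−1)(N−2)/2.  Disconnected graphs are scored per connected
    component with the component-level normaliser; components with fewer
    than 3 nodes contribute zeros.
    """
    result: dict[str, float] = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        if len(comp) < 3:
            continue
        sub = graph.subgraph(comp)
        result.update(nx.betweenness_centrality(sub, normalized=True))
    return result


def pathway_score(pathway: Pathway, hits: set[str]) -> float:
    """Hit-mass fraction of total compound-node betweenness, in [0, 1].

    Degenerate pathways whose compound nodes all have zero centrality
    (e.g. all compounds are leaves) score 0 and are logged.
    """
    centrality = relative_betweenness(pathway.graph)
    total = sum(centrality[c] for c in pathway.compounds)
    if total == 0.0:
        if hits & pathway.compounds:
            logger.warning("pathway %r: zero total compound centrality; "
                           "score degenerates to 0", pathway.name)
        return 0.0
    hit_mass = sum(centrality[c] for c in pathway.compounds & hits)
    return hit_mass / total


def hypergeometric_ora(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` hits among ``n`` drawn, ``K`` pathway compounds in a background
    of ``N``.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class PathwayScoreResult:
    pathway: str
    score: float
    ora_p: float
    hits: tuple[str, ...]
    k: int
    K: int
    n: int
    N: int


def rank_pathways(pathway_set: PathwaySet, significant_lipids: list[str],
                  lipid_to_compounds: dict[str, str | list[str]],
                  ) -> list[PathwayScoreResult]:
    """Score and rank all pathways for a significant-lipid list.

    Lipids map to class-level compound identifiers.  Results are sorted by
    descending centrality score, ties by ascending ORA p then name.  The
    ORA background is the union of all pathway compounds; hit compounds
    outside it are ignored for the test.
    """
    hits: set[str] = set()
    for lipid in significant_lipids:
        mapped = lipid_to_compounds.get(lipid)
        if mapped is None:
            continue
        if isinstance(mapped, str):
            hits.add(mapped)
        else:
            hits.update(mapped)
    background = pathway_set.background
    eff_hits = hits & background
    if not eff_hits:
        logger.warning("no hit compounds map into the pathway background; "
                       "all scores are 0")
    n = len(eff_hits)
    N = len(background)
    results = []
    for name, pw in sorted(pathway_set.pathways.items()):
        pw_hits = tuple(sorted(pw.compounds & eff_hits))
        k = len(pw_hits)
        K = len(pw.compounds & background)
        results.append(PathwayScoreResult(
            pathway=name, score=pathway_score(pw, eff_hits),
            ora_p=hypergeometric_ora(k, K, n, N) if n else 1.0,
            hits=pw_hits, k=k, K=K, n=n, N=N))
    results.sort(key=lambda r: (-r.score, r.ora_p, r.pathway))
    return results


def results_frame(results: list[PathwayScoreResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway": r.pathway, "score": r.score, "ora_p": r.ora_p,
        "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "hits": ";".join(r.hits),
    } for r in results])
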