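"""Contact difference maps between conditions, and transmission-pathway
extraction from high-persistence contact networks.

A difference map compares ligand-bound vs apo persistence with two noise
floors: a pair is retained only when its larger persistence reaches the
persistence floor AND the absolute change reaches the delta floor (both
default 0.10). The floor rule uses the larger of the two persistences, so
contacts gained only upon ligand binding survive and the retained set is
the same in either comparison direction (deltas negate).

Candidate allosteric routes are ranked by the widest-path (maximum
bottleneck) criterion: among source→target paths, maximize the minimum
edge persistence, breaking ties by shorter length then lexicographic
residue order.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .contacts import ContactMap, PairKey
from .errors import ComparisonError, ParameterError
from .system import ResidueKey

__all__ = [
    "DiffMap",
    "PathwayGraph",
    "PathwayResult",
    "difference_map",
    "build_pathway_graph",
    "find_pathways",
    "diff_map_to_table",
]


@dataclass
class DiffMap:
    """Thresholded persistence differences between two conditions."""

    condition_ligand: str
    condition_apo: str
    entries: dict[PairKey, tuple[float, float, float]]  # (p_apo, p_ligand, delta)
    persistence_floor: float
    delta_floor: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, (p_apo, p_lig, delta) in self.entries.items():
            if max(p_apo, p_lig) < self.persistence_floor:
                raise ParameterError(f"{pair}: retained below persistence floor")
            if abs(delta) < self.delta_floor:
                raise ParameterError(f"{pair}: retained below delta floor")


_PROVENANCE_KEYS = ("cutoff", "exclude_time", "stride_time")


def difference_map(map_ligand: ContactMap, map_apo: ContactMap,
                   persistence_floor: float = 0.10,
                   delta_floor: float = 0.10,
                   condition_ligand: str = "ligand",
                   condition_apo: str = "apo") -> DiffMap:
    """Per-pair persistence change ``delta = p_ligand - p_apo`` after noise
    thresholds.

    The two maps must describe the same interface with the same analysis
    settings, and the caller asserts that both conditions are in the same
    gating state. A pair missing from one map contributes persistence 0.
    """
    if map_ligand.interface != map_apo.interface:
        raise ComparisonError(
            f"interface mismatch: {map_ligand.interface} vs {map_apo.interface}")
    for k in _PROVENANCE_KEYS:
        a = map_ligand.provenance.get(k)
        b = map_apo.provenance.get(k)
        if a is not None and b is not None and a != b:
            raise ComparisonError(f"provenance mismatch on {k}: {a} vs {b}")
    if not (0 <= persistence_floor <= 1 and 0 <= delta_floor <= 1):
        raise ParameterError("floors must lie in [0, 1]")

    def canon(pair: PairKey) -> PairKey:
        return pair if pair[0] <= pair[1] else (pair[1], pair[0])

    lig = {canon(p): v for p, v in map_ligand.entries.items()}
    apo = {canon(p): v for p, v in map_apo.entries.items()}
    entries: dict[PairKey, tuple[float, float, float]] = {}
    for pair in sorted(set(lig) | set(apo)):
        p_lig = lig.get(pair, 0.0)
        p_apo = apo.get(pair, 0.0)
        delta = p_lig - p_apo
        if max(p_apo, p_lig) < persistence_floor:
            continue
        if abs(delta) < delta_floor:
            continue
        entries[pair] = (p_apo, p_lig, delta)
    prov = {k: map_ligand.provenance.get(k, map_apo.provenance.get(k))
            for k in _PROVENANCE_KEYS}
    return DiffMap(condition_ligand=condition_ligand, condition_apo=condition_apo,
                   entries=entries, persistence_floor=persistence_floor,
                   delta_floor=delta_floor, provenance=prov)


def diff_map_to_table(dmap: DiffMap) -> pd.DataFrame:
    rows = []
    for (ra, rb), (p_apo, p_lig, delta) in dmap.entries.items():
        rows.append(dict(chainA=ra[0], residA=ra[1], resnameA=ra[2],
                         chainB=rb[0], residB=rb[1], resnameB=rb[2],
                         p_apo=p_apo, p_ligand=p_lig, delta=delta))
    df = pd.DataFrame(rows, columns=["chainA", "residA", "resnameA",
                                     "chainB", "residB", "resnameB",
                                     "p_apo", "p_ligand", "delta"])
    return df.sort_values(["chainA", "residA", "chainB", "residB"],
                          kind="mergesort").reset_index(drop=True)


@dataclass
class PathwayGraph:
    """Undirected residue graph with persistence-weighted edges."""

    graph: nx.Graph
    sources: list[ResidueKey] = field(default_factory=list)
    targets: list[ResidueKey] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def build_pathway_graph(maps: Sequence[ContactMap],
                        edge_threshold: float = 0.50,
                        sources: Sequence[ResidueKey | tuple[str, int]] = (),
                        targets: Sequence[ResidueKey | tuple[str, int]] = (),
                        ) -> PathwayGraph:
    """Graph of all residue pairs with persistence >= ``edge_threshold``.

    Multiple maps may be supplied to chain interfaces (e.g. TARP–GluA2 and
    GluA2–GluA1); if the same pair occurs in several maps the largest
    persistence wins. Declared source/target residues are added as nodes
    even when isolated.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise ParameterError(f"edge_threshold={edge_threshold} outside [0, 1]")
    g = nx.Graph()
    for cmap in maps:
        for (ra, rb), frac in cmap.entries.items():
            if frac >= edge_threshold:
                if g.has_edge(ra, rb):
                    g[ra][rb]["weight"] = max(g[ra][rb]["weight"], frac)
                else:
                    g.add_edge(ra, rb, weight=frac)

    def resolve(declared) -> list[ResidueKey]:
        out = []
        for res in declared:
            if len(res) == 3:
                out.append(tuple(res))
                continue
            chain, resid = res
            matches = [n for n in g.nodes
                       if n[0] == chain and n[1] == resid]
            if matches:
                out.extend(sorted(matches))
            else:
                warnings.warn(f"declared residue {chain}:{resid} absent from "
                              "graph; treated as isolated")
                out.append((chain, resid, "UNK"))
        return out

    src = resolve(sources)
    tgt = resolve(targets)
    for n in src + tgt:
        g.add_node(n)
    return PathwayGraph(graph=g, sources=src, targets=tgt,
                        provenance=dict(edge_threshold=edge_threshold,
                                        n_maps=len(maps),
                                        interfaces=[m.interface for m in maps]))


@dataclass
class PathwayResult:
    residues: list[ResidueKey]
    bottleneck: float


def _k_widest_paths(g: nx.Graph, source: ResidueKey, target: ResidueKey,
                    k: int, max_pops: int = 200_000,
                    ) -> list[tuple[float, list[ResidueKey]]]:
    """Up to k maximum-bottleneck simple paths by best-first enumeration.

    The search key (−bottleneck, length, path) is monotone non-decreasing
    along edge extensions, so target pops occur in optimal order including
    the shorter-then-lexicographic tie-breaks; the first pop is the widest
    path. Expansion is capped for pathological dense graphs.
    """
    if source not in g or target not in g:
        return []
    heap = [(-float("inf"), 0, (source,))]
    found: list[tuple[float, list[ResidueKey]]] = []
    pops = 0
    while heap and len(found) < k and pops < max_pops:
        neg_b, length, path = heapq.heappop(heap)
        pops += 1
        node = path[-1]
        if node == target:
            if neg_b != -float("inf"):
                found.append((-neg_b, list(path)))
            continue
        for nbr, data in sorted(g[node].items()):
            if nbr in path:
                continue
            nb = max(neg_b, -data["weight"])
            heapq.heappush(heap, (nb, length + 1, path + (nbr,)))
    if pops >= max_pops:
        warnings.warn("pathway search truncated at expansion cap; "
                      "returned paths may be incomplete beyond the best one")
    return found


def find_pathways(pgraph: PathwayGraph, k: int = 3) -> list[PathwayResult]:
    """Up to ``k`` source→target paths ranked by bottleneck persistence.

    For every (source, target) combination the widest (maximum-bottleneck)
    simple path is computed; distinct paths are ranked by bottleneck
    (descending), then path length, then lexicographic residue order.
    Disconnected pairs contribute nothing; an empty list means no source
    reaches any target.
    """
    if not pgraph.sources or not pgraph.targets:
        raise ParameterError("source and target sets must be non-empty")
    results: dict[tuple, float] = {}
    for s in pgraph.sources:
        for t in pgraph.targets:
            if s == t:
                continue
            for bottleneck, path in _k_widest_paths(pgraph.graph, s, t, k):
                if len(path) >= 2:
                    results[tuple(path)] = bottleneck
    ranked = sorted(results.items(),
                    key=lambda item: (-item[1], len(item[0]), item[0]))
    return [PathwayResult(residues=list(path), bottleneck=b)
            for path, b in ranked[:k]]
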