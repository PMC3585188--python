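"""Median-joining haplotype networks (Bandelt, Forster & Röhl 1999).

The network starts from the minimum spanning network (MSN) of the observed
haplotypes at tolerance ``epsilon`` and iteratively adds *median vectors* —
per-site majority consensus sequences of connected triplets — whenever they
shorten the connections, until closure; superfluous medians are then pruned.
Median vectors stand for unsampled (extinct or missed) intermediate
haplotypes; loops reflect ambiguity the data cannot resolve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import AlignmentError, PopmapError
from .seqio import HaplotypeTable

_MAX_ROUNDS = 64


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def _dist_matrix(seq_arrays: list[np.ndarray]) -> np.ndarray:
    n = len(seq_arrays)
    M = np.vstack(seq_arrays)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        D[i] = (M[i] != M).sum(axis=1)
    return D


def _feasible_links(D: np.ndarray, eps: int) -> list[tuple[int, int]]:
    """Minimum-spanning-network links at tolerance eps.

    A pair (u, v) is feasible iff d(u,v) <= lambda(u,v) + eps where lambda is
    the distance level at which u and v first fall into one component when
    links are admitted in ascending distance order (Kruskal joining level).
    """
    n = D.shape[0]
    if n == 1:
        return []
    lam = np.zeros((n, n), dtype=int)
    comp = np.arange(n)
    levels = np.unique(D[np.triu_indices(n, 1)])
    for d in levels:
        before = comp.copy()
        for u, v in zip(*np.where(np.triu(D, 1) == d)):
            a, b = comp[u], comp[v]
            if a != b:
                comp[comp == b] = a
        merged = (before[:, None] != before[None, :]) & (comp[:, None] == comp[None, :])
        lam[merged & (lam == 0)] = d
    links = []
    for u in range(n):
        for v in range(u + 1, n):
            if D[u, v] <= lam[u, v] + eps:
                links.append((u, v))
    return links


def _median_seq(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-site majority of three sequences; three-way ties take the first parent."""
    m = a.copy()
    m[b == c] = b[b == c]
    return m


@dataclass
class HaploNetwork:
    """A haplotype network: observed nodes (with sizes) plus inferred medians."""

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def sequence(self, node: str) -> str:
        return self.graph.nodes[node]["sequence"]

    def edges_tsv(self) -> str:
        lines = ["node_a\tnode_b\tweight\tchanged_sites"]
        for u, v, d in sorted(self.graph.edges(data=True)):
            sites = ",".join(str(s) for s in d["changed_sites"])
            lines.append(f"{u}\t{v}\t{d['weight']}\t{sites}")
        return "\n".join(lines) + "\n"

    def nodes_tsv(self) -> str:
        lines = ["node\tkind\tsize\tcategory_mix"]
        for n, d in sorted(self.graph.nodes(data=True)):
            mix = json.dumps(d.get("category_mix", {}), sort_keys=True)
            lines.append(f"{n}\t{d['kind']}\t{d['size']}\t{mix}")
        return "\n".join(lines) + "\n"


def _build_graph(ids: list[str], arrs: list[np.ndarray], kinds: list[str],
                 sizes: list[int], eps: int) -> nx.Graph:
    D = _dist_matrix(arrs)
    G = nx.Graph()
    for i, nid in enumerate(ids):
        G.add_node(nid, kind=kinds[i], size=sizes[i],
                   sequence=arrs[i].tobytes().decode("ascii"))
    for u, v in _feasible_links(D, eps):
        sites = [int(s) for s in np.where(arrs[u] != arrs[v])[0]]
        G.add_edge(ids[u], ids[v], weight=int(D[u, v]), changed_sites=sites)
    return G


def median_joining(table: HaplotypeTable, epsilon: int = 0) -> HaploNetwork:
    """Build the median-joining network of a haplotype table.

    Requires haplotype sequences of equal length.  Node sizes are individual
    counts when the table carries them, otherwise the number of populations
    the haplotype occurs in; median nodes have size 0.
    """
    if any(s is None for _, s in table.haplotypes):
        raise AlignmentError("median joining requires haplotype sequences")
    lengths = {len(s) for _, s in table.haplotypes}
    if len(lengths) != 1:
        raise AlignmentError("haplotype sequences differ in length")

    ids = [h for h, _ in table.haplotypes]
    arrs = [_to_array(s) for _, s in table.haplotypes]
    known = {a.tobytes() for a in arrs}
    kinds = ["observed"] * len(ids)
    n_median = 0

    for _ in range(_MAX_ROUNDS):
        D = _dist_matrix(arrs)
        links = _feasible_links(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(ids))}
        for u, v in links:
            adj[u].add(v)
            adj[v].add(u)
        candidates: dict[bytes, tuple[int, np.ndarray]] = {}
        for u in range(len(ids)):
            nbrs = sorted(adj[u])
            for i, v in enumerate(nbrs):
                for w in nbrs[i + 1:]:
                    t = sorted((u, v, w))
                    m = _median_seq(arrs[t[0]], arrs[t[1]], arrs[t[2]])
                    key = m.tobytes()
                    if key in known:
                        continue
                    cost = sum(_hamming(m, arrs[x]) for x in t)
                    if key not in candidates or cost < candidates[key][0]:
                        candidates[key] = (cost, m)
        if not candidates:
            break
        lam_min = min(c for c, _ in candidates.values())
        added = False
        for key, (cost, m) in sorted(candidates.items()):
            if cost <= lam_min + epsilon:
                n_median += 1
                ids.append(f"mv{n_median}")
                arrs.append(m)
                kinds.append("median")
                known.add(key)
                added = True
        if not added:
            break

    sizes = []
    for nid, kind in zip(ids, kinds):
        if kind == "median":
            sizes.append(0)
        elif table.counts:
            sizes.append(sum(table.counts.get((p, nid), 0) for p in table.incidence[nid]))
        else:
            sizes.append(len(table.incidence[nid]))

    # prune superfluous medians: low-degree medians not needed by any shortest
    # observed-to-observed connection
    while True:
        G = _build_graph(ids, arrs, kinds, sizes, epsilon)
        obs = [n for n, d in G.nodes(data=True) if d["kind"] == "observed"]
        removable = None
        for nid in sorted(n for n, d in G.nodes(data=True) if d["kind"] == "median"):
            if G.degree(nid) > 2:
                continue
            H = G.copy()
            H.remove_node(nid)
            if obs and not _spans(H, obs):
                continue
            if _paths_preserved(G, H, obs):
                removable = nid
                break
        if removable is None:
            break
        k = ids.index(removable)
        for lst in (ids, arrs, kinds, sizes):
            del lst[k]

    G = _build_graph(ids, arrs, kinds, sizes, epsilon)
    for n in G.nodes:
        G.nodes[n].setdefault("category_mix", {})
    return HaploNetwork(G, epsilon)


def _spans(G: nx.Graph, obs: list[str]) -> bool:
    if not obs:
        return True
    seen = nx.node_connected_component(G, obs[0]) if obs[0] in G else set()
    return all(o in seen for o in obs)


def _paths_preserved(G: nx.Graph, H: nx.Graph, obs: list[str]) -> bool:
    for i, a in enumerate(obs):
        la = nx.single_source_dijkstra_path_length(G, a)
        lb = nx.single_source_dijkstra_path_length(H, a)
        for b in obs[i + 1:]:
            if la.get(b) != lb.get(b):
                return False
    return True


def annotate_categories(net: HaploNetwork, covariates, variable: str,
                        table: HaplotypeTable) -> HaploNetwork:
    """Attach a per-node category mix (counts of individuals by population category)."""
    df = getattr(covariates, "df", covariates)
    if variable not in df.columns:
        raise PopmapError(f"category variable {variable!r} not in covariate table")
    cat_of = df[variable].to_dict()
    missing = [p for p in table.populations if p not in cat_of]
    if missing:
        raise PopmapError(f"no category for populations {missing}")
    for nid in net.observed:
        mix: dict[str, int] = {}
        for pop in sorted(table.incidence[nid]):
            w = table.counts.get((pop, nid), 0) if table.counts else 1
            key = str(cat_of[pop])
            mix[key] = mix.get(key, 0) + w
        net.graph.nodes[nid]["category_mix"] = mix
    return net


def network_summary(net: HaploNetwork) -> tuple[int, int]:
    """(number of median vectors, number of independent loops |E| − |V| + components)."""
    G = net.graph
    loops = G.number_of_edges() - G.number_of_nodes() + nx.number_connected_components(G)
    return len(net.medians), loops


def attach_outgroup(net: HaploNetwork, outgroup_seq: str) -> tuple[str, int]:
    """Nearest observed node to an outgroup sequence (candidate ancestral haplotype)."""
    arr = _to_array(outgroup_seq)
    best, bd = None, math.inf
    for nid in sorted(net.observed):
        d = _hamming(arr, _to_array(net.sequence(nid)))
        if d < bd:
            best, bd = nid, d
    return best, int(bd)
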