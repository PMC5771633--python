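"""Median-joining haplotype networks and rho-statistic clade dating.

The median-joining construction iterates three steps until stable:
(i) build the epsilon-relaxed minimum-spanning network (MSN) over the current
node set under weighted Hamming distance -- at epsilon 0 this is the union of
all minimum spanning trees, obtained by admitting an edge (u, v) exactly when
its length equals the minimax path cost between u and v; (ii) for node
triplets adjacent in the MSN, add the quasi-median (per-character majority,
well defined for binary characters) as a synthetic "median vector" when it is
new and of minimal connection cost this round; (iii) drop obsolete median
vectors (degree <= 2 and on no shortest observed-observed path). DNA-state
input is binarised per segregating state before construction.

The rho statistic is the multiplicity-weighted mean shortest-path mutation
count from a designated ancestral node to a set of descendant haplotypes;
multiplying by a mutation rate (years per mutation) converts it to an age.
Its standard deviation is computed on the shortest-path tree rooted at the
ancestor as sqrt(sum_e l_e * n_e^2) / n, with l_e the edge's mutation count
and n_e the number of descendant lineages traversing edge e.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FescueError, InputError
from .variants import round_half_up


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus median vectors with mutation-weighted edges.

    ``graph`` is an undirected networkx graph whose nodes carry attributes
    ``haplotype`` (tuple of character states), ``is_median``, ``taxa`` (list
    of taxon labels collapsed onto the node) and ``multiplicity``; edges
    carry ``mutations`` (unweighted differing-character count) and ``weight``
    (character-weighted distance used during construction).
    """

    graph: nx.Graph
    epsilon: int = 0
    character_weights: tuple[float, ...] = ()

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def node_of_taxon(self, taxon: str) -> str:
        for n, d in self.graph.nodes(data=True):
            if taxon in d["taxa"]:
                return n
        raise InputError(f"taxon {taxon!r} not in network")


@dataclass
class AgeEstimate:
    """Rho, its standard deviation, and mutation-rate-scaled ages."""

    ancestral_node: str
    descendants: tuple[str, ...]
    rho: float
    sd_rho: float
    mutation_rate: float  # years per mutation

    @property
    def age_years(self) -> float:
        return self.rho * self.mutation_rate

    @property
    def sd_years(self) -> float:
        return self.sd_rho * self.mutation_rate

    @property
    def age_my(self) -> float:
        return self.age_years / 1e6

    @property
    def sd_my(self) -> float:
        return self.sd_years / 1e6

    @property
    def age_my_rounded(self) -> float:
        return round_half_up(self.age_my, 2)

    @property
    def sd_my_rounded(self) -> float:
        """SD in My at the precision ages are reported with (one extra
        decimal below 0.1 My, mirroring values like 0.061)."""
        return round_half_up(self.sd_my, 3 if self.sd_my < 0.1 else 2)


def _binarise(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Drop constant characters; expand multi-state characters one column per
    segregating non-reference state. Returns (matrix, weights-mask index)."""
    cols = []
    names = []
    for c in matrix.columns:
        col = matrix[c]
        states = sorted(set(col))
        if len(states) < 2:
            continue
        if set(states) <= {0, 1}:
            cols.append(col.to_numpy(dtype=np.int8))
            names.append(str(c))
        else:
            for s in states[1:]:
                cols.append((col == s).to_numpy(dtype=np.int8))
                names.append(f"{c}={s}")
    if not cols:
        return np.zeros((len(matrix), 0), dtype=np.int8), np.array([]), []
    return np.column_stack(cols), np.arange(len(cols)), names


def _weighted_dists(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted and unweighted Hamming distances between binary rows.

    Uses |x != y| = |x| + |y| - 2 x.y so both reduce to matrix products.
    """
    Xf = X.astype(np.float64)
    Xw = Xf * w
    s = Xw.sum(axis=1)
    wd = s[:, None] + s[None, :] - 2.0 * (Xw @ Xf.T)
    r = Xf.sum(axis=1)
    md = r[:, None] + r[None, :] - 2.0 * (Xf @ Xf.T)
    return np.maximum(wd, 0.0), np.rint(np.maximum(md, 0.0)).astype(int)


def _msn_edges(wd: np.ndarray, epsilon: float) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge qualifies when its weighted length is within epsilon of the
    minimax path cost between its endpoints (computed on the complete
    graph); epsilon 0 yields exactly the union of all MSTs.
    """
    n = wd.shape[0]
    if n == 1:
        return []
    # minimax path costs via Prim-grown MST
    minimax = np.zeros((n, n))
    in_tree = [0]
    best = wd[0].copy()
    parent = np.zeros(n, dtype=int)
    order = []
    used = np.zeros(n, bool)
    used[0] = True
    for _ in range(n - 1):
        cand = np.where(~used, best, np.inf)
        j = int(np.argmin(cand))
        order.append((parent[j], j, best[j]))
        used[j] = True
        upd = wd[j] < best
        parent[np.where(upd & ~used)[0]] = j
        best = np.where(upd, wd[j], best)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v, w in order:
        g.add_edge(u, v, weight=w)
    for src in range(n):
        # BFS over MST tracking max edge weight
        stack = [(src, -1, 0.0)]
        while stack:
            node, prev, mx = stack.pop()
            minimax[src, node] = mx
            for nb in g.neighbors(node):
                if nb != prev:
                    stack.append((nb, node, max(mx, g.edges[node, nb]["weight"])))
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if wd[i, j] <= minimax[i, j] + epsilon + 1e-9
    ]
    return edges


def median_joining(
    haplotypes: pd.DataFrame,
    epsilon: int = 0,
    weight: float | np.ndarray = 10.0,
    max_rounds: int = 50,
) -> HaplotypeNetwork:
    """Construct a median-joining network from a haplotype character matrix.

    ``haplotypes`` has one row per sampled haplotype (index = taxon labels;
    identical rows are collapsed with multiplicity) and one column per
    character (binary 0/1, or arbitrary states which are binarised per
    segregating state). ``weight`` is the per-character weight (scalar or
    vector); uniform scaling leaves the result unchanged.
    """
    if len(haplotypes) < 1:
        raise InputError("need at least one haplotype")
    X_full, _, char_names = _binarise(haplotypes)
    n_chars = X_full.shape[1]
    w = np.asarray(
        np.broadcast_to(np.asarray(weight, dtype=float), (n_chars,)),
        dtype=float,
    ).copy()
    if n_chars and (w <= 0).any():
        raise InputError("character weights must be positive")

    # collapse identical haplotypes
    taxa_of: dict[tuple, list[str]] = {}
    for taxon, row in zip(haplotypes.index, X_full):
        taxa_of.setdefault(tuple(int(v) for v in row), []).append(str(taxon))
    observed = list(taxa_of)
    nodes: list[tuple] = list(observed)
    is_median = [False] * len(nodes)

    scaled_eps = float(epsilon) * (float(np.mean(w)) if n_chars else 1.0)

    for _ in range(max_rounds):
        X = np.array(nodes, dtype=np.int8).reshape(len(nodes), n_chars)
        wd, _ = _weighted_dists(X, w)
        edges = _msn_edges(wd, scaled_eps)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for u, v in edges:
            adj[u].add(v)
            adj[v].add(u)
        # candidate quasi-medians from adjacent triplets u - v - t
        tri = []
        for v in range(len(nodes)):
            nbrs = sorted(adj[v])
            for ui, u in enumerate(nbrs):
                for t in nbrs[ui + 1 :]:
                    tri.append((u, v, t))
        if not tri:
            break
        tri_arr = np.array(tri)
        u_i, v_i, t_i = tri_arr[:, 0], tri_arr[:, 1], tri_arr[:, 2]
        sums = X[u_i] + X[v_i]
        sums += X[t_i]
        meds = (sums >= 2).astype(np.int8)
        # for a binary majority median the connection cost is half the
        # triplet's pairwise distance sum
        lams = (wd[u_i, v_i] + wd[v_i, t_i] + wd[u_i, t_i]) / 2.0
        existing = {row.tobytes() for row in X}
        candidates: dict[bytes, tuple[np.ndarray, float]] = {}
        for k in range(len(tri)):
            key = meds[k].tobytes()
            if key in existing:
                continue
            if key not in candidates or lams[k] < candidates[key][1]:
                candidates[key] = (meds[k], float(lams[k]))
        if not candidates:
            break
        lam_min = min(lam for _, lam in candidates.values())
        for med_row, lam in candidates.values():
            if lam <= lam_min + 1e-9:
                nodes.append(tuple(int(v) for v in med_row))
                is_median.append(True)
    else:
        warnings.warn("median-joining did not stabilise; returning current net")

    # final MSN + obsolete-median cleanup
    while True:
        X = np.array(nodes, dtype=np.int8).reshape(len(nodes), n_chars)
        wd, md = _weighted_dists(X, w)
        edges = _msn_edges(wd, scaled_eps)
        g = nx.Graph()
        for i in range(len(nodes)):
            g.add_node(i)
        for u, v in edges:
            g.add_edge(u, v, weight=wd[u, v], mutations=int(md[u, v]))
        obs_idx = [i for i, m in enumerate(is_median) if not m]
        drop = _obsolete_medians(g, is_median, obs_idx)
        if not drop:
            break
        nodes = [nd for i, nd in enumerate(nodes) if i not in drop]
        is_median = [m for i, m in enumerate(is_median) if i not in drop]

    # relabel into a stable public graph
    out = nx.Graph()
    med_counter = 0
    names = {}
    for i, nd in enumerate(nodes):
        if is_median[i]:
            med_counter += 1
            label = f"mv{med_counter}"
            taxa: list[str] = []
        else:
            taxa = taxa_of[nd]
            label = taxa[0]
        names[i] = label
        out.add_node(
            label,
            haplotype=nd,
            is_median=bool(is_median[i]),
            taxa=list(taxa),
            multiplicity=len(taxa),
        )
    for u, v, data in g.edges(data=True):
        out.add_edge(names[u], names[v], **data)
    return HaplotypeNetwork(
        graph=out, epsilon=epsilon, character_weights=tuple(w)
    )


def _obsolete_medians(
    g: nx.Graph, is_median: list[bool], obs_idx: list[int]
) -> set[int]:
    """Median nodes of degree <= 2 lying on no shortest observed-observed
    path (plus any median of degree <= 1)."""
    drop: set[int] = set()
    medians = [m for m, med in enumerate(is_median) if med]
    if not medians:
        return drop
    on_shortest: set[int] = set()
    dists = {
        s: nx.single_source_dijkstra_path_length(g, s, weight="weight")
        for s in obs_idx
    }
    for si, s in enumerate(obs_idx):
        for t in obs_idx[si + 1 :]:
            if t not in dists[s]:
                continue
            d_st = dists[s][t]
            for m in medians:
                if m in dists[s] and m in dists[t]:
                    if abs(dists[s][m] + dists[t][m] - d_st) < 1e-9:
                        on_shortest.add(m)
    for m, med in enumerate(is_median):
        if not med:
            continue
        if g.degree[m] <= 1 or (g.degree[m] <= 2 and m not in on_shortest):
            drop.add(m)
    return drop


def rho_age(
    net: HaplotypeNetwork,
    ancestral: str,
    descendants: list[str],
    mutation_rate: float = 20180.0,
) -> AgeEstimate:
    """Date a clade from its network: rho and SD scaled by a mutation rate.

    ``descendants`` are taxon labels; each maps to its (collapsed) network
    node and contributes with its multiplicity. Shortest paths are measured
    in summed edge mutation counts; ties among equal-length paths are broken
    toward the path with lexicographically smallest node labels, and
    reticulation at the ancestor (multiple equally short routes) triggers a
    warning.
    """
    g = net.graph
    if ancestral not in g:
        raise InputError(f"ancestral node {ancestral!r} not in network")
    if not descendants:
        raise InputError("descendants must be non-empty")
    node_of = {}
    for taxon in descendants:
        node_of[taxon] = net.node_of_taxon(taxon)

    dist, parent, tie_seen = _dijkstra_tree(g, ancestral)
    for taxon, node in node_of.items():
        if node not in dist:
            raise FescueError(
                f"descendant {taxon!r} (node {node!r}) unreachable from {ancestral!r}"
            )
    if tie_seen:
        warnings.warn(
            "multiple equal-length shortest paths from the ancestor; "
            "SD computed on the deterministic tie-broken shortest-path tree"
        )

    # lineage counts per shortest-path-tree edge
    n_through: dict[tuple[str, str], int] = {}
    total = 0
    rho_sum = 0.0
    for taxon, node in node_of.items():
        total += 1
        rho_sum += dist[node]
        cur = node
        while cur != ancestral:
            p = parent[cur]
            e = (p, cur)
            n_through[e] = n_through.get(e, 0) + 1
            cur = p
    rho = rho_sum / total
    var_sum = 0.0
    for (p, c), n_e in n_through.items():
        l_e = g.edges[p, c]["mutations"]
        var_sum += l_e * n_e**2
    sd_rho = np.sqrt(var_sum) / total
    return AgeEstimate(
        ancestral_node=ancestral,
        descendants=tuple(descendants),
        rho=float(rho),
        sd_rho=float(sd_rho),
        mutation_rate=float(mutation_rate),
    )


def _dijkstra_tree(g: nx.Graph, source: str):
    """Dijkstra over edge 'mutations' with deterministic lexicographic
    tie-breaking on predecessor labels. Returns (dist, parent, tie_seen)."""
    dist: dict[str, float] = {source: 0.0}
    parent: dict[str, str] = {}
    tie_seen = False
    heap = [(0.0, source)]
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in g.neighbors(u):
            nd = d + g.edges[u, v]["mutations"]
            if v not in dist or nd < dist[v] - 1e-12:
                dist[v] = nd
                parent[v] = u
                heapq.heappush(heap, (nd, v))
            elif v not in done and abs(nd - dist[v]) <= 1e-12:
                tie_seen = True
                if u < parent.get(v, u):
                    parent[v] = u
    return dist, parent, tie_seen


def scale_age(rho: float, sd_rho: float, mutation_rate: float = 20180.0) -> AgeEstimate:
    """Arithmetic-only age estimate from an externally computed rho/SD."""
    return AgeEstimate(
        ancestral_node="",
        descendants=(),
        rho=rho,
        sd_rho=sd_rho,
        mutation_rate=mutation_rate,
    )
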