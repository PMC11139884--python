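"""Speech-graph narrative features.

The narrative is represented as a directed multigraph over word types: one
node per distinct unit (lemma by default), one directed edge per consecutive
unit pair. Repetitive, recursive discourse shows up as loops and parallel
edges; fragmented discourse shows up in connectivity statistics.

Loop counts follow the speech-graph convention on the simple directed
projection (self-loops excluded from L2/L3):

* L1 — number of self-adjacent repetitions (self-loop node instances),
* L2 — number of node pairs connected in both directions (directed 2-cycles),
* L3 — number of distinct directed 3-cycles, ``trace(A³)/3`` on the
  zero-diagonal binary adjacency,
* PE — parallel-edge pairs: ``Σ C(m, 2)`` over ordered node pairs with
  multiplicity ``m``.

Path, clustering and transitivity statistics are computed with networkx on
the undirected simple projection of the largest weakly connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

GRAPH_FEATURE_NAMES = (
    "graph_l1", "graph_l2", "graph_l3", "graph_pe",
    "graph_degree_average", "graph_degree_std",
    "graph_average_clustering", "graph_average_shortest_path",
    "graph_transitivity", "graph_n_nodes", "graph_n_edges", "graph_lcc_size",
)


@dataclass
class GraphConfig:
    unit: str = "lemma"  # lemma | surface
    scope: str = "document"  # document | sentence


def build_speech_graph(doc, config: GraphConfig | None = None) -> nx.MultiDiGraph:
    """Build the word-adjacency multigraph of a tokenized transcript.

    Punctuation (including silent-break marks) is excluded; an edge is drawn
    between consecutive words within the chosen scope, so sentence scope
    breaks the stream at sentence boundaries.
    """
    config = config or GraphConfig()
    g = nx.MultiDiGraph()
    for segment in _unit_segments(doc, config):
        for u in segment:
            g.add_node(u)
        for u, v in zip(segment, segment[1:]):
            g.add_edge(u, v)
    return g


def _unit_segments(doc, config: GraphConfig) -> list[list[str]]:
    def unit(tok):
        s = tok.lemma if config.unit == "lemma" else tok.surface
        return s.lower()

    if config.scope == "sentence":
        return [
            [unit(t) for t in doc.tokens[a:b] if t.is_word]
            for (a, b) in doc.sentences
        ]
    return [[t_ for t_ in ([unit(t) for t in doc.tokens if t.is_word])]]


def graph_features(g: nx.MultiDiGraph) -> dict:
    """Compute the 12 speech-graph statistics of a narrative graph."""
    n = g.number_of_nodes()
    e = g.number_of_edges()
    out = dict.fromkeys(GRAPH_FEATURE_NAMES, 0.0)
    out["graph_n_nodes"] = float(n)
    out["graph_n_edges"] = float(e)
    if n == 0:
        return out

    # multiplicities of ordered pairs
    mult: dict = {}
    l1 = 0
    for u, v in g.edges():
        if u == v:
            l1 += 1
        mult[(u, v)] = mult.get((u, v), 0) + 1
    out["graph_l1"] = float(l1)
    out["graph_pe"] = float(sum(m * (m - 1) // 2 for m in mult.values()))

    from scipy import sparse
    from scipy.sparse import csgraph

    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    pairs = [(index[u], index[v]) for (u, v) in mult if u != v]
    if pairs:
        rows, cols = zip(*pairs)
        a = sparse.csr_array(
            (np.ones(len(pairs)), (rows, cols)), shape=(n, n))
    else:
        a = sparse.csr_array((n, n))
    at = a.T.tocsr()
    out["graph_l2"] = float(a.multiply(at).sum() // 2)
    out["graph_l3"] = float(round((a @ a).multiply(at).sum()) // 3)

    degrees = np.array([d for _, d in g.degree()], dtype=float)
    out["graph_degree_average"] = float(2.0 * e / n)
    out["graph_degree_std"] = float(degrees.std())

    und = ((a + at) > 0).astype(np.float64)
    n_comp, labels = csgraph.connected_components(und, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    lcc_label = int(np.argmax(sizes))
    out["graph_lcc_size"] = float(sizes[lcc_label])
    keep = np.flatnonzero(labels == lcc_label)
    if len(keep) > 1:
        u = und[np.ix_(keep, keep)].tocsr()
        deg = np.asarray(u.sum(axis=1)).ravel()
        closed = np.asarray((u @ u).multiply(u).sum(axis=1)).ravel()
        denom = deg * (deg - 1.0)
        local = np.divide(closed, denom, out=np.zeros_like(closed),
                          where=denom > 0)
        out["graph_average_clustering"] = float(local.mean())
        out["graph_transitivity"] = (
            float(closed.sum() / denom.sum()) if denom.sum() > 0 else 0.0)
        dist = csgraph.shortest_path(u, method="D", unweighted=True)
        m = len(keep)
        out["graph_average_shortest_path"] = float(
            dist[~np.eye(m, dtype=bool)].mean())
    return out


def speech_graph_features(doc, config: GraphConfig | None = None) -> dict:
    return graph_features(build_speech_graph(doc, config))
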