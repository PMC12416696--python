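"""Social-state vectors and transition-graph metrics.

The cage floor is discretized into a 5 x 4 grid (5 columns along the 57.2 cm
axis, 4 rows along the 35.6 cm axis — cells of about 11 x 9 cm).  At each
frame the number of animals of a chosen subset in each cell forms a 20-D
social state vector; a day's directed state graph connects every pair of
distinct states ever observed on consecutive recorded frames.  Reported
metrics: node count, number of independent cycles (circuit rank), global
transitivity, and mean shortest-path length.
"""
from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .trajectory_io import TrackSet, centroid_series

__all__ = [
    "build_state_graph",
    "graph_metrics",
    "network_subsets",
    "simple_cycle_count",
    "state_sequence",
]

GRID_COLS = 5  # along the cage length
GRID_ROWS = 4  # along the cage width


def state_sequence(
    tracks: TrackSet,
    subset: list[str] | None = None,
    grid: tuple[int, int] = (GRID_COLS, GRID_ROWS),
) -> np.ndarray:
    """Per-frame social state vectors, shape ``(T, cols*rows)`` int.

    Each present subset animal is assigned to exactly one grid cell
    (half-open cell edges, the last row/column closed at the cage wall);
    missing animals are omitted, so the vector sum equals the number of
    tracked subset animals at that frame.  Vectors are row-major over
    (row, column).
    """
    cols, rows = grid
    names = subset if subset is not None else tracks.animal_names
    if not names:
        raise ValueError("subset must be non-empty")
    cw = tracks.cage.length_cm / cols
    rh = tracks.cage.width_cm / rows
    T = tracks.n_frames
    out = np.zeros((T, cols * rows), dtype=np.int16)
    for name in names:
        cent = centroid_series(tracks, name)
        present = ~np.isnan(cent[:, 0])
        c = np.minimum((cent[present, 0] // cw).astype(int), cols - 1)
        r = np.minimum((cent[present, 1] // rh).astype(int), rows - 1)
        np.add.at(out, (np.flatnonzero(present), r * cols + c), 1)
    return out


def network_subsets(tracks: TrackSet) -> dict[str, list[str]]:
    """The standard subset families: single pups, animal pairs, all pups, all animals.

    For a full 6-animal family this yields the study's 14 networks per day:
    4 single-pup, 1 adult-pair, 6 pup-pair, 1 all-pup, 1 all-animal, plus
    the aggregate singles.
    """
    pups = [a.name for a in tracks.animals if a.age_class == "pup"]
    adults = [a.name for a in tracks.animals if a.age_class == "adult"]
    subsets: dict[str, list[str]] = {}
    for p in pups:
        subsets[f"single:{p}"] = [p]
    if len(adults) == 2:
        subsets["pair:adults"] = adults
    for a, b in combinations(pups, 2):
        subsets[f"pair:{a}+{b}"] = [a, b]
    if pups:
        subsets["all-pups"] = pups
    subsets["all-animals"] = tracks.animal_names
    return subsets


def build_state_graph(
    sequence: np.ndarray,
    timestamps: np.ndarray | None = None,
    fps: float | None = None,
) -> nx.DiGraph:
    """Directed graph of observed transitions between distinct social states.

    Consecutive identical vectors are collapsed (no self-loops), repeated
    transitions are deduplicated, and consecutive frames separated by
    recording downtime (timestamp gap above 1.5 frame steps) do not create
    an edge.  Each edge stores the frame index of its first observation.
    """
    seq = np.asarray(sequence)
    if len(seq) < 2:
        raise ValueError("need at least 2 frames to build a state graph")
    if timestamps is not None and fps is not None:
        linked = np.diff(np.asarray(timestamps, dtype=float)) <= 1.5 / fps
    else:
        linked = np.ones(len(seq) - 1, dtype=bool)
    g = nx.DiGraph()
    states = [tuple(int(v) for v in row) for row in seq]
    g.add_node(states[0])
    for f in range(1, len(states)):
        g.add_node(states[f])
        if not linked[f - 1]:
            continue
        u, v = states[f - 1], states[f]
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v, first_frame=f)
    return g


def graph_metrics(graph: nx.DiGraph) -> dict[str, float]:
    """Size, independent-cycle count, transitivity and mean path length.

    ``n_cycles`` is the circuit rank (edges - nodes + components) of the
    undirected simple projection — the number of independent, unrepeated
    cycles.  ``transitivity`` is 3 x triangles / connected triples on the
    same projection (0 when no triples exist), and ``mean_path_length``
    averages shortest-path lengths within the largest connected component.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    u = nx.Graph(graph)
    u.remove_edges_from(nx.selfloop_edges(u))
    n, e = u.number_of_nodes(), u.number_of_edges()
    c = nx.number_connected_components(u)
    n_cycles = e - n + c
    transitivity = nx.transitivity(u)
    largest = max(nx.connected_components(u), key=len)
    sub = u.subgraph(largest)
    if sub.number_of_nodes() > 1:
        adj = nx.to_scipy_sparse_array(sub, format="csr")
        dist = shortest_path(adj, method="D", unweighted=True, directed=False)
        m = sub.number_of_nodes()
        mpl = float(dist[~np.eye(m, dtype=bool)].mean())
    else:
        mpl = 0.0
    return {
        "size": float(n),
        "n_cycles": float(n_cycles),
        "transitivity": float(transitivity),
        "mean_path_length": float(mpl),
    }


def simple_cycle_count(graph: nx.DiGraph, max_nodes: int = 50) -> int:
    """Exact directed simple-cycle enumeration (exponential; small graphs only)."""
    if graph.number_of_nodes() > max_nodes:
        raise ValueError(
            f"simple-cycle enumeration limited to {max_nodes} nodes; "
            "use graph_metrics (circuit rank) for larger graphs"
        )
    return sum(1 for _ in nx.simple_cycles(graph))


def _state_str(state: tuple[int, ...]) -> str:
    return "".join(str(min(v, 9)) for v in state)


def write_edge_list(graph: nx.DiGraph, path) -> None:
    rows = [
        (_state_str(u), _state_str(v), d.get("first_frame", -1))
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["src_state", "dst_state", "first_frame"]).sort_values(
        ["src_state", "dst_state"]
    ).to_csv(path, index=False)


def write_graphml(graph: nx.DiGraph, path) -> None:
    relabeled = nx.relabel_nodes(graph, {n: _state_str(n) for n in graph.nodes})
    nx.write_graphml(relabeled, path)
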