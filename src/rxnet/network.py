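"""Shared-patient physician network construction and positional measures.

Nodes are physicians; an edge's weight counts the occasions on which a
patient visited the two physicians consecutively within a 30-day window,
pooled over patients.  Distance-based centralities (closeness,
betweenness) are computed on the largest connected component with edge
lengths equal to inverse edge weights, so heavier patient-sharing means a
shorter path.

Note on closeness: with inverse-weight distances pairwise distances can be
below 1, so Freeman-normalized closeness ``(n - 1) / sum_j d_ij`` may
exceed 1 on weighted graphs.  Values are reported as computed, not
clamped.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "build_shared_patient_network",
    "extract_lcc",
    "compute_centralities",
    "barrat_clustering",
    "eigenvector_power",
    "compute_volume",
    "standardize_measures",
    "physician_metrics",
]

#: network measures produced per physician, in reporting order
MEASURES = ("strength", "degree", "closeness", "betweenness", "eigenvector", "clustering")


def _collapse_runs(pairs: list[tuple[int, str]]) -> list[tuple[str, int, int]]:
    """Collapse consecutive same-physician encounters to (phys, first, last)."""
    runs: list[tuple[str, int, int]] = []
    for date, phys in pairs:
        if runs and runs[-1][0] == phys:
            runs[-1] = (phys, runs[-1][1], date)
        else:
            runs.append((phys, date, date))
    return runs


def build_shared_patient_network(
    encounters: pd.DataFrame,
    window_days: int = 30,
    physicians: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the undirected weighted shared-patient network.

    For each patient, encounters are ordered by date (ties broken by
    physician id); consecutive runs with the same physician collapse to a
    single visit block, and each adjacent pair of distinct physicians whose
    visit dates differ by at most ``window_days`` increments that pair's
    edge weight by one.  The inclusive window reads "within 30 days" as
    a gap of <= 30 days.
    """
    if encounters.empty:
        raise ValueError("encounter log is empty")
    if (encounters["date"] < 0).any():
        raise ValueError("encounter dates must be non-negative")
    if physicians is not None:
        known = set(physicians["physician_id"].astype(str))
        seen = set(encounters["physician_id"].astype(str))
        unknown = seen - known
        if unknown:
            raise ValueError(f"unknown physician ids in encounter log: {sorted(unknown)[:5]}")

    g = nx.Graph()
    g.add_nodes_from(sorted(encounters["physician_id"].astype(str).unique()))
    for _, patient_df in encounters.groupby("patient_id", sort=True):
        pairs = sorted(
            zip(patient_df["date"].astype(int), patient_df["physician_id"].astype(str))
        )
        runs = _collapse_runs(pairs)
        for (p1, _, last1), (p2, first2, _) in zip(runs, runs[1:]):
            if first2 - last1 <= window_days:
                if g.has_edge(p1, p2):
                    g[p1][p2]["weight"] += 1
                else:
                    g.add_edge(p1, p2, weight=1)
    return g


def extract_lcc(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member id so the
    result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return g.subgraph(components[0]).copy()


def barrat_clustering(g: nx.Graph) -> dict[str, float]:
    """Barrat weighted local clustering coefficient.

    ``c_i = 1 / (s_i (k_i - 1)) * sum_{j,h} (w_ij + w_ih) / 2`` over pairs
    of neighbours j, h of i that are themselves connected; defined as 0
    for nodes with degree <= 1.  Reduces to the binary clustering
    coefficient when all weights are equal.
    """
    out: dict[str, float] = {}
    for i in g.nodes:
        neighbors = list(g.neighbors(i))
        k = len(neighbors)
        if k <= 1:
            out[i] = 0.0
            continue
        s = sum(g[i][j]["weight"] for j in neighbors)
        total = 0.0
        for a in range(k):  # ordered neighbour pairs, as in the binary limit
            for b in range(a + 1, k):
                j, h = neighbors[a], neighbors[b]
                if g.has_edge(j, h):
                    total += g[i][j]["weight"] + g[i][h]["weight"]
        out[i] = total / (s * (k - 1))
    return out


def eigenvector_power(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, max entry scaled to 1.

    Power iteration to relative tolerance ``tol``; invariant under uniform
    rescaling of all edge weights.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 1:
        return {nodes[0]: 1.0}
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    # positive diagonal shift: same principal eigenvector, but damps the
    # +/-lambda oscillation of bipartite-like adjacencies
    shift = a.sum(axis=1).max()
    a = a + shift * np.eye(n)
    x = np.ones(n) / n
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("adjacency has no principal eigenvector (no edges)")
        y /= norm
        if np.linalg.norm(y - x) <= tol * np.linalg.norm(y):
            x = y
            break
        x = y
    else:
        raise RuntimeError("power iteration did not converge")
    x = np.abs(x)
    return dict(zip(nodes, x / x.max()))


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Six positional measures for every node of a connected network.

    Strength and degree come straight from the weighted adjacency;
    closeness and betweenness use Dijkstra distances over edge lengths
    ``1 / weight``; eigenvector centrality is the power-iteration principal
    vector; clustering is the Barrat weighted coefficient.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if not nx.is_connected(g):
        raise ValueError(
            "network is disconnected; extract the largest connected component first"
        )
    for u, v, d in g.edges(data=True):
        d["dist"] = 1.0 / d["weight"]

    nodes = sorted(g.nodes)
    strength = {n: float(sum(g[n][j]["weight"] for j in g.neighbors(n))) for n in nodes}
    degree = {n: g.degree(n) for n in nodes}
    closeness = nx.closeness_centrality(g, distance="dist")
    betweenness = nx.betweenness_centrality(g, weight="dist", normalized=True)
    if g.number_of_edges() > 0:
        eigen = eigenvector_power(g)
    else:
        eigen = {n: 1.0 for n in nodes}
    clustering = barrat_clustering(g)

    return pd.DataFrame(
        {
            "strength": [strength[n] for n in nodes],
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "eigenvector": [eigen[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
        },
        index=pd.Index(nodes, name="physician_id"),
    )


def compute_volume(
    encounters: pd.DataFrame, physicians: pd.DataFrame
) -> pd.Series:
    """Distinct patients encountered per physician over the study window.

    Physicians in the roster with no encounters get volume 0.
    """
    counts = (
        encounters.astype({"physician_id": str, "patient_id": str})
        .groupby("physician_id")["patient_id"]
        .nunique()
    )
    index = pd.Index(sorted(physicians["physician_id"].astype(str)), name="physician_id")
    return counts.reindex(index, fill_value=0).astype(int).rename("volume")


def standardize_measures(
    metrics: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each named column by its sample SD (ddof=1), without centering.

    Coefficients on standardized columns then correspond to a one-SD change
    in the predictor.  Returns the new frame (columns replaced in place)
    and a mapping of column name to the SD used.
    """
    out = metrics.copy()
    sds: dict[str, float] = {}
    for col in columns:
        sd = float(out[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero or undefined sample SD")
        out[col] = out[col] / sd
        sds[col] = sd
    out.attrs["standardization_sds"] = sds
    return out, sds


def physician_metrics(
    encounters: pd.DataFrame,
    physicians: pd.DataFrame,
    window_days: int = 30,
) -> tuple[pd.DataFrame, nx.Graph, nx.Graph]:
    """Full network stage: graph, LCC, centralities, volume, specialty.

    Returns ``(metrics, network, lcc)``.  Distance-based measures are only
    defined inside the LCC; physicians outside it carry NaN there and are
    excluded from modeling via the ``in_lcc`` flag.
    """
    g = build_shared_patient_network(encounters, window_days, physicians)
    lcc = extract_lcc(g)
    cent = compute_centralities(lcc)
    volume = compute_volume(encounters, physicians)

    phys = physicians.astype({"physician_id": str}).set_index("physician_id")
    metrics = pd.DataFrame(index=volume.index)
    metrics["volume"] = volume
    metrics["specialty"] = phys["specialty"].reindex(metrics.index)
    metrics["in_lcc"] = metrics.index.isin(cent.index)
    # strength/degree are defined on the full graph for every physician in it
    full_strength = {n: float(sum(g[n][j]["weight"] for j in g.neighbors(n))) for n in g.nodes}
    metrics["strength"] = pd.Series(full_strength).reindex(metrics.index)
    metrics["degree"] = pd.Series(dict(g.degree())).reindex(metrics.index)
    for m in ("closeness", "betweenness", "eigenvector", "clustering"):
        metrics[m] = cent[m].reindex(metrics.index)
    return metrics, g, lcc
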