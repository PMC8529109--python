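"""Correlation-based co-occurrence networks and their summary indexes.

Follows the molecular-ecological-network recipe: keep features present in
more than half of the samples, fill remaining zeros with a small
pseudo-abundance, log10-transform, correlate features with Pearson's r,
and link every feature pair whose |r| reaches a similarity threshold S_t.
Edges keep the correlation sign, so cooperative (positive) and
competitive (negative) associations stay distinguishable. Modules come
from greedy (CNM-style) modularity optimization on the unsigned graph.

The threshold can be fixed, or scanned with a random-matrix-theory
heuristic: the eigenvalue spacing distribution of the thresholded
adjacency transitions from the Wigner surmise (GOE-like level repulsion,
typical of a correlated noise background) to the Poisson law (independent
levels) once the surviving edges reflect modular structure; the scan
returns the smallest threshold where a chi-squared fit prefers Poisson.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractError
from .io_profiles import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    prevalence_min: float = 0.5  # keep features present in strictly more than this fraction
    fill_value: float = 0.01
    log_base: float = 10.0
    threshold_method: str = "fixed"  # or "scan"
    S_t: float = 0.8
    scan_range: tuple[float, float, float] = (0.30, 0.99, 0.01)

    def __post_init__(self) -> None:
        if not 0.0 < self.S_t < 1.0:
            raise ValueError("S_t must lie in (0, 1)")
        lo, hi, step = self.scan_range
        if not (lo < hi and step > 0):
            raise ValueError("scan_range must be (low, high, step) ascending")
        if self.threshold_method not in ("fixed", "scan"):
            raise ValueError("threshold_method must be 'fixed' or 'scan'")


@dataclass
class NetworkResult:
    graph: nx.Graph  # nodes carry 'classification'; edges carry 'sign', 'correlation'
    modules: dict[str, int]
    indexes: dict[str, float]

    @property
    def edges(self) -> list[tuple[str, str, int, float]]:
        return sorted(
            (min(u, v), max(u, v), d["sign"], d["correlation"])
            for u, v, d in self.graph.edges(data=True)
        )


def prepare_matrix(table: AbundanceTable, config: NetworkConfig = NetworkConfig()) -> pd.DataFrame:
    """Prevalence-filter, zero-fill and log-transform an abundance table.

    Keeps features with abundance > 0 in strictly more than
    ``prevalence_min`` of samples (the default majority rule drops a
    feature present in exactly half). Zeros become ``fill_value`` before
    the log, so an absent observation maps to log10(0.01) = -2.
    """
    vals = table.values
    if len(vals) < 4:
        raise ContractError("network inference needs at least four samples")
    prevalence = (vals > 0).mean(axis=0)
    keep = prevalence > config.prevalence_min
    if not keep.any():
        raise ContractError(
            "no feature passes the prevalence filter; lower prevalence_min"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter dropped %d of %d features", dropped, len(keep))
    out = vals.loc[:, keep].astype(float)
    out = out.where(out > 0, config.fill_value)
    return np.log(out) / np.log(config.log_base)


def correlation_matrix(prepared: pd.DataFrame) -> pd.DataFrame:
    """Feature x feature Pearson correlations of the prepared matrix."""
    sd = prepared.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "dropping %d zero-variance feature(s) before correlation", int((~keep).sum())
        )
        prepared = prepared.loc[:, keep]
    arr = np.corrcoef(prepared.to_numpy().T)
    return pd.DataFrame(arr, index=prepared.columns, columns=prepared.columns)


def _spacing_chi2(spacings: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Chi-squared distances of unit-mean spacings to Poisson and Wigner laws."""
    s = np.sort(spacings)
    edges = np.linspace(0.0, max(3.0, s.max()), n_bins + 1)
    obs, _ = np.histogram(s, bins=edges)
    obs = obs / obs.sum()
    # expected bin masses under each law
    poisson = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    wig_cdf = 1.0 - np.exp(-np.pi * edges**2 / 4.0)
    wigner = wig_cdf[1:] - wig_cdf[:-1]
    eps = 1e-9
    chi_p = float(np.sum((obs - poisson) ** 2 / (poisson + eps)))
    chi_w = float(np.sum((obs - wigner) ** 2 / (wigner + eps)))
    return chi_p, chi_w


def select_threshold(corr: pd.DataFrame, config: NetworkConfig = NetworkConfig()) -> float:
    """Choose the similarity threshold S_t.

    ``fixed`` returns ``config.S_t``. ``scan`` walks the candidate range
    upward and returns the smallest cutoff where the adjacency eigenvalue
    spacing distribution is closer to the Poisson law than to the Wigner
    surmise (degenerate spectra — heavy spacing mass at zero — count as
    Poisson, since level clustering is the Poisson signature). If no
    candidate qualifies, the scan maximum is returned with a warning.
    """
    if config.threshold_method == "fixed":
        return config.S_t
    n = corr.shape[0]
    if n < 10:
        raise ContractError("threshold scan needs >= 10 features; use the fixed method")
    A_full = np.abs(corr.to_numpy())
    np.fill_diagonal(A_full, 0.0)
    lo, hi, step = config.scan_range
    for t in np.arange(lo, hi + step / 2, step):
        A = (A_full >= t).astype(float)
        eigs = np.sort(np.linalg.eigvalsh(A))
        spacings = np.diff(eigs)
        mean = spacings.mean()
        if mean == 0:
            return float(round(t, 10))  # fully degenerate spectrum: Poisson-like
        chi_p, chi_w = _spacing_chi2(spacings / mean)
        if chi_p <= chi_w:
            return float(round(t, 10))
    logger.warning("no threshold in scan range preferred Poisson spacing; using maximum")
    return float(round(hi, 10))


def build_network(
    corr: pd.DataFrame,
    S_t: float,
    classification: dict[str, str] | None = None,
) -> NetworkResult:
    """Threshold the correlation matrix into a signed co-occurrence graph.

    An undirected edge joins every feature pair with |r| >= S_t; its sign
    is the sign of r. Isolated features are excluded (nodes are edge
    endpoints only). Modules are greedy-modularity communities of the
    unsigned, unweighted graph. Geodesic distance is averaged over
    connected node pairs only.
    """
    if not 0.0 < S_t < 1.0:
        raise ValueError("S_t must lie in (0, 1)")
    feats = [str(f) for f in corr.columns]
    R = corr.to_numpy()
    G = nx.Graph()
    n = len(feats)
    iu, ju = np.triu_indices(n, k=1)
    strong = np.abs(R[iu, ju]) >= S_t
    for i, j in zip(iu[strong], ju[strong]):
        r = float(R[i, j])
        G.add_edge(feats[i], feats[j], sign=1 if r >= 0 else -1, correlation=r)
    classification = classification or {}
    for node in G.nodes:
        G.nodes[node]["classification"] = classification.get(node, "")
    if G.number_of_edges() == 0:
        logger.warning("no feature pair reaches S_t=%.3f; empty network", S_t)
        indexes = dict.fromkeys(
            (
                "total_nodes", "total_links", "avg_connectivity",
                "avg_clustering_coefficient", "avg_geodesic_distance",
                "modularity", "pct_negative_links", "n_modules", "n_components",
            ),
            0.0,
        )
        return NetworkResult(graph=G, modules={}, indexes=indexes)

    communities = nx.community.greedy_modularity_communities(G)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules = {node: i for i, comm in enumerate(communities) for node in comm}
    Q = nx.community.modularity(G, communities)

    n_nodes = G.number_of_nodes()
    n_links = G.number_of_edges()
    geo_sum, geo_pairs = 0.0, 0
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            geo_sum += sum(lengths.values())
        geo_pairs += len(comp) * (len(comp) - 1)
    neg = sum(1 for _, _, d in G.edges(data=True) if d["sign"] < 0)
    indexes = {
        "total_nodes": float(n_nodes),
        "total_links": float(n_links),
        "avg_connectivity": 2.0 * n_links / n_nodes,
        "avg_clustering_coefficient": float(nx.average_clustering(G)),
        "avg_geodesic_distance": geo_sum / geo_pairs if geo_pairs else 0.0,
        "modularity": float(Q),
        "pct_negative_links": 100.0 * neg / n_links,
        "n_modules": float(len(communities)),
        "n_components": float(nx.number_connected_components(G)),
    }
    return NetworkResult(graph=G, modules=modules, indexes=indexes)


def export_cytoscape(net: NetworkResult, out_dir: str | Path, prefix: str = "network") -> tuple[Path, Path]:
    """Write Cytoscape-loadable edge and node attribute tables.

    Rows are sorted lexicographically so exports are deterministic.
    Returns (edge_path, node_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / f"{prefix}_edges.tsv"
    node_path = out_dir / f"{prefix}_nodes.tsv"
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\tcorrelation\n")
        for u, v, sign, r in net.edges:
            fh.write(f"{u}\t{v}\t{sign}\t{r:.12g}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\tclassification\tmodule\tdegree\n")
        for node in sorted(net.graph.nodes):
            fh.write(
                f"{node}\t{net.graph.nodes[node].get('classification', '')}\t"
                f"{net.modules.get(node, -1)}\t{net.graph.degree[node]}\n"
            )
    return edge_path, node_path


def read_cytoscape(edge_path: str | Path, node_path: str | Path) -> NetworkResult:
    """Rebuild a network from exported edge/node tables (round-trip support)."""
    edges = pd.read_csv(edge_path, sep="\t")
    nodes = pd.read_csv(node_path, sep="\t")
    G = nx.Graph()
    for row in nodes.itertuples():
        G.add_node(
            str(row.id),
            classification="" if pd.isna(row.classification) else str(row.classification),
        )
    for row in edges.itertuples():
        G.add_edge(str(row.source), str(row.target), sign=int(row.sign),
                   correlation=float(row.correlation))
    modules = {str(r.id): int(r.module) for r in nodes.itertuples()}
    neg = sum(1 for _, _, d in G.edges(data=True) if d["sign"] < 0)
    n_nodes, n_links = G.number_of_nodes(), G.number_of_edges()
    indexes = {
        "total_nodes": float(n_nodes),
        "total_links": float(n_links),
        "avg_connectivity": 2.0 * n_links / n_nodes if n_nodes else 0.0,
        "pct_negative_links": 100.0 * neg / n_links if n_links else 0.0,
    }
    return NetworkResult(graph=G, modules=modules, indexes=indexes)
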